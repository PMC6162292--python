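"""Simulation studies: method comparison, causality-test accuracy, robustness.

These drivers reproduce the package's evaluation protocol end to end:
generate data from the stated designs, run the tests, and summarize power
(ROC AUC over a null/alternative mixture), causal-direction accuracy,
model-selection accuracy, missing-data robustness, and confidence-interval
coverage.  Every driver is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .association import METHODS, handle_missing
from .causality import compare_m1_m2, select_cis_trans_model
from .data import GenotypeSplit
from .mptga import mptga_test
from .scan import estimate_ci
from .simulate import (CausalPairDesign, SimDesign, drop_missing,
                       simulate_genotypes, simulate_pair, simulate_trait)

__all__ = [
    "auc_from_pvalues", "association_power_study", "tgct_direction_study",
    "tgct_selection_study", "missing_robustness_study", "ci_coverage_study",
    "DEFAULT_TGCT_GRID",
]

#: TGCT simulation coefficient grid: lag coefficient beta1, causal effect
#: beta2, and the genotype offset applied to Y's intercepts in the
#: independent/partial designs.  One cell is drawn uniformly per replicate.
DEFAULT_TGCT_GRID = {
    "beta1": (0.2, 0.4, 0.6, 0.8),
    "beta2": (0.3, 0.5, 0.8, 1.0),
    "offset": (0.5, 1.0),
}

#: effect scale for the method-comparison study, chosen so the operating
#: point sits in the informative mid-range of the ROC rather than at
#: saturation (see docs/methods.md)
POWER_STUDY_EFFECT_SCALE = 0.35


def auc_from_pvalues(p_null: np.ndarray, p_alt: np.ndarray) -> float:
    """ROC AUC of a p-value-based detector (smaller p = more eQTL-like).

    Computed as the Mann-Whitney probability that a random alternative
    dataset receives a smaller p-value than a random null dataset.
    """
    p_null = np.asarray(p_null, float)
    p_alt = np.asarray(p_alt, float)
    u = stats.mannwhitneyu(-p_alt, -p_null, alternative="two-sided").statistic
    return float(u / (len(p_null) * len(p_alt)))


def _random_pattern_pair(rng) -> tuple[str, str]:
    from .simulate import PATTERNS
    a, b = rng.choice(list(PATTERNS), size=2, replace=False)
    return str(a), str(b)


def association_power_study(methods=("mptga", "regression", "ar"),
                            rho_mean: float = 0.9, n_datasets: int = 2000,
                            n_strains: int = 30, noise_sd: float = 0.5,
                            effect_scale: float = POWER_STUDY_EFFECT_SCALE,
                            missing_rate: float = 0.0, seed=None) -> dict:
    """AUC per method over a half-null / half-alternative dataset mixture.

    Each dataset draws a fresh genotype vector, a random pattern pair and
    a dataset-level AR(1) correlation from N(rho_mean, 0.02); alternatives
    shrink the second pattern toward the first by ``effect_scale``.  With
    ``missing_rate`` > 0 cells are masked and each method applies its own
    missing-data policy.
    """
    rng = np.random.default_rng(seed)
    pvals: dict[str, dict[bool, list]] = {m: {False: [], True: []}
                                          for m in methods}
    for _ in range(n_datasets):
        is_alt = rng.random() < 0.5
        pat = _random_pattern_pair(rng)
        design = SimDesign(n_strains=n_strains, rho_mean=rho_mean,
                           rho_sd=0.02, effect=pat,
                           effect_scale=effect_scale if is_alt else 0.0,
                           noise_sd=noise_sd)
        g = rng.integers(0, 2, size=n_strains)
        while min(g.sum(), n_strains - g.sum()) < 3:
            g = rng.integers(0, 2, size=n_strains)
        trait = simulate_trait(design, g, seed=rng)
        if missing_rate > 0:
            trait = drop_missing(trait, missing_rate, seed=rng)
        split = GenotypeSplit.from_genotypes(g)
        for m in methods:
            prepared = handle_missing(trait, split, m)
            p = METHODS[m](prepared, split).p_value
            pvals[m][is_alt].append(p)
    return {m: auc_from_pvalues(pvals[m][False], pvals[m][True])
            for m in methods}


def _draw_pair_design(rng, model: str, n_strains: int,
                      grid=None) -> CausalPairDesign:
    grid = grid or DEFAULT_TGCT_GRID
    b1 = float(rng.choice(grid["beta1"]))
    b2 = float(rng.choice(grid["beta2"]))
    off = float(rng.choice(grid["offset"]))
    pat = _random_pattern_pair(rng)
    if model == "causal":
        beta0, beta1 = (0.0, 0.0), (b1, b1)
    else:
        # genetics acts on Y directly: offset intercepts, shared lag
        beta0, beta1 = (0.0, off), (b1, b1)
    return CausalPairDesign(model=model, n_strains=n_strains, x_effect=pat,
                            beta0=beta0, beta1=beta1, beta2=b2)


def _linked_pair(X, Y, split, threshold):
    p_x = mptga_test(X, split).p_value
    if not p_x < threshold:
        return None
    p_y = mptga_test(Y, split).p_value
    if not p_y < threshold:
        return None
    return p_x, p_y


def _pair_iter(rng, model, n_strains, n_pairs, max_attempts, threshold, grid):
    """Yield (X, Y, split, p_x, p_y) for pairs passing the linkage filter."""
    kept = attempts = 0
    while kept < n_pairs and attempts < max_attempts:
        attempts += 1
        g = rng.integers(0, 2, size=n_strains)
        if min(g.sum(), n_strains - g.sum()) < 3:
            continue
        design = _draw_pair_design(rng, model, n_strains, grid)
        X, Y = simulate_pair(design, g, seed=rng)
        split = GenotypeSplit.from_genotypes(g)
        ps = _linked_pair(X, Y, split, threshold)
        if ps is None:
            continue
        kept += 1
        yield X, Y, split, ps[0], ps[1]


def tgct_direction_study(n_strains: int, n_pairs: int = 2000,
                         max_attempts: int = 40_000,
                         threshold: float = 1e-6, grid=None,
                         seed=None) -> dict:
    """Accuracy of the M1-vs-M2 directional call on simulated causal pairs.

    Pairs are generated under the causal wiring (X genetic, Y driven by
    lagged X), filtered so both traits are linked at the locus, and the
    joint-likelihood comparison is scored against the generating truth.
    """
    rng = np.random.default_rng(seed)
    correct = total = 0
    for X, Y, split, p_x, p_y in _pair_iter(rng, "causal", n_strains, n_pairs,
                                            max_attempts, threshold, grid):
        call = compare_m1_m2(X, Y, split, p_x=p_x, p_y=p_y,
                             p_threshold=threshold)
        total += 1
        correct += call.best_model == "M1"
    return {"n_strains": n_strains, "n_pairs": total,
            "accuracy": 100.0 * correct / total if total else np.nan}


def tgct_selection_study(n_strains: int, model: str = "independent",
                         n_pairs: int = 2000, max_attempts: int = 40_000,
                         threshold: float = 1e-6, grid=None,
                         seed=None) -> dict:
    """Accuracy of BIC selection among M1/M3/M4 on pairs of known wiring."""
    truth = {"causal": "M1", "independent": "M3", "partial": "M4"}[model]
    rng = np.random.default_rng(seed)
    correct = total = 0
    for X, Y, split, p_x, p_y in _pair_iter(rng, model, n_strains, n_pairs,
                                            max_attempts, threshold, grid):
        call = select_cis_trans_model(X, Y, split, p_x=p_x, p_y=p_y,
                                      p_threshold=threshold)
        total += 1
        correct += call.best_model == truth
    return {"n_strains": n_strains, "n_pairs": total, "model": model,
            "accuracy": 100.0 * correct / total if total else np.nan}


def missing_robustness_study(methods=("mptga", "regression", "ar", "union",
                                      "fisher", "manova"),
                             rates=(0.0, 0.05, 0.1), n_datasets: int = 2000,
                             n_strains: int = 30, rho_mean: float = 0.9,
                             effect_scale: float = POWER_STUDY_EFFECT_SCALE,
                             seed=None) -> dict:
    """AUC per method at increasing missing-data rates.

    Uses common random numbers: the same base datasets are reused at every
    rate and the masks are nested (cells missing at a lower rate stay
    missing at a higher one), so within-method AUC differences across
    rates are paired comparisons.
    """
    rng = np.random.default_rng(seed)
    pvals = {m: {r: {False: [], True: []} for r in rates} for m in methods}
    for _ in range(n_datasets):
        is_alt = rng.random() < 0.5
        pat = _random_pattern_pair(rng)
        design = SimDesign(n_strains=n_strains, rho_mean=rho_mean,
                           rho_sd=0.02, effect=pat,
                           effect_scale=effect_scale if is_alt else 0.0)
        g = rng.integers(0, 2, size=n_strains)
        while min(g.sum(), n_strains - g.sum()) < 3:
            g = rng.integers(0, 2, size=n_strains)
        trait = simulate_trait(design, g, seed=rng)
        split = GenotypeSplit.from_genotypes(g)
        u = rng.random(trait.values.shape)  # nested masks across rates
        for r in rates:
            masked = trait.copy()
            if r > 0:
                masked.mask = u < r
            for m in methods:
                try:
                    prepared = handle_missing(masked, split, m)
                    p = METHODS[m](prepared, split).p_value
                except ValueError:
                    p = 1.0  # degenerate masked dataset: no evidence
                pvals[m][r][is_alt].append(p)
    return {m: {r: auc_from_pvalues(pvals[m][r][False], pvals[m][r][True])
                for r in rates} for m in methods}


def ci_coverage_study(n_replicates: int = 500, n_strains: int = 95,
                      n_markers: int = 15, flip_prob: float = 0.02,
                      alpha: float = 0.05, df: int = 1,
                      effect_scale: float = 0.3, seed=None) -> dict:
    """Empirical coverage of the chi-square-quantile eQTL intervals.

    Each replicate plants an eQTL at the middle marker of an LD-chained
    chromosome and checks whether the interval covers its position.
    """
    rng = np.random.default_rng(seed)
    covered = 0
    widths = []
    for _ in range(n_replicates):
        geno = simulate_genotypes(n_strains, n_markers, seed=rng,
                                  linkage=True, flip_prob=flip_prob)
        true_j = n_markers // 2
        pat = _random_pattern_pair(rng)
        design = SimDesign(n_strains=n_strains, effect=pat,
                           effect_scale=effect_scale)
        trait = simulate_trait(design, geno.codes[:, true_j], seed=rng)
        ci = estimate_ci(trait, geno, alpha=alpha, df=df)
        true_pos = int(geno.pos[true_j])
        covered += ci.ci_low <= true_pos <= ci.ci_high
        widths.append(ci.ci_high - ci.ci_low)
    return {"coverage": covered / n_replicates,
            "median_width": float(np.median(widths)),
            "n_replicates": n_replicates}
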