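"""Temporal genetic causality test (TGCT).

For two traits X and Y linked to the same locus, five lag-one
autoregressive wirings are possible: X drives Y (M1), Y drives X (M2),
the locus acts on each independently (M3), and partial variants where the
locus acts on both but one trait also drives the other (M4: X->Y,
M5: Y->X).  Each model is a pair of OLS regressions stacking the lag
equations over strains; Gaussian profile likelihoods and BIC select the
best-supported structure.

Model equations (delta_g = genotype indicators, t = 2..m):

    M1:  X_t = d0(a00 + a10 X_{t-1}) + d1(a01 + a11 X_{t-1}) + eps
         Y_t = b0 + b1 Y_{t-1} + b2 X_{t-1} + mu
    M2:  the mirror image of M1 with X and Y swapped
    M3:  X_t as in M1;  Y_t = d0(b00 + b10 Y_{t-1}) + d1(b01 + b11 Y_{t-1}) + mu
    M4:  X_t as in M1;  Y_t as in M3 plus b2 X_{t-1}
    M5:  the mirror image of M4

When X is known to be cis-regulated at the locus, only M1/M3/M4 are in
play and they share the X equation, so selection reduces to the Y
regressions alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeSplit, TimeCourseMatrix

__all__ = [
    "CausalModelFit", "CausalCall", "fit_tgct_models", "compare_m1_m2",
    "select_cis_trans_model", "rank_regulators", "FilterNotSatisfied",
]

#: Y-equation parameter counts: shared AR (M1) = 3, per-genotype AR (M3) = 4,
#: per-genotype AR + causal lag (M4) = 5.  The residual variance is profiled
#: identically in every model and is not counted.
K_Y = {"M1": 3, "M3": 4, "M4": 5}
#: complexity order used to break exact BIC ties toward the simpler model
_COMPLEXITY = {"M1": 0, "M3": 1, "M4": 2, "M2": 0, "M5": 2}


class FilterNotSatisfied(ValueError):
    """Raised when a causality call is requested for an unlinked trait pair."""


@dataclass
class CausalModelFit:
    """One fitted model: coefficients, RSS, profile log-likelihood, BIC."""

    model_id: str
    coef_y: np.ndarray
    rss_y: float
    loglik_y: float
    k: int
    bic: float
    coef_x: np.ndarray | None = None
    rss_x: float | None = None
    loglik_x: float | None = None


@dataclass
class CausalCall:
    """Outcome of a model comparison for one trait pair."""

    x_gene: str
    y_gene: str
    marker: str
    best_model: str
    bic_margin: float
    bics: dict = field(default_factory=dict)
    log_lr: float | None = None  # M1-vs-M2 mode: ln L(M1) - ln L(M2)


def _stack_lags(trait: TimeCourseMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(response, lag) rows stacking t = 2..m over strains."""
    if trait.has_missing:
        raise ValueError("TGCT requires complete data; impute first")
    return trait.values[:, 1:].ravel(), trait.values[:, :-1].ravel()


def _profile_loglik(rss: float, n_obs: int) -> float:
    """Gaussian log-likelihood with sigma^2 profiled out at RSS/n.

    ln L = -(n/2) ln(2 pi) - (n/2) ln(RSS) + (n/2) ln(n) - n/2,
    where n counts the stacked lag observations.
    """
    rss = max(rss, 1e-300)
    return float(-0.5 * n_obs * (np.log(2 * np.pi) + np.log(rss)
                                 - np.log(n_obs) + 1.0))


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design (constant trait?)")
    r = y - X @ coef
    return coef, float(r @ r)


def _design_split_ar(lag: np.ndarray, glab: np.ndarray, n_groups: int) -> np.ndarray:
    X = np.zeros((len(lag), 2 * n_groups))
    for g in range(n_groups):
        sel = glab == g
        X[sel, 2 * g] = 1.0
        X[sel, 2 * g + 1] = lag[sel]
    return X


def _fit_x_split(X: TimeCourseMatrix, split: GenotypeSplit):
    """Genotype-split AR(1) fit of the X equation (shared by M1/M3/M4)."""
    x, xlag = _stack_lags(X)
    glab = np.repeat(split.indicator(X.n_strains), X.n_times - 1)
    coef, rss = _ols(_design_split_ar(xlag, glab, split.n_groups), x)
    return coef, rss, _profile_loglik(rss, len(x))


def fit_tgct_models(X: TimeCourseMatrix, Y: TimeCourseMatrix,
                    split: GenotypeSplit,
                    models: tuple[str, ...] = ("M1", "M3", "M4"),
                    ) -> list[CausalModelFit]:
    """OLS-fit the requested Y-equation models (with the shared X equation).

    X and Y must be aligned on the same strain panel.  Returns one
    :class:`CausalModelFit` per requested model, BIC attached.
    """
    if X.values.shape != Y.values.shape:
        raise ValueError("X and Y must share strains and timepoints")
    y, ylag = _stack_lags(Y)
    _, xlag = _stack_lags(X)
    n_obs = len(y)
    glab = np.repeat(split.indicator(X.n_strains), X.n_times - 1)
    coef_x, rss_x, ll_x = _fit_x_split(X, split)
    split_ar = _design_split_ar(ylag, glab, split.n_groups)

    designs = {
        "M1": np.column_stack([np.ones(n_obs), ylag, xlag]),
        "M3": split_ar,
        "M4": np.column_stack([split_ar, xlag]),
    }
    fits = []
    for mid in models:
        if mid not in designs:
            raise ValueError(f"unknown model {mid!r} (use M1/M3/M4, or "
                             "compare_m1_m2 for the directional test)")
        coef, rss = _ols(designs[mid], y)
        ll = _profile_loglik(rss, n_obs)
        k = K_Y[mid] if split.n_groups == 2 else {
            "M1": 3, "M3": 2 * split.n_groups, "M4": 2 * split.n_groups + 1}[mid]
        bic = np.log(n_obs) * k - 2.0 * ll
        fits.append(CausalModelFit(mid, coef, rss, ll, k, bic,
                                   coef_x=coef_x, rss_x=rss_x, loglik_x=ll_x))
    return fits


def _check_filter(p_x: float | None, p_y: float | None, threshold: float) -> None:
    if p_x is None and p_y is None:
        return  # caller takes responsibility for the association filter
    for name, p in (("X", p_x), ("Y", p_y)):
        if p is not None and not p < threshold:
            raise FilterNotSatisfied(
                f"trait {name} is not linked at the locus "
                f"(association p = {p:.3g} >= {threshold:g})")


def compare_m1_m2(X: TimeCourseMatrix, Y: TimeCourseMatrix,
                  split: GenotypeSplit, p_x: float | None = None,
                  p_y: float | None = None, p_threshold: float = 1e-6,
                  ) -> CausalCall:
    """Directional call: does X drive Y (M1) or Y drive X (M2)?

    Computes the joint profile log-likelihood ln L(X) + ln L(Y) under each
    wiring.  M1 and M2 have equal parameter counts, so the likelihood
    comparison and the BIC comparison coincide; ``log_lr`` > 0 favours M1.
    Pass the traits' association p-values to enforce the linkage filter.
    """
    _check_filter(p_x, p_y, p_threshold)
    x, xlag = _stack_lags(X)
    y, ylag = _stack_lags(Y)
    n_obs = len(y)
    glab = np.repeat(split.indicator(X.n_strains), X.n_times - 1)
    ones = np.ones(n_obs)

    # M1: genotype-split AR on X; Y regressed on its own lag and X's lag
    _, rss = _ols(_design_split_ar(xlag, glab, split.n_groups), x)
    ll_m1 = _profile_loglik(rss, n_obs)
    _, rss = _ols(np.column_stack([ones, ylag, xlag]), y)
    ll_m1 += _profile_loglik(rss, n_obs)
    # M2: the mirror image
    _, rss = _ols(_design_split_ar(ylag, glab, split.n_groups), y)
    ll_m2 = _profile_loglik(rss, n_obs)
    _, rss = _ols(np.column_stack([ones, xlag, ylag]), x)
    ll_m2 += _profile_loglik(rss, n_obs)

    log_lr = ll_m1 - ll_m2
    best = "M1" if log_lr >= 0 else "M2"
    return CausalCall(X.gene_id, Y.gene_id, "", best, abs(2 * log_lr),
                      bics={"M1": -2 * ll_m1, "M2": -2 * ll_m2}, log_lr=log_lr)


def select_cis_trans_model(X_cis: TimeCourseMatrix, Y_trans: TimeCourseMatrix,
                           split: GenotypeSplit, p_x: float | None = None,
                           p_y: float | None = None, p_threshold: float = 1e-6,
                           ) -> CausalCall:
    """BIC selection among causal / independent / partial-causal models.

    X is assumed cis-regulated at the locus, which rules out M2/M5; the
    three remaining models share the X equation, so only the Y regressions
    enter the comparison.  Exact BIC ties go to the simpler model.
    """
    _check_filter(p_x, p_y, p_threshold)
    fits = fit_tgct_models(X_cis, Y_trans, split, models=("M1", "M3", "M4"))
    order = sorted(fits, key=lambda f: (f.bic, _COMPLEXITY[f.model_id]))
    margin = order[1].bic - order[0].bic
    return CausalCall(X_cis.gene_id, Y_trans.gene_id, "", order[0].model_id,
                      float(margin), bics={f.model_id: f.bic for f in fits})


def rank_regulators(calls: list[CausalCall], hotspot_cutoff: int,
                    count_partial: bool = False) -> pd.DataFrame:
    """Rank candidate cis regulators of a hotspot by causal-edge counts.

    Counts, per cis gene, the trans genes whose best model is the causal
    one (optionally also the partial-causal one), ranks descending and
    flags genes whose count reaches the hotspot threshold as putative key
    regulators.  Cis genes with identical trait profiles will tie — the
    test cannot distinguish them and both are reported.
    """
    if not calls:
        return pd.DataFrame(columns=["x_gene", "n_causal", "n_pairs",
                                     "is_key_regulator"])
    causal_models = ("M1", "M4") if count_partial else ("M1",)
    rows: dict[str, dict] = {}
    for c in calls:
        r = rows.setdefault(c.x_gene, {"x_gene": c.x_gene, "n_causal": 0,
                                       "n_pairs": 0})
        r["n_pairs"] += 1
        if c.best_model in causal_models:
            r["n_causal"] += 1
    df = pd.DataFrame(rows.values()).sort_values(
        ["n_causal", "x_gene"], ascending=[False, True]).reset_index(drop=True)
    df["is_key_regulator"] = df["n_causal"] >= hotspot_cutoff
    return df
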