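"""Synthetic time-course genetics: every input the analyses need.

Traits are drawn from a multivariate normal with a cubic-polynomial mean
per genotype group and AR(1)-correlated residuals; trait pairs for the
causality test are generated from lag-one recursions with a causal,
independent, or partial-causal wiring; genotypes are Bernoulli(0.5)
markers, optionally chained into a linkage-disequilibrium block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .data import ExpressionSet, GenotypeTable, TimeCourseMatrix
from .mptga import ar1_corr

__all__ = [
    "PATTERNS", "pattern_curve", "SimDesign", "CausalPairDesign",
    "simulate_trait", "simulate_genotypes", "simulate_pair", "drop_missing",
    "simulate_scan_dataset",
]

# ---------------------------------------------------------------------------
# Pattern library: named cubic mean trajectories on t = 1..6, amplitude ~[-1, 1].
# Coefficients are (a0, a1, a2, a3) for a0 + a1 t + a2 t^2 + a3 t^3.
PATTERNS: dict[str, tuple[float, float, float, float]] = {
    "flat":           (0.0, 0.0, 0.0, 0.0),
    "linear_up":      (-1.4, 0.4, 0.0, 0.0),
    "linear_down":    (1.4, -0.4, 0.0, 0.0),
    "peak":           (-2.92, 2.24, -0.32, 0.0),
    "dip":            (2.92, -2.24, 0.32, 0.0),
    "rise_fall_rise": (-3.5, 3.45, -1.05, 0.1),
    "fall_rise_fall": (3.5, -3.45, 1.05, -0.1),
    "saturating_up":  (-1.88, 0.96, -0.08, 0.0),
}


def pattern_curve(pattern: str | tuple, times: np.ndarray) -> np.ndarray:
    """Evaluate a named or coefficient-tuple pattern on a time grid."""
    coeffs = PATTERNS[pattern] if isinstance(pattern, str) else tuple(pattern)
    t = np.asarray(times, dtype=float)
    return sum(c * t ** k for k, c in enumerate(coeffs))


@dataclass
class SimDesign:
    """Design of one simulated association dataset.

    ``effect`` names the mean pattern per genotype group; equal patterns
    mean no eQTL.  ``effect_scale`` shrinks the group-1 pattern toward
    the group-0 pattern (1 = full library contrast, 0 = null).
    The AR(1) correlation of the residuals is drawn once per dataset from
    ``N(rho_mean, rho_sd)`` truncated to [0, 0.99].
    """

    n_strains: int = 95
    n_timepoints: int = 6
    rho_mean: float = 0.9
    rho_sd: float = 0.02
    effect: tuple = ("linear_up", "peak")
    effect_scale: float = 1.0
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.n_strains < 2:
            raise ValueError("need at least 2 strains")
        if self.n_timepoints < 4:
            raise ValueError("cubic mean patterns need at least 4 timepoints")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(1, self.n_timepoints + 1, dtype=float)


@dataclass
class CausalPairDesign:
    """Design of a trait pair (X cis, Y trans) for the causality test.

    X always carries the genetic effect and is drawn as an MPTGA-style
    trait (genotype-specific patterns, AR(1) residuals with
    rho ~ N(0.8, 0.1)).  Y is then generated from the lag-one recursion
    of the chosen model:

    * causal      — Y_t = b0 + b1 Y_{t-1} + b2 X_{t-1} + noise
    * independent — Y_t = b0g + b1g Y_{t-1} + noise, per genotype g
    * partial     — independent recursion plus the b2 X_{t-1} term

    Y at t=1 is drawn from the stationary marginal of Y's own recursion
    (with X at its group mean for the causal terms).
    """

    model: str = "causal"  # causal | independent | partial
    n_strains: int = 100
    n_timepoints: int = 6
    x_effect: tuple = ("linear_up", "peak")
    rho_mean: float = 0.8
    rho_sd: float = 0.1
    noise_sd: float = 0.5
    y_noise_sd: float = 0.5
    # Y-equation coefficients; per-genotype values as 2-tuples (group0, group1)
    beta0: tuple[float, float] = (0.0, 0.0)
    beta1: tuple[float, float] = (0.5, 0.5)
    beta2: float = 0.8

    _ALIASES = {"M1": "causal", "M3": "independent", "M4": "partial"}

    def __post_init__(self) -> None:
        self.model = self._ALIASES.get(self.model, self.model)
        if self.model not in ("causal", "independent", "partial"):
            raise ValueError(f"unknown pair model {self.model!r}")
        if max(abs(b) for b in self.beta1) >= 1:
            raise ValueError("|beta1| must be < 1 for a stationary Y recursion")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _draw_rho(rng, mean, sd) -> float:
    return float(np.clip(rng.normal(mean, sd), 0.0, 0.99))


def simulate_trait(design: SimDesign, genotypes: np.ndarray,
                   seed=None, gene_id: str = "trait") -> TimeCourseMatrix:
    """Draw one trait: MVN(pattern mean per genotype, sigma_e^2 * AR1(rho))."""
    rng = _rng(seed)
    g = np.asarray(genotypes, dtype=int)
    if g.shape[0] != design.n_strains:
        raise ValueError("genotype vector length must equal n_strains")
    t = design.times
    mu0 = pattern_curve(design.effect[0], t)
    mu1 = mu0 + design.effect_scale * (pattern_curve(design.effect[1], t) - mu0)
    rho = _draw_rho(rng, design.rho_mean, design.rho_sd)
    cov = design.noise_sd ** 2 * ar1_corr(rho, design.n_timepoints)
    L = np.linalg.cholesky(cov)
    noise = rng.standard_normal((design.n_strains, design.n_timepoints)) @ L.T
    means = np.where(g[:, None] == 0, mu0[None, :], mu1[None, :])
    return TimeCourseMatrix(means + noise, t, gene_id=gene_id)


def simulate_genotypes(n_strains: int, n_markers: int, seed=None,
                       linkage: bool = False, flip_prob: float = 0.05,
                       chrom: str = "chr1", spacing: int = 10_000,
                       prefix: str = "m") -> GenotypeTable:
    """Bernoulli(0.5) marker codes; linkage mode chains neighboring markers.

    In linkage mode marker j+1 copies marker j per strain and flips with
    probability ``flip_prob``, giving adjacent-marker concordance 1 - p.
    """
    if n_strains < 1 or n_markers < 1:
        raise ValueError("counts must be >= 1")
    rng = _rng(seed)
    if not linkage:
        codes = rng.integers(0, 2, size=(n_strains, n_markers))
    else:
        codes = np.empty((n_strains, n_markers), dtype=int)
        codes[:, 0] = rng.integers(0, 2, size=n_strains)
        for j in range(1, n_markers):
            flip = rng.random(n_strains) < flip_prob
            codes[:, j] = np.where(flip, 1 - codes[:, j - 1], codes[:, j - 1])
    markers = [f"{prefix}{j + 1}" for j in range(n_markers)]
    strains = [f"s{i + 1}" for i in range(n_strains)]
    pos = np.arange(n_markers) * spacing + spacing // 2
    return GenotypeTable(codes, strains, markers,
                         chrom=[chrom] * n_markers, pos=pos)


def simulate_pair(design: CausalPairDesign, genotypes: np.ndarray,
                  seed=None) -> tuple[TimeCourseMatrix, TimeCourseMatrix]:
    """Simulate a (X, Y) trait pair under the chosen causal structure."""
    rng = _rng(seed)
    g = np.asarray(genotypes, dtype=int)
    x_design = SimDesign(
        n_strains=design.n_strains, n_timepoints=design.n_timepoints,
        rho_mean=design.rho_mean, rho_sd=design.rho_sd,
        effect=design.x_effect, noise_sd=design.noise_sd)
    X = simulate_trait(x_design, g, seed=rng, gene_id="X")

    m = design.n_timepoints
    b0 = np.asarray(design.beta0)[g]           # per-strain intercept
    b1 = np.asarray(design.beta1)[g]           # per-strain lag coefficient
    if design.model == "causal":
        # shared Y-equation: genetics reaches Y only through X
        b0 = np.full_like(b0, design.beta0[0])
        b1 = np.full_like(b1, design.beta1[0])
    b2 = 0.0 if design.model == "independent" else design.beta2

    Y = np.empty((design.n_strains, m))
    # stationary start: mean and variance of Y's own recursion, with the
    # causal input held at its genotype-group mean at t=1
    x_mean_t1 = np.where(
        g == 0,
        pattern_curve(design.x_effect[0], np.array([1.0]))[0],
        pattern_curve(design.x_effect[1], np.array([1.0]))[0])
    y1_mean = (b0 + b2 * x_mean_t1) / (1 - b1)
    y1_sd = design.y_noise_sd / np.sqrt(1 - b1 ** 2)
    Y[:, 0] = y1_mean + y1_sd * rng.standard_normal(design.n_strains)
    for t in range(1, m):
        Y[:, t] = (b0 + b1 * Y[:, t - 1] + b2 * X.values[:, t - 1]
                   + design.y_noise_sd * rng.standard_normal(design.n_strains))
    return X, TimeCourseMatrix(Y, X.times, gene_id="Y")


def drop_missing(trait: TimeCourseMatrix, rate: float, seed=None) -> TimeCourseMatrix:
    """Mask each cell independently with probability ``rate``.

    Values are preserved under the mask so oracle checks can compare
    imputed against true values.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    if rate > 0.1:
        warnings.warn("missing rate above 0.1 is outside the studied range",
                      stacklevel=2)
    out = trait.copy()
    if rate == 0:
        return out
    rng = _rng(seed)
    new_mask = rng.random(out.values.shape) < rate
    out.mask = new_mask if out.mask is None else (out.mask | new_mask)
    return out


def simulate_scan_dataset(n_strains: int = 95, n_genes: int = 50,
                          n_markers: int = 20, frac_linked: float = 0.5,
                          design: SimDesign | None = None, seed=None,
                          linkage: bool = False, flip_prob: float = 0.05,
                          ) -> tuple[ExpressionSet, GenotypeTable, dict]:
    """A whole scan input: genotypes plus traits, a fraction with a real eQTL.

    Linked genes get a marker assigned round-robin and genotype-specific
    patterns drawn from the library; unlinked genes use one shared pattern.
    Returns the expression set, the genotype table and a truth dict
    (gene -> linked marker or None, plus generating patterns).
    """
    rng = _rng(seed)
    base = design or SimDesign(n_strains=n_strains)
    geno = simulate_genotypes(n_strains, n_markers, seed=rng,
                              linkage=linkage, flip_prob=flip_prob)
    names = list(PATTERNS)
    values = np.empty((n_strains, n_genes, base.n_timepoints))
    genes, truth = [], {}
    for j in range(n_genes):
        gene = f"g{j + 1}"
        genes.append(gene)
        linked = rng.random() < frac_linked
        if linked:
            marker = int(rng.integers(n_markers))
            pat = tuple(rng.choice(names, size=2, replace=False))
            d = replace(base, n_strains=n_strains, effect=pat)
            trait = simulate_trait(d, geno.codes[:, marker], seed=rng, gene_id=gene)
            truth[gene] = {"marker": geno.markers[marker], "patterns": pat}
        else:
            pat = str(rng.choice(names))
            d = replace(base, n_strains=n_strains, effect=(pat, pat))
            trait = simulate_trait(d, geno.codes[:, 0], seed=rng, gene_id=gene)
            truth[gene] = {"marker": None, "patterns": (pat, pat)}
        values[:, j, :] = trait.values
    expr = ExpressionSet(values, geno.strains, genes, base.times)
    return expr, geno, truth
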