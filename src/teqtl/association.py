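"""Temporal-genetic association tests.

Seven tests of whether a genotype split alters an expression trajectory:

* ``static``  — Wilcoxon rank-sum at a single timepoint (classic eQTL).
* ``union``   — minimum of the per-timepoint Wilcoxon p-values.
* ``fisher``  — product of the per-timepoint Wilcoxon p-values (a ranking
  score; calibrate by permutation, not against a chi-square).
* ``manova``  — one-way MANOVA on the m-dimensional trajectory (Pillai).
* ``regression`` — stacked cubic-in-time OLS, F-test of a pooled curve
  against per-genotype curves.
* ``ar``      — lag-one autoregression, F-test of pooled against
  per-genotype AR parameters.
* ``mptga``   — the profile-likelihood LR test (see :mod:`teqtl.mptga`).

`run_test` dispatches by name; `handle_missing` implements the two
missing-data policies (curve-based imputation for the model-based
methods, strain masking for the others).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .data import AssociationRecord, GenotypeSplit, TimeCourseMatrix
from .mptga import DEGREE, fit_mptga, mptga_test

__all__ = [
    "static_test", "union_test", "fisher_test", "manova_test",
    "regression_test", "ar_test", "run_test", "handle_missing", "METHODS",
]

#: group size above which the rank-sum test switches to the tie-corrected
#: normal approximation
EXACT_WILCOXON_MAX_N = 25


def _group_values(trait: TimeCourseMatrix, split: GenotypeSplit, t: int):
    """Unmasked values per group at timepoint index t."""
    out = []
    for idx in split.groups:
        v = trait.values[idx, t]
        if trait.mask is not None:
            v = v[~trait.mask[idx, t]]
        out.append(v)
    return out


def _wilcoxon(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty genotype group at the tested timepoint")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = ("exact" if not ties and max(len(a), len(b)) <= EXACT_WILCOXON_MAX_N
              else "asymptotic")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def static_test(trait: TimeCourseMatrix, split: GenotypeSplit,
                timepoint: int = 0) -> AssociationRecord:
    """Wilcoxon rank-sum on the expression at one timepoint (default first)."""
    if split.n_groups != 2:
        raise ValueError("rank-sum static test is defined for 2 genotype groups")
    a, b = _group_values(trait, split, timepoint)
    stat, p = _wilcoxon(a, b)
    return AssociationRecord(trait.gene_id, "", "static", stat, p,
                             extra={"timepoint": timepoint})


def _per_timepoint_p(trait: TimeCourseMatrix, split: GenotypeSplit) -> np.ndarray:
    ps = np.full(trait.n_times, np.nan)
    for t in range(trait.n_times):
        groups = _group_values(trait, split, t)
        if any(len(v) == 0 for v in groups):
            continue  # timepoint entirely missing in a group: excluded
        try:
            ps[t] = _wilcoxon(groups[0], groups[1])[1]
        except ValueError:
            continue
    if np.isnan(ps).all():
        raise ValueError("all timepoints degenerate")
    return ps


def union_test(trait: TimeCourseMatrix, split: GenotypeSplit) -> AssociationRecord:
    """Best single-timepoint association: p = min_t p_t."""
    ps = _per_timepoint_p(trait, split)
    p = float(np.nanmin(ps))
    return AssociationRecord(trait.gene_id, "", "union", -np.log10(max(p, 1e-300)),
                             p, per_timepoint_p=ps)


def fisher_test(trait: TimeCourseMatrix, split: GenotypeSplit) -> AssociationRecord:
    """Product of per-timepoint p-values.

    The product is reported verbatim in the ``p_value`` slot as a ranking
    score; it is not a calibrated tail probability.
    """
    ps = _per_timepoint_p(trait, split)
    score = float(np.nanprod(ps))
    return AssociationRecord(trait.gene_id, "", "fisher",
                             -np.log10(max(score, 1e-300)), score,
                             per_timepoint_p=ps)


def manova_test(trait: TimeCourseMatrix, split: GenotypeSplit) -> AssociationRecord:
    """One-way MANOVA of the m-dimensional trajectory on genotype.

    Pillai's trace with the standard F approximation (exact for two
    groups, where all four classical statistics coincide).  Strains with
    any masked timepoint are dropped.
    """
    keep = trait.complete_rows()
    groups = [trait.values[idx[keep[idx]]] for idx in split.groups]
    gsizes = [len(x) for x in groups]
    if any(s < 2 for s in gsizes):
        raise ValueError("a genotype group has < 2 complete strains")
    n, p, g = sum(gsizes), trait.n_times, len(groups)
    if n <= p + g:
        raise ValueError("too few strains for a nonsingular MANOVA")
    grand = np.concatenate(groups).mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for x in groups:
        d = x.mean(axis=0) - grand
        H += len(x) * np.outer(d, d)
        c = x - x.mean(axis=0)
        E += c.T @ c
    V = float(np.trace(np.linalg.solve(E + H, H)))  # Pillai's trace
    s = min(p, g - 1)
    mm = (abs(p - (g - 1)) - 1) / 2
    nn = (n - g - p - 1) / 2
    df1 = s * (2 * mm + s + 1)
    df2 = s * (2 * nn + s + 1)
    F = (df2 / df1) * V / (s - V)
    pval = float(stats.f.sf(F, df1, df2))
    return AssociationRecord(trait.gene_id, "", "manova", F, pval,
                             extra={"pillai": V, "df1": df1, "df2": df2})


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def _nested_f(rss0: float, rss1: float, df_diff: int, df_resid: int):
    rss1 = max(rss1, 1e-300)
    F = ((rss0 - rss1) / df_diff) / (rss1 / df_resid)
    F = max(F, 0.0)
    return F, float(stats.f.sf(F, df_diff, df_resid))


def regression_test(trait: TimeCourseMatrix, split: GenotypeSplit) -> AssociationRecord:
    """Stacked cubic regression: pooled curve vs per-genotype curves.

    Each strain contributes m observations; the F statistic compares the
    4-parameter shared cubic against 4 parameters per genotype group.
    """
    if trait.has_missing:
        raise ValueError("regression test requires complete data; impute first")
    lab = split.indicator(trait.n_strains)
    if (lab < 0).any():
        raise ValueError("split does not cover all strains")
    t = trait.times
    P = np.vander(t, DEGREE + 1, increasing=True)  # (m, 4)
    N, m = trait.values.shape
    y = trait.values.ravel()
    X0 = np.tile(P, (N, 1))
    G = split.n_groups
    X1 = np.zeros((N * m, (DEGREE + 1) * G))
    for i in range(N):
        g = lab[i]
        X1[i * m:(i + 1) * m, g * (DEGREE + 1):(g + 1) * (DEGREE + 1)] = P
    rss0 = _ols_rss(X0, y)
    rss1 = _ols_rss(X1, y)
    df_diff = (DEGREE + 1) * (G - 1)
    df_resid = N * m - (DEGREE + 1) * G
    F, p = _nested_f(rss0, rss1, df_diff, df_resid)
    return AssociationRecord(trait.gene_id, "", "regression", F, p,
                             extra={"rss0": rss0, "rss1": rss1})


def ar_test(trait: TimeCourseMatrix, split: GenotypeSplit) -> AssociationRecord:
    """Lag-one autoregression: pooled vs per-genotype AR parameters.

    Stacks the m-1 lag equations per strain and F-tests the 2-parameter
    pooled recursion against 2 parameters per genotype group.
    """
    if trait.has_missing:
        raise ValueError("AR test requires complete data; impute first")
    lab = split.indicator(trait.n_strains)
    if (lab < 0).any():
        raise ValueError("split does not cover all strains")
    N, m = trait.values.shape
    if m < 2:
        raise ValueError("AR test needs at least 2 timepoints")
    y = trait.values[:, 1:].ravel()
    ylag = trait.values[:, :-1].ravel()
    rows = N * (m - 1)
    X0 = np.column_stack([np.ones(rows), ylag])
    G = split.n_groups
    X1 = np.zeros((rows, 2 * G))
    glab = np.repeat(lab, m - 1)
    for g in range(G):
        sel = glab == g
        X1[sel, 2 * g] = 1.0
        X1[sel, 2 * g + 1] = ylag[sel]
    rss0 = _ols_rss(X0, y)
    rss1 = _ols_rss(X1, y)
    F, p = _nested_f(rss0, rss1, 2 * (G - 1), rows - 2 * G)
    return AssociationRecord(trait.gene_id, "", "ar", F, p,
                             extra={"rss0": rss0, "rss1": rss1})


METHODS = {
    "static": static_test,
    "union": union_test,
    "fisher": fisher_test,
    "manova": manova_test,
    "regression": regression_test,
    "ar": ar_test,
    "mptga": mptga_test,
}

#: methods that fit a curve per genotype and therefore impute missing cells
IMPUTING_METHODS = ("mptga", "regression", "ar")


def handle_missing(trait: TimeCourseMatrix, split: GenotypeSplit,
                   method: str) -> TimeCourseMatrix:
    """Prepare a trait with missing cells for one association method.

    For the curve-fitting methods (MPTGA, regression, AR) the per-genotype
    model is fitted on complete strains only and missing cells are filled
    from the fit.  For the remaining methods, strains with any missing
    timepoint are masked out entirely and the tests run on the complete
    strains.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if not trait.has_missing:
        return trait
    if method not in IMPUTING_METHODS:
        out = trait.copy()
        incomplete = ~trait.complete_rows()
        out.mask = out.mask.copy()
        out.mask[incomplete, :] = True
        return out
    out = trait.copy()
    complete = trait.complete_rows()
    lab = split.indicator(trait.n_strains)
    t = trait.times
    for g, idx in enumerate(split.groups):
        fit_rows = idx[complete[idx]]
        if len(fit_rows) == 0:
            raise ValueError(f"no complete strains in genotype group {g}")
        rows = idx[~complete[idx]]
        if method == "ar":
            _ar_impute(trait, out, fit_rows, rows)
        else:
            P = np.vander(t, DEGREE + 1, increasing=True)
            coef, _, _, _ = np.linalg.lstsq(
                np.tile(P, (len(fit_rows), 1)),
                trait.values[fit_rows].ravel(), rcond=None)
            curve = P @ coef
            for i in rows:
                miss = trait.mask[i]
                out.values[i, miss] = curve[miss]
    out.mask = None
    return out


def _ar_impute(trait: TimeCourseMatrix, out: TimeCourseMatrix,
               fit_rows: np.ndarray, rows: np.ndarray) -> None:
    """Fill missing cells from the group-fitted lag-one recursion.

    The AR coefficients come from the complete strains of the genotype
    group; each missing cell is then predicted from the strain's own
    previous (observed or already imputed) value, so imputation chains
    forward in time.  A missing first timepoint falls back to the group
    mean at t=1.
    """
    Y = trait.values[fit_rows]
    y, ylag = Y[:, 1:].ravel(), Y[:, :-1].ravel()
    X = np.column_stack([np.ones_like(ylag), ylag])
    (b0, b1), _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    t1_mean = Y[:, 0].mean()
    for i in rows:
        for t in range(trait.n_times):
            if not trait.mask[i, t]:
                continue
            out.values[i, t] = (t1_mean if t == 0
                                else b0 + b1 * out.values[i, t - 1])
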