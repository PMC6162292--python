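"""Genome-scale utilities around an association scan.

Covers the full post-scan workflow: running a scan of every trait against
every marker, permutation-based FDR calibration, hotspot detection with a
Bonferroni-adjusted binomial threshold, chi-square-quantile confidence
intervals for eQTL location, QQ-based validity checks, the neighboring-SNP
overfitting assessment, and hypergeometric gene-set enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import METHODS, handle_missing
from .data import ExpressionSet, GenotypeSplit, GenotypeTable, ScanResult
from .mptga import fit_mptga

__all__ = [
    "scan", "permutation_fdr", "FDRResult", "detect_hotspots", "HotspotCall",
    "estimate_ci", "CIResult", "qq_validate", "overfit_check",
    "enrichment_test",
]


def scan(expression: ExpressionSet, genotypes: GenotypeTable,
         method: str = "mptga") -> ScanResult:
    """Test every (gene, marker) pair with one association method.

    Missing cells are handled per method (imputation for the curve-based
    methods, masking otherwise).  Rows are ordered gene-major,
    marker-minor.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    test = METHODS[method]
    rows = []
    for trait in expression:
        for j, marker in enumerate(genotypes.markers):
            split = GenotypeSplit.from_genotypes(genotypes.codes[:, j])
            prepared = handle_missing(trait, split, method)
            rec = test(prepared, split)
            rows.append((trait.gene_id, marker, rec.statistic, rec.p_value,
                         method))
    records = pd.DataFrame(rows, columns=["gene", "marker", "statistic",
                                          "p_value", "method"])
    return ScanResult(records, marker_map=genotypes.marker_map())


@dataclass
class FDRResult:
    """Permutation FDR curve and the cutoff achieving a target FDR."""

    table: pd.DataFrame  # p_cutoff, n_real, mean_n_perm, fdr_raw, fdr
    p_cutoff: float | None
    target: float
    n_perm: int


def permutation_fdr(expression: ExpressionSet, genotypes: GenotypeTable,
                    method: str = "mptga", n_perm: int = 10,
                    target: float = 0.05, seed=None,
                    real_scan: ScanResult | None = None) -> FDRResult:
    """Estimate FDR by permuting strain labels of the genotype data.

    Expression is left untouched (preserving each trait's temporal
    correlation); only the strain labels of the genotype matrix are
    shuffled, which destroys genuine associations while keeping marker LD
    intact.  FDR(p) = (average permuted hits < p) / (real hits < p); the
    curve is made monotone by a cumulative-minimum sweep from small to
    large p before the cutoff lookup.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if real_scan is None:
        real_scan = scan(expression, genotypes, method)
    real_p = np.sort(real_scan.records["p_value"].to_numpy())
    if real_p.size == 0:
        raise ValueError("empty scan")
    perm_p = []
    for _ in range(n_perm):
        order = rng.permutation(genotypes.n_strains)
        perm_geno = GenotypeTable(genotypes.codes[order], genotypes.strains,
                                  genotypes.markers, genotypes.chrom,
                                  genotypes.pos, genotypes.ploidy)
        perm_p.append(scan(expression, perm_geno, method)
                      .records["p_value"].to_numpy())
    perm_p = np.sort(np.concatenate(perm_p))

    cutoffs = real_p
    n_real = np.arange(1, len(real_p) + 1, dtype=float)  # hits <= each real p
    mean_perm = np.searchsorted(perm_p, cutoffs, side="right") / n_perm
    fdr_raw = mean_perm / n_real
    fdr = np.minimum.accumulate(fdr_raw[::-1])[::-1]  # monotone non-decreasing in p
    table = pd.DataFrame({"p_cutoff": cutoffs, "n_real": n_real,
                          "mean_n_perm": mean_perm, "fdr_raw": fdr_raw,
                          "fdr": fdr})
    ok = np.flatnonzero(fdr <= target)
    p_cut = float(cutoffs[ok[-1]]) if ok.size else None
    return FDRResult(table, p_cut, target, n_perm)


@dataclass
class HotspotCall:
    chrom: str
    start: int
    end: int
    count: int
    threshold: int
    merged: bool


def hotspot_threshold(n_total: int, n_bins: int, alpha: float = 0.05) -> int:
    """Smallest N0 with P(Binom(n_total, 1/n_bins) >= N0) < alpha / n_bins."""
    k = np.arange(0, n_total + 2)
    tail = stats.binom.sf(k - 1, n_total, 1.0 / n_bins)
    return int(k[np.argmax(tail < alpha / n_bins)])


def detect_hotspots(scan_result: ScanResult, p_cutoff: float,
                    bin_size: int = 20_000, alpha: float = 0.05,
                    n_bins_override: int | None = None,
                    peak_per_gene: bool = True) -> list[HotspotCall]:
    """Find genomic bins with more linkages than a uniform binomial allows.

    Each significant trait contributes its peak marker per chromosome (or
    every significant marker with ``peak_per_gene=False``).  The genome is
    cut into ``bin_size`` bins; a bin is a hotspot when its linkage count
    reaches the Bonferroni-adjusted binomial threshold N0, and adjacent
    significant bins are merged.
    """
    if scan_result.marker_map is None:
        raise ValueError("hotspot detection needs a marker map")
    if peak_per_gene:
        hits = scan_result.peak_per_gene_chrom(p_cutoff)
    else:
        hits = scan_result.significant(p_cutoff).merge(
            scan_result.marker_map, on="marker")
    if hits.empty:
        return []
    hits = hits.assign(bin=hits["pos"] // bin_size)
    counts = hits.groupby(["chrom", "bin"]).size()

    if n_bins_override is not None:
        n_bins = n_bins_override
    else:
        span = scan_result.marker_map.groupby("chrom")["pos"].max()
        n_bins = int((span // bin_size + 1).sum())
    n_total = len(hits)
    n0 = hotspot_threshold(n_total, n_bins, alpha)

    sig = counts[counts >= n0]
    hotspots: list[HotspotCall] = []
    for chrom in sorted({c for c, _ in sig.index}):
        bins = sorted(b for c, b in sig.index if c == chrom)
        run = [bins[0]]
        for b in bins[1:]:
            if b == run[-1] + 1:
                run.append(b)
            else:
                hotspots.append(_merge_bins(chrom, run, counts, bin_size, n0))
                run = [b]
        hotspots.append(_merge_bins(chrom, run, counts, bin_size, n0))
    return hotspots


def _merge_bins(chrom, run, counts, bin_size, n0) -> HotspotCall:
    total = int(sum(counts[(chrom, b)] for b in run))
    return HotspotCall(chrom, int(run[0] * bin_size),
                       int((run[-1] + 1) * bin_size), total, n0,
                       merged=len(run) > 1)


@dataclass
class CIResult:
    """Chi-square-quantile confidence interval for an eQTL location."""

    peak_pos: int
    ci_low: int
    ci_high: int
    profile: pd.DataFrame  # marker, pos, R, T
    alpha: float
    df: int


def estimate_ci(trait, genotypes: GenotypeTable, alpha: float = 0.05,
                df: int = 1) -> CIResult:
    """Confidence interval for eQTL position along one chromosome.

    R(d) = 2 * [loglik(eQTL at d) - loglik(no eQTL)] profiles the MPTGA
    likelihood over marker positions d; T(d0) = sup_d R(d) - R(d0) is
    referred to a chi-square with ``df`` degrees of freedom, and the
    (1 - alpha) interval collects all positions whose T stays below the
    upper-alpha quantile.
    """
    if genotypes.n_markers < 3:
        raise ValueError("need at least 3 markers on the chromosome")
    null_ll = fit_mptga(trait, None).loglik
    R = np.empty(genotypes.n_markers)
    for j in range(genotypes.n_markers):
        split = GenotypeSplit.from_genotypes(genotypes.codes[:, j])
        R[j] = 2.0 * (fit_mptga(trait, split).loglik - null_ll)
    if np.ptp(R) <= 0:
        raise ValueError("flat likelihood-ratio profile: no peak")
    T = R.max() - R
    thresh = stats.chi2.ppf(1 - alpha, df)
    inside = T < thresh
    pos = genotypes.pos if genotypes.pos is not None else np.arange(len(R))
    profile = pd.DataFrame({"marker": genotypes.markers, "pos": pos,
                            "R": R, "T": T})
    peak = int(pos[np.argmax(R)])
    return CIResult(peak, int(pos[inside].min()), int(pos[inside].max()),
                    profile, alpha, df)


def qq_validate(p_values: np.ndarray) -> dict:
    """QQ points (expected vs observed -log10 p) and an inflation summary.

    The inflation factor is the genomic-control-style ratio of the median
    observed 1-df chi-square equivalent to its null median (0.4549).
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    n = p.size
    if n == 0:
        raise ValueError("no p-values")
    expected = (np.arange(1, n + 1) - 0.5) / n
    chisq = stats.chi2.isf(np.clip(p, 1e-300, 1), 1)
    lam = float(np.median(chisq) / stats.chi2.ppf(0.5, 1))
    return {"expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(np.clip(p, 1e-300, 1)),
            "inflation": lam}


def overfit_check(scan_result: ScanResult, genotypes: GenotypeTable,
                  p_cutoff: float, ld_threshold: float = 0.9,
                  window: int = 2) -> dict:
    """Peak-vs-neighbor association consistency under strong LD.

    For each significant (gene, peak marker), flanking markers within
    ``window`` positions whose genotype concordance with the peak is at
    least ``ld_threshold`` contribute a (-log10 p_peak, -log10 p_neighbor)
    pair; the Pearson correlation of those pairs measures how well the
    fitted association generalizes to nearly identical genotypes (low
    correlation indicates overfitting to noise).
    """
    peaks = scan_result.peak_per_gene_chrom(p_cutoff)
    if peaks.empty:
        raise ValueError("no significant associations to assess")
    pmat = scan_result.records.pivot(index="gene", columns="marker",
                                     values="p_value")
    marker_idx = {m: j for j, m in enumerate(genotypes.markers)}
    xs, ys = [], []
    for _, row in peaks.iterrows():
        j = marker_idx[row["marker"]]
        peak_codes = genotypes.codes[:, j]
        for k in range(max(0, j - window), min(genotypes.n_markers, j + window + 1)):
            if k == j:
                continue
            concordance = float(np.mean(genotypes.codes[:, k] == peak_codes))
            if max(concordance, 1 - concordance) < ld_threshold:
                continue
            p_nb = pmat.loc[row["gene"], genotypes.markers[k]]
            xs.append(-np.log10(max(row["p_value"], 1e-300)))
            ys.append(-np.log10(max(p_nb, 1e-300)))
    if len(xs) < 2:
        raise ValueError("no LD neighbors found for the significant peaks")
    r = float(np.corrcoef(xs, ys)[0, 1])
    return {"correlation": r, "n_pairs": len(xs),
            "peak_neglog10": np.array(xs), "neighbor_neglog10": np.array(ys)}


def enrichment_test(hit_set, signature, universe) -> dict:
    """One-sided hypergeometric enrichment of a hit set in a signature.

    Returns the tail p-value for observing at least the overlap, and the
    fold enrichment observed / expected.
    """
    hits = set(hit_set) & set(universe)
    sig = set(signature) & set(universe)
    if not sig:
        raise ValueError("empty signature")
    M, n, N = len(set(universe)), len(sig), len(hits)
    k = len(hits & sig)
    p = float(stats.hypergeom.sf(k - 1, M, n, N))
    expected = N * n / M
    fold = k / expected if expected > 0 else np.nan
    return {"overlap": k, "expected": expected, "fold": fold, "p_value": p}
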