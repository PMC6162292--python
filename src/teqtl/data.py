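"""Core in-memory containers shared by every stage of a temporal eQTL analysis.

The central object is the :class:`TimeCourseMatrix` — one expression trait
measured for ``N`` strains at ``m`` ordered timepoints — together with a
:class:`GenotypeTable` holding marker codes and genomic coordinates, and a
:class:`GenotypeSplit` that partitions strains by their allele at one marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeCourseMatrix",
    "ExpressionSet",
    "GenotypeTable",
    "GenotypeSplit",
    "AssociationRecord",
    "ScanResult",
]


@dataclass
class TimeCourseMatrix:
    """Expression of a single gene: strains x timepoints, with optional mask.

    Parameters
    ----------
    values : (N, m) float array
        Expression levels; entries under ``mask`` are present but flagged
        missing (they are never silently treated as zero).
    times : (m,) array
        The time grid, by convention the integers ``1..m``.
    gene_id : str
        Trait identifier.
    mask : (N, m) bool array or None
        ``True`` marks a missing cell.
    """

    values: np.ndarray
    times: np.ndarray | None = None
    gene_id: str = "trait"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D strains x timepoints array")
        if self.times is None:
            self.times = np.arange(1, self.values.shape[1] + 1, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape[0] != self.values.shape[1]:
            raise ValueError("times length must match the number of columns")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values")

    @property
    def n_strains(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return self.mask is not None and bool(self.mask.any())

    def complete_rows(self) -> np.ndarray:
        """Boolean selector of strains with no missing timepoint."""
        if self.mask is None:
            return np.ones(self.n_strains, dtype=bool)
        return ~self.mask.any(axis=1)

    def copy(self) -> "TimeCourseMatrix":
        return TimeCourseMatrix(
            self.values.copy(),
            self.times.copy(),
            self.gene_id,
            None if self.mask is None else self.mask.copy(),
        )


@dataclass
class ExpressionSet:
    """A collection of traits on a common strain panel and time grid."""

    values: np.ndarray  # (N strains, G genes, m timepoints)
    strains: list[str]
    genes: list[str]
    times: np.ndarray
    mask: np.ndarray | None = None  # same shape as values

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        n, g, m = self.values.shape
        if len(self.strains) != n or len(self.genes) != g or len(self.times) != m:
            raise ValueError("axis labels inconsistent with values shape")

    @property
    def n_strains(self) -> int:
        return self.values.shape[0]

    def trait(self, gene: str | int) -> TimeCourseMatrix:
        j = gene if isinstance(gene, int) else self.genes.index(gene)
        mask = None if self.mask is None else self.mask[:, j, :]
        return TimeCourseMatrix(self.values[:, j, :], self.times,
                                gene_id=self.genes[j], mask=mask)

    def __iter__(self):
        for j in range(len(self.genes)):
            yield self.trait(j)


@dataclass
class GenotypeTable:
    """Strains x markers allele codes plus marker genomic coordinates.

    Codes are 0/1 for a haploid cross, 0/1/2 for diploids.
    """

    codes: np.ndarray  # (N, M) int
    strains: list[str]
    markers: list[str]
    chrom: Sequence[str] | None = None
    pos: np.ndarray | None = None
    ploidy: int = 1

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        allowed = {0, 1} if self.ploidy == 1 else {0, 1, 2}
        observed = set(np.unique(self.codes).tolist())
        if not observed <= allowed:
            raise ValueError(
                f"genotype codes {sorted(observed - allowed)} invalid for "
                f"ploidy {self.ploidy}")
        if self.pos is not None:
            self.pos = np.asarray(self.pos, dtype=int)

    @property
    def n_strains(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def marker_codes(self, marker: str | int) -> np.ndarray:
        j = marker if isinstance(marker, int) else self.markers.index(marker)
        return self.codes[:, j]

    def marker_map(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker": self.markers,
            "chrom": list(self.chrom) if self.chrom is not None else "chr1",
            "pos": self.pos if self.pos is not None else np.arange(self.n_markers),
        })


class GenotypeSplit:
    """Partition of strains into genotype groups at one marker."""

    def __init__(self, groups: Sequence[np.ndarray]):
        self.groups = [np.asarray(g, dtype=int) for g in groups]
        sizes = [len(g) for g in self.groups]
        if any(s < 2 for s in sizes):
            raise ValueError(f"every genotype group needs >= 2 strains, got {sizes}")
        all_idx = np.concatenate(self.groups)
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("groups must be disjoint")
        self.sizes = sizes

    @classmethod
    def from_genotypes(cls, genotypes: np.ndarray) -> "GenotypeSplit":
        g = np.asarray(genotypes, dtype=int)
        levels = np.unique(g)
        return cls([np.flatnonzero(g == lv) for lv in levels])

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def indicator(self, n_strains: int) -> np.ndarray:
        """Group label per strain (-1 for strains in no group)."""
        lab = np.full(n_strains, -1, dtype=int)
        for k, idx in enumerate(self.groups):
            lab[idx] = k
        return lab


@dataclass
class AssociationRecord:
    """One (gene, marker) association result from any method."""

    gene_id: str
    marker_id: str
    method: str
    statistic: float
    p_value: float
    per_timepoint_p: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class ScanResult:
    """All (gene, marker) association records from one genome scan."""

    records: pd.DataFrame  # columns: gene, marker, statistic, p_value, method
    marker_map: pd.DataFrame | None = None  # marker, chrom, pos

    REQUIRED = ("gene", "marker", "statistic", "p_value", "method")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"scan records missing columns {missing}")

    def significant(self, p_cutoff: float) -> pd.DataFrame:
        return self.records[self.records["p_value"] < p_cutoff]

    def peak_per_gene_chrom(self, p_cutoff: float) -> pd.DataFrame:
        """One row per (gene, chromosome): the marker with the smallest p.

        Requires a marker map. This is the counting convention used for
        hotspot detection — each trait contributes at most one linkage
        per chromosome.
        """
        if self.marker_map is None:
            raise ValueError("marker map required for peak extraction")
        sig = self.significant(p_cutoff).merge(self.marker_map, on="marker")
        if sig.empty:
            return sig
        idx = sig.groupby(["gene", "chrom"], sort=True)["p_value"].idxmin()
        return sig.loc[idx].reset_index(drop=True)
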