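"""Readers and writers for the plain-text matrix formats.

Everything is tab-delimited UTF-8 with '.' decimals: expression matrices
(wide ``gene@timepoint`` columns or long format), genotype matrices,
marker maps, and BED hotspot output.  Missing expression cells are
encoded ``NA`` and come back masked, never as zeros.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionSet, GenotypeTable

__all__ = [
    "read_expression", "write_expression", "read_genotypes",
    "write_genotypes", "write_hotspots_bed", "RunConfig",
]


def write_expression(expr: ExpressionSet, path) -> None:
    cols = {}
    n, g, m = expr.values.shape
    for j, gene in enumerate(expr.genes):
        for t in range(m):
            col = expr.values[:, j, t].astype(object)
            if expr.mask is not None:
                col = col.copy()
                col[expr.mask[:, j, t]] = np.nan
            cols[f"{gene}@{int(expr.times[t])}"] = col
    df = pd.DataFrame(cols, index=pd.Index(expr.strains, name="strain"))
    df.to_csv(path, sep="\t", na_rep="NA")


def read_expression(path) -> ExpressionSet:
    """Read a wide (``gene@timepoint`` columns) or long expression TSV."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    long_cols = {"strain", "gene", "time", "value"}
    if long_cols <= set(df.columns):
        if df.duplicated(["strain", "gene", "time"]).any():
            raise ValueError("duplicate (strain, gene, time) entries")
        wide = df.pivot(index="strain", columns=["gene", "time"],
                        values="value")
        strains = [str(s) for s in wide.index]
        genes = sorted({g for g, _ in wide.columns})
        times = np.array(sorted({t for _, t in wide.columns}), dtype=float)
        values = np.empty((len(strains), len(genes), len(times)))
        for jg, g in enumerate(genes):
            for jt, t in enumerate(times):
                values[:, jg, jt] = wide[(g, t)].to_numpy()
    else:
        df = df.set_index(df.columns[0])
        strains = [str(s) for s in df.index]
        parsed = []
        for c in df.columns:
            gene, _, t = c.rpartition("@")
            if not gene:
                raise ValueError(f"column {c!r} is not gene@timepoint")
            parsed.append((gene, float(t)))
        genes = sorted({g for g, _ in parsed}, key=[g for g, _ in parsed].index)
        times = np.array(sorted({t for _, t in parsed}), dtype=float)
        values = np.full((len(strains), len(genes), len(times)), np.nan)
        gi = {g: j for j, g in enumerate(genes)}
        ti = {t: j for j, t in enumerate(times)}
        for c, (g, t) in zip(df.columns, parsed):
            col = pd.to_numeric(df[c], errors="raise").to_numpy()
            values[:, gi[g], ti[t]] = col
    mask = np.isnan(values)
    return ExpressionSet(np.nan_to_num(values), strains, genes, times,
                         mask=mask if mask.any() else None)


def write_genotypes(geno: GenotypeTable, path, map_path=None) -> None:
    df = pd.DataFrame(geno.codes, index=pd.Index(geno.strains, name="strain"),
                      columns=geno.markers)
    df.to_csv(path, sep="\t")
    if map_path is not None:
        geno.marker_map().to_csv(map_path, sep="\t", index=False)


def read_genotypes(path, map_path=None, ploidy: int = 1) -> GenotypeTable:
    """Read a genotype TSV (codes 0/1, or 0/1/2 in diploid mode) plus map.

    Markers are returned sorted by (chrom, pos), stable for ties.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    codes = df.to_numpy()
    if not np.issubdtype(codes.dtype, np.integer):
        raise ValueError("genotype codes must be integers")
    markers = list(df.columns)
    chrom, pos = None, None
    if map_path is not None:
        mm = pd.read_csv(map_path, sep="\t")
        missing = set(markers) - set(mm["marker"])
        if missing:
            raise ValueError(f"markers missing from the map: {sorted(missing)}")
        mm = mm.set_index("marker").loc[markers].reset_index()
        order = mm.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
        codes = codes[:, order]
        markers = [markers[j] for j in order]
        mm = mm.iloc[order]
        chrom = mm["chrom"].tolist()
        pos = mm["pos"].to_numpy()
    return GenotypeTable(codes, [str(s) for s in df.index], markers,
                         chrom=chrom, pos=pos, ploidy=ploidy)


def write_hotspots_bed(hotspots, path) -> None:
    with open(path, "w") as fh:
        for h in hotspots:
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\t{h.count}\t{h.threshold}\n")


@dataclass
class RunConfig:
    """Everything one reproducible end-to-end run needs.

    All stage seeds are derived deterministically from ``seed``; no stage
    reads ambient entropy.
    """

    expression: str = ""
    genotypes: str = ""
    marker_map: str | None = None
    gene_map: str | None = None
    out_dir: str = "teqtl_out"
    method: str = "mptga"
    fdr_target: float = 0.05
    n_perm: int = 10
    seed: int = 0
    bin_size: int = 20_000
    hotspot_alpha: float = 0.05
    filter_p: float = 1e-6
    cis_window: int = 50_000
    count_partial: bool = False

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2**31."""
        h = np.uint32(self.seed)
        for ch in stage:
            h = np.uint32(h * np.uint32(31) + np.uint32(ord(ch)))
        return int(h % np.uint32(2 ** 31 - 1))
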