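"""End-to-end run: scan -> FDR -> hotspots -> cis/trans pairing -> causality.

Each stage writes its artifact under the configured output directory and
logs one structured line (stage, counts in/out, cutoff, wall time).  A
rerun with the same config and seed is bit-identical for every
deterministic stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from .causality import rank_regulators, select_cis_trans_model
from .data import ExpressionSet, GenotypeSplit, GenotypeTable
from .io import (RunConfig, read_expression, read_genotypes,
                 write_hotspots_bed)
from .scan import detect_hotspots, permutation_fdr, scan

log = logging.getLogger("teqtl")

__all__ = ["run_pipeline"]


def _stage(name: str, t0: float, **info) -> None:
    fields = " ".join(f"{k}={v}" for k, v in info.items())
    log.info("stage=%s elapsed=%.2fs %s", name, time.time() - t0, fields)


def _config_hash(config: RunConfig) -> str:
    # output location does not affect results and is excluded from the stamp
    fields = {k: v for k, v in config.__dict__.items() if k != "out_dir"}
    return hashlib.sha256(
        json.dumps(fields, sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig,
                 expression: ExpressionSet | None = None,
                 genotypes: GenotypeTable | None = None) -> dict:
    """Execute the whole analysis described by ``config``.

    Inputs may be passed in memory or read from the configured paths.
    Returns a dict of in-memory results; artifacts land in
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if expression is None:
        if not Path(config.expression).exists():
            raise FileNotFoundError(f"expression input {config.expression!r}")
        expression = read_expression(config.expression)
    if genotypes is None:
        if not Path(config.genotypes).exists():
            raise FileNotFoundError(f"genotype input {config.genotypes!r}")
        genotypes = read_genotypes(config.genotypes, config.marker_map)
    stamp = {"config_hash": _config_hash(config), "seed": config.seed}
    config.to_json(out / "config.json")

    t0 = time.time()
    scan_result = scan(expression, genotypes, config.method)
    scan_result.records.assign(**stamp).to_csv(out / "scan.tsv", sep="\t",
                                               index=False)
    _stage("scan", t0, genes=len(expression.genes),
           markers=genotypes.n_markers, method=config.method)

    t0 = time.time()
    fdr = permutation_fdr(expression, genotypes, config.method,
                          n_perm=config.n_perm, target=config.fdr_target,
                          seed=config.stage_seed("fdr"),
                          real_scan=scan_result)
    fdr.table.to_csv(out / "fdr.tsv", sep="\t", index=False)
    if fdr.p_cutoff is None:
        raise RuntimeError("fdr stage: no p-value cutoff achieves the target FDR")
    _stage("fdr", t0, n_perm=config.n_perm, cutoff=f"{fdr.p_cutoff:.3g}")

    t0 = time.time()
    hotspots = detect_hotspots(scan_result, fdr.p_cutoff,
                               bin_size=config.bin_size,
                               alpha=config.hotspot_alpha)
    write_hotspots_bed(hotspots, out / "hotspots.bed")
    _stage("hotspots", t0, n=len(hotspots))

    gene_pos = None
    if config.gene_map:
        gene_pos = pd.read_csv(config.gene_map, sep="\t").set_index("gene")

    calls, rankings = [], []
    t0 = time.time()
    peaks = scan_result.peak_per_gene_chrom(fdr.p_cutoff)
    for h in hotspots:
        in_bin = peaks[(peaks["chrom"] == h.chrom)
                       & (peaks["pos"] >= h.start) & (peaks["pos"] < h.end)]
        if gene_pos is None:
            continue  # cannot separate cis from trans without gene positions
        cis, trans = [], []
        for _, row in in_bin.iterrows():
            g = row["gene"]
            if g not in gene_pos.index:
                continue
            gchrom, gpos = gene_pos.loc[g, "chrom"], gene_pos.loc[g, "pos"]
            if gchrom == h.chrom and abs(gpos - row["pos"]) <= config.cis_window:
                cis.append(row)
            else:
                trans.append(row)
        hot_calls = []
        for cx in cis:
            for ty in trans:
                split = GenotypeSplit.from_genotypes(
                    genotypes.marker_codes(cx["marker"]))
                call = select_cis_trans_model(
                    expression.trait(cx["gene"]), expression.trait(ty["gene"]),
                    split, p_x=cx["p_value"], p_y=ty["p_value"],
                    p_threshold=max(config.filter_p, fdr.p_cutoff))
                call.marker = cx["marker"]
                hot_calls.append(call)
        calls.extend(hot_calls)
        if hot_calls:
            rank = rank_regulators(hot_calls, h.threshold,
                                   count_partial=config.count_partial)
            rank.insert(0, "hotspot", f"{h.chrom}:{h.start}-{h.end}")
            rankings.append(rank)
    _stage("tgct", t0, n_calls=len(calls), n_hotspots=len(hotspots))

    if calls:
        pd.DataFrame([{"x_gene": c.x_gene, "y_gene": c.y_gene,
                       "marker": c.marker, "best_model": c.best_model,
                       "bic_margin": c.bic_margin, **{
                           f"bic_{k.lower()}": v for k, v in c.bics.items()}}
                      for c in calls]).to_csv(out / "tgct.tsv", sep="\t",
                                              index=False)
    if rankings:
        pd.concat(rankings).to_csv(out / "regulators.tsv", sep="\t",
                                   index=False)
    return {"scan": scan_result, "fdr": fdr, "hotspots": hotspots,
            "calls": calls,
            "regulators": pd.concat(rankings) if rankings else None}
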