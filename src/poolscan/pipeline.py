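"""End-to-end orchestration: simulate -> FST -> filter -> windows ->
enrichment -> DE filters -> motifs -> network, with a JSON run report.

Every stage writes a plain-text artifact (TSV/JSON/FASTA/VCF) into the
output directory, and the report reconciles record counts across stages
(filtered + excluded = input).  Given the same config (including seed) the
report and artifacts are byte-identical between runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from . import expression, fst, proximity, regulatory, simulate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    With ``simulate_inputs=True`` the synthetic generator produces every
    input under ``out_dir`` first; otherwise the four input paths must point
    at existing files.
    """

    out_dir: str = "poolscan_run"
    simulate_inputs: bool = True
    seed: int = 0

    # inputs (generated when simulate_inputs, required otherwise)
    vcf_path: str | None = None
    gff_path: str | None = None
    de_path: str | None = None
    promoters_path: str | None = None
    edges_path: str | None = None

    # synthetic-study knobs
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    n_genes: int = 200
    n_planted_deg: int = 10
    colocate_fraction: float = 0.5
    planted_motif_rate: float = 1.0

    # analysis thresholds
    fst_threshold: float = 0.95
    min_control_pools: int = 1
    vep_like_max_dist: int = 5_000
    deg_flank: int = 200_000
    motif_threshold: float = 0.8
    motif_consensus: str = "TGACGTCATTGG"  # planted motif for synthetic runs
    min_component_nodes: int = 4
    genome_length: int | None = None  # default: sum of annotation chrom lengths

    def validate(self) -> None:
        if not 0.0 <= self.fst_threshold <= 1.0:
            raise ValueError("fst_threshold must be in [0, 1]")
        if self.deg_flank < 0 or self.vep_like_max_dist < 0:
            raise ValueError("flanks must be >= 0")
        if not 0.0 <= self.motif_threshold <= 1.0:
            raise ValueError("motif_threshold must be in [0, 1]")
        if not self.simulate_inputs:
            for key in ("vcf_path", "gff_path", "de_path"):
                path = getattr(self, key)
                if path is None or not os.path.exists(path):
                    raise FileNotFoundError(f"{key} missing or not found: {path!r}")


def _consensus_motif(consensus: str) -> regulatory.MotifModel:
    counts = np.zeros((4, len(consensus)))
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 10
    return regulatory.MotifModel("SYN0001", "synthetic-consensus", counts)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the report (also written as JSON)."""
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    p = lambda name: os.path.join(cfg.out_dir, name)
    report: dict = {
        "tool": "poolscan",
        "version": __version__,
        "seed": cfg.seed,
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "stages": {},
    }

    truth = None
    if cfg.simulate_inputs:
        logger.info("pipeline: simulating study inputs")
        sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        genes, de, truth = simulate.simulate_study(
            sim,
            cfg.out_dir,
            n_genes=cfg.n_genes,
            n_planted_deg=cfg.n_planted_deg,
            colocate_fraction=cfg.colocate_fraction,
            flank=cfg.deg_flank,
            motif_consensus=cfg.motif_consensus,
            planted_motif_rate=cfg.planted_motif_rate,
        )
        vcf_path = p("pools.vcf")
        gff_path, de_path = p("genes.gff3"), p("de_table.tsv")
        promoters_path, edges_path = p("promoters.fa"), p("edges.tsv")
        pool_specs = [fst.PoolSpec("SEIZURE", "seizure", sim.case_pool_size)] + [
            fst.PoolSpec(f"CONTROL{i+1}", "control", n)
            for i, n in enumerate(sim.control_pool_sizes)
        ]
        pd.DataFrame(
            [(s.name, s.role, s.n) for s in pool_specs], columns=["name", "role", "n"]
        ).to_csv(p("pools.tsv"), sep="\t", index=False)
        report["stages"]["simulate"] = {
            "n_loci": sim.n_loci,
            "n_fixed_difference": len(truth.fixed_difference_idx),
            "n_genes": cfg.n_genes,
            "n_planted_deg": len(truth.planted_deg_ids),
        }
    else:
        vcf_path, gff_path, de_path = cfg.vcf_path, cfg.gff_path, cfg.de_path
        promoters_path, edges_path = cfg.promoters_path, cfg.edges_path
        if not os.path.exists(p("pools.tsv")):
            raise FileNotFoundError("pools.tsv (pool specs) required for non-simulated runs")
        pool_specs = fst.read_pool_specs(p("pools.tsv"))

    # --- FST stage
    fst_table, counts = fst.run_fst(
        vcf_path, pool_specs, min_control_pools=cfg.min_control_pools
    )
    fst_table.to_csv(p("fst.tsv"), sep="\t", index=False, float_format="%.6g")
    high = fst.filter_high_fst(fst_table, cfg.fst_threshold)
    high.to_csv(p("high_fst.tsv"), sep="\t", index=False, float_format="%.6g")
    report["stages"]["fst"] = {**counts.as_dict(), "n_high_fst": int(len(high)),
                               "threshold": cfg.fst_threshold}

    # --- expression filters
    de = expression.read_de_table(de_path)
    strict = expression.filter_strict(de)
    relaxed = expression.filter_relaxed(de)
    background = expression.background_set(de)
    for name, res in (("strict", strict), ("relaxed", relaxed), ("background", background)):
        pd.Series(sorted(res.genes)).to_csv(p(f"genes_{name}.txt"), index=False, header=False)
    report["stages"]["expression"] = {
        name: {"n_input": r.n_input, "n_pass": r.n_pass, "n_fail": r.n_fail,
               "n_missing": r.n_missing}
        for name, r in (("strict", strict), ("relaxed", relaxed), ("background", background))
    }

    # --- annotation + DEG-window enrichment
    genes_all = proximity.read_gff3(gff_path)
    chrom_lengths = _chrom_lengths(gff_path, genes_all)
    index = proximity.GeneIndex(genes_all)
    calls = []
    for _, v in high.iterrows():
        calls.extend(
            dataclasses.asdict(c)
            for c in proximity.classify_variant(v["chrom"], int(v["pos"]), index,
                                                max_dist=cfg.vep_like_max_dist)
        )
    pd.DataFrame(calls).to_csv(p("consequences.tsv"), sep="\t", index=False)

    deg_models = [g for g in genes_all if g.gene_id in strict.gene_set]
    windows = proximity.build_windows(deg_models, cfg.deg_flank, chrom_lengths)
    observed, inside = proximity.count_in_windows(high, windows)
    pair_table = proximity.variant_gene_table(inside, deg_models, cfg.deg_flank, de)
    pair_table.to_csv(p("deg_window_variants.tsv"), sep="\t", index=False)
    genome_length = cfg.genome_length or sum(chrom_lengths.values())
    summary = proximity.fold_enrichment(len(high), windows.coverage_bp, genome_length, observed) \
        if len(high) and windows.coverage_bp else None
    report["stages"]["enrichment"] = {
        "n_deg_windows_genes": len(deg_models),
        "coverage_bp": windows.coverage_bp,
        "genome_length_bp": genome_length,
        "observed_distinct_positions": observed,
        "variant_gene_pairs": int(len(pair_table)),
        "summary": summary.as_dict() if summary else None,
    }

    # --- promoter motifs
    if promoters_path and os.path.exists(promoters_path):
        motif = _consensus_motif(cfg.motif_consensus)
        hits = regulatory.scan_fasta(promoters_path, motif, cfg.motif_threshold)
        targets = [g for g in strict.genes if g in hits]
        bg = [g for g in background.genes if g in hits and g not in strict.gene_set]
        if targets and bg:
            enr = regulatory.coverage_enrichment(targets, bg, hits, motif.motif_id)
            report["stages"]["motifs"] = {
                "motif_id": enr.motif_id,
                "targets_covered": f"{enr.a}/{enr.A}",
                "background_covered": f"{enr.b}/{enr.B}",
                "log2_enrichment": None if not np.isfinite(enr.log2_enrichment)
                else round(enr.log2_enrichment, 4),
                "pvalue": enr.pvalue,
            }

    # --- co-regulation network
    if edges_path and os.path.exists(edges_path):
        edges = pd.read_csv(edges_path, sep="\t")
        net = regulatory.filter_network(edges, relaxed.gene_set, cfg.min_component_nodes)
        report["stages"]["network"] = {
            "n_edges_input": net.n_edges_input,
            "n_self_loops_dropped": net.n_self_loops_dropped,
            "n_components_retained": len(net.components),
            "component_sizes": [len(c) for c in net.components],
        }

    with open(p("report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report


def _chrom_lengths(gff_path: str, genes) -> dict[str, int]:
    """Chromosome lengths from GFF3 sequence-region pragmas, else gene extents."""
    lengths: dict[str, int] = {}
    with open(gff_path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, chrom, _start, end = line.split()[:4]
                lengths[chrom] = int(end)
            elif not line.startswith("#"):
                break
    for g in genes:
        lengths[g.chrom] = max(lengths.get(g.chrom, 0), g.end)
    return lengths
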