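"""Tests for the synthetic pooled-WGS study generator."""

import numpy as np
import pytest
from Bio import SeqIO
from cyvcf2 import VCF

from poolscan import fst, simulate
from poolscan.proximity import build_windows
from poolscan.regulatory import MotifModel


def _pool_specs(cfg):
    return [fst.PoolSpec("SEIZURE", "seizure", cfg.case_pool_size)] + [
        fst.PoolSpec(f"CONTROL{i + 1}", "control", n)
        for i, n in enumerate(cfg.control_pool_sizes)
    ]


def test_config_validation():
    with pytest.raises(ValueError):
        simulate.SimConfig(divergence_F=1.0)
    with pytest.raises(ValueError):
        simulate.SimConfig(mean_depth=0)
    with pytest.raises(ValueError):
        simulate.SimConfig(n_loci=10, n_fixed_difference_loci=11)


def test_vcf_record_count_and_parseability(tmp_path):
    cfg = simulate.SimConfig(n_loci=1000, seed=7)
    path = str(tmp_path / "pools.vcf")
    simulate.simulate_pool_vcf(cfg, path)
    records = list(VCF(path))
    assert len(records) == 1000
    assert all(len(r.ALT) == 1 and r.is_snp for r in records)


def test_fixed_difference_loci_have_clean_allelic_depths(tmp_path):
    """Case pool carries only alt reads, every control only ref reads."""
    cfg = simulate.SimConfig(n_loci=300, n_fixed_difference_loci=12, seed=3)
    path = str(tmp_path / "pools.vcf")
    truth = simulate.simulate_pool_vcf(cfg, path)
    records = list(VCF(path))
    assert len(truth.fixed_difference_idx) == 12
    for i in truth.fixed_difference_idx:
        ad = records[i].format("AD")
        assert ad[0][0] == 0 and ad[0][1] > 0  # case: (0, d)
        for j in range(1, 5):
            assert ad[j][1] == 0 and ad[j][0] > 0  # controls: (d, 0)


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    cfg = simulate.SimConfig(n_loci=200, seed=5)
    a, b = tmp_path / "a", tmp_path / "b"
    simulate.simulate_study(cfg, str(a), n_genes=40, n_planted_deg=4)
    simulate.simulate_study(cfg, str(b), n_genes=40, n_planted_deg=4)
    for name in ("pools.vcf", "genes.gff3", "de_table.tsv", "promoters.fa", "edges.tsv", "truth.json"):
        assert (a / name).read_bytes() == (b / name).read_bytes(), name


def test_pool_frequency_error_shrinks_with_depth(tmp_path):
    """With no divergence, estimated pool frequencies approach the ancestral
    frequency as depth grows (read-sampling noise dominates at 30x)."""
    errs = {}
    for depth in (30, 3000):
        cfg = simulate.SimConfig(
            n_loci=400, divergence_F=0.0, mean_depth=depth,
            n_fixed_difference_loci=0, seed=9,
        )
        path = str(tmp_path / f"d{depth}.vcf")
        truth = simulate.simulate_pool_vcf(cfg, path)
        p0 = np.array(truth.ancestral_freq)
        est = []
        for rec in VCF(path):
            ad = rec.format("AD")
            est.append(ad[:, 1] / ad.sum(axis=1))
        est = np.array(est)
        errs[depth] = np.mean(np.abs(est - p0[:, None]))
    assert errs[3000] < errs[30]
    # binomial read noise at the pool level still leaves finite-pool noise
    assert errs[30] < 0.12


def test_mean_fst_increases_with_simulated_divergence(tmp_path):
    """Estimated differentiation recovers the simulated divergence ordering."""
    means = []
    for f in (0.01, 0.3):
        cfg = simulate.SimConfig(
            n_loci=2000, divergence_F=f, n_fixed_difference_loci=0, seed=21
        )
        path = str(tmp_path / f"f{f}.vcf")
        simulate.simulate_pool_vcf(cfg, path)
        table, _ = fst.run_fst(path, _pool_specs(cfg))
        means.append(table["fst"].mean())
    assert means[0] < means[1]


def test_de_table_shape_and_planted_rows(study):
    de, truth = study["de"], study["truth"]
    assert len(de) == 80  # one row per gene, planted DEGs included
    planted = de[de["gene_id"].isin(truth.planted_deg_ids)]
    assert len(planted) == 8
    assert (planted["log2fc"].abs() > 1).all()
    assert (planted["padj"] < 0.001).all()


def test_gene_models_are_disjoint_and_well_formed(study):
    by_chrom = {}
    for g in study["genes"]:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    for spans in by_chrom.values():
        spans.sort()
        assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(spans, spans[1:]))


def test_cannot_plant_more_degs_than_genes(tmp_path):
    cfg = simulate.SimConfig(n_loci=10, n_fixed_difference_loci=2, seed=1)
    with pytest.raises(ValueError):
        simulate.simulate_annotation_and_de(cfg, n_genes=5, n_planted_deg=6)


def test_colocated_fixed_loci_fall_in_planted_windows(study):
    cfg, truth = study["cfg"], study["truth"]
    planted = [g for g in study["genes"] if g.gene_id in set(truth.planted_deg_ids)]
    windows = build_windows(planted, 200_000, cfg.chrom_lengths)
    inside = sum(
        any(s <= truth.pos[i] - 1 < e for s, e in windows.intervals.get(truth.chrom[i], []))
        for i in truth.fixed_difference_idx
    )
    assert inside >= round(0.5 * len(truth.fixed_difference_idx))


def _consensus_motif(consensus):
    counts = np.zeros((4, len(consensus)))
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 10
    return MotifModel("M1", "m1", counts)


def test_promoters_planted_rate_one_contains_consensus(study, tmp_path):
    genes = study["genes"][:10]
    targets = [g.gene_id for g in genes]
    path = str(tmp_path / "prom.fa")
    records, truth = simulate.simulate_promoters(
        genes, "TGACGTCATTGG", 1.0, target_gene_ids=targets, fasta_path=path, seed=4
    )
    assert all("TGACGTCATTGG" in seq for _, seq in records)
    assert set(truth.planted_motif_positions) == set(targets)
    # round-trip: written records parse back identically
    parsed = {r.id: str(r.seq) for r in SeqIO.parse(path, "fasta")}
    assert parsed == dict(records)


def test_promoters_without_planting_have_no_consensus_hits(study):
    """Chance exact-consensus hits for a 12-mer: ~2000*2/4^12 per promoter."""
    genes = study["genes"]
    records, truth = simulate.simulate_promoters(
        genes, "TGACGTCATTGG", 0.0, target_gene_ids=[], seed=8
    )
    assert len(records) == len(genes)
    assert not truth.planted_motif_positions
    hits = sum("TGACGTCATTGG" in seq for _, seq in records)
    assert hits <= 2  # expectation ~0.02 over 80 promoters


def test_coreg_edges_build_a_planted_core(study):
    deg_ids = study["truth"].planted_deg_ids
    others = [g.gene_id for g in study["genes"] if g.gene_id not in set(deg_ids)]
    edges = simulate.simulate_coreg_edges(deg_ids, others, core_size=5, seed=2)
    core_edges = edges[edges["gene_a"].isin(deg_ids) & edges["gene_b"].isin(deg_ids)]
    assert len(core_edges) >= 5 * 4 // 2
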