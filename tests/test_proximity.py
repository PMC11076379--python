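"""Tests for proximity classification, DEG windows and fold enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import random_genes
from oracles import naive_classify, naive_in_windows
from poolscan.proximity import (
    GeneIndex,
    GeneModel,
    build_windows,
    classify_variant,
    count_in_windows,
    fold_enrichment,
    merge_intervals,
    variant_gene_table,
)


def test_gene_model_validation():
    with pytest.raises(ValueError):
        GeneModel("g", "g", "1", 100, 100, "+")
    with pytest.raises(ValueError):
        GeneModel("g", "g", "1", 100, 200, "+", exons=((50, 150),))
    with pytest.raises(ValueError):
        GeneModel("g", "g", "1", 100, 200, "+", exons=((100, 160), (150, 200)))


def test_downstream_distance_convention(plus_gene):
    """A variant 47,323 bp past a + strand gene end is downstream at that gap."""
    index = GeneIndex([plus_gene])
    calls = classify_variant("1", 67_323, index, max_dist=200_000)
    assert [(c.gene_id, c.consequence, c.distance) for c in calls] == [
        ("g1", "downstream_gene_variant", 47_323)
    ]


def test_intronic_variant_has_zero_distance(plus_gene):
    index = GeneIndex([plus_gene])
    (call,) = classify_variant("1", 15_000, index)  # between the two exons
    assert (call.consequence, call.distance) == ("intron_variant", 0)
    (call,) = classify_variant("1", 11_000, index)
    assert (call.consequence, call.distance) == ("exon_variant", 0)


def test_upstream_boundary_distance_is_one():
    gene = GeneModel("g", "g", "1", 5_000, 9_000, "+")
    index = GeneIndex([gene])
    (call,) = classify_variant("1", 5_000, index)  # 1-based pos 5000 = 0-based 4999
    assert (call.consequence, call.distance) == ("upstream_gene_variant", 1)


def test_strand_flips_upstream_downstream():
    minus = GeneModel("g", "g", "1", 5_000, 9_000, "-")
    index = GeneIndex([minus])
    (before,) = classify_variant("1", 4_000, index)
    (after,) = classify_variant("1", 9_500, index)
    assert before.consequence == "downstream_gene_variant"
    assert after.consequence == "upstream_gene_variant"


def test_no_gene_in_range_is_intergenic(plus_gene):
    index = GeneIndex([plus_gene])
    (call,) = classify_variant("1", 500_000, index, max_dist=5_000)
    assert call.consequence == "intergenic" and call.gene_id is None
    (call,) = classify_variant("chrUn", 100, index, max_dist=5_000)
    assert call.consequence == "intergenic"


def test_classification_matches_brute_force_scan():
    rng = np.random.default_rng(17)
    genes = random_genes(rng, 60)
    index = GeneIndex(genes)
    for _ in range(1000):
        chrom = str(rng.integers(1, 3))
        pos = int(rng.integers(1, 1_000_001))
        got = [
            (c.gene_id, c.consequence, c.distance)
            for c in classify_variant(chrom, pos, index, max_dist=5_000)
        ]
        assert got == naive_classify(chrom, pos, genes, 5_000)


def test_window_merging_by_hand():
    genes = [
        GeneModel("a", "a", "1", 1_000, 2_000, "+"),
        GeneModel("b", "b", "1", 1_500, 2_500, "+"),
    ]
    ws = build_windows(genes, 100, {"1": 10_000})
    assert ws.intervals == {"1": [(900, 2_600)]}
    assert ws.coverage_bp == 1_700


def test_zero_flank_coverage_is_gene_length_sum():
    genes = [
        GeneModel("a", "a", "1", 100, 200, "+"),
        GeneModel("b", "b", "1", 300, 450, "+"),
    ]
    ws = build_windows(genes, 0, {"1": 1_000})
    assert ws.coverage_bp == 250


def test_windows_clip_at_chromosome_bounds():
    genes = [GeneModel("a", "a", "1", 100, 300, "+")]
    ws = build_windows(genes, 200_000, {"1": 50_000})
    assert ws.intervals == {"1": [(0, 50_000)]}


def test_unknown_chromosome_names_the_gene():
    genes = [GeneModel("lost", "lost", "99", 100, 300, "+")]
    with pytest.raises(ValueError, match="lost"):
        build_windows(genes, 0, {"1": 1_000})


def test_merge_is_idempotent_and_order_invariant():
    rng = np.random.default_rng(3)
    ivs = [(int(s), int(s + rng.integers(1, 50))) for s in rng.integers(0, 500, 40)]
    merged = merge_intervals(ivs)
    assert merge_intervals(merged) == merged
    rng.shuffle(ivs)
    assert merge_intervals(ivs) == merged


def test_count_in_windows_against_naive_membership():
    rng = np.random.default_rng(23)
    genes = random_genes(rng, 30)
    ws = build_windows(genes, 10_000, {"1": 2_000_000, "2": 2_000_000})
    variants = pd.DataFrame(
        {
            "chrom": [str(c) for c in rng.integers(1, 3, 10_000)],
            "pos": rng.integers(1, 1_000_001, 10_000),
        }
    ).drop_duplicates(subset=["chrom", "pos"])
    observed, inside = count_in_windows(variants, ws)
    expected = sum(naive_in_windows(c, p, ws.intervals) for c, p in zip(variants.chrom, variants.pos))
    assert observed == expected == len(inside)


def test_duplicate_positions_counted_once():
    genes = [GeneModel("a", "a", "1", 100, 200, "+")]
    ws = build_windows(genes, 0, {"1": 1_000})
    variants = pd.DataFrame({"chrom": ["1", "1", "1"], "pos": [150, 150, 500]})
    observed, _ = count_in_windows(variants, ws)
    assert observed == 1
    assert count_in_windows(variants.iloc[0:0], ws)[0] == 0


def test_variant_gene_table_lists_every_source_gene_in_flank():
    genes = [
        GeneModel("a", "a", "1", 100_000, 110_000, "+"),
        GeneModel("b", "b", "1", 150_000, 160_000, "-"),
    ]
    variants = pd.DataFrame({"chrom": ["1"], "pos": [130_000]})
    table = variant_gene_table(variants, genes, 200_000)
    assert set(table["gene_id"]) == {"a", "b"}
    assert (table["pos"] == 130_000).all()


def test_fold_enrichment_study_scale_numbers():
    """1276 variants, 26.2 Mbp windows in a 2.42 Gbp genome, 27 observed."""
    s = fold_enrichment(1276, 26.2e6, 2.42e9, 27)
    assert s.expected_rounded == 14
    assert round(s.fold, 1) == 1.9


def test_fold_enrichment_degenerate_and_simple_cases():
    s = fold_enrichment(100, 1_000, 1_000, 100)  # windows cover the genome
    assert s.fold == pytest.approx(1.0)
    s = fold_enrichment(10, 100, 1_000, 3)
    assert s.expected_rounded == 1 and s.fold == pytest.approx(3.0)
    s = fold_enrichment(10, 1, 1_000_000, 1)  # expectation rounds to zero
    assert s.expected_rounded == 0 and math.isinf(s.fold) and s.infinite
    with pytest.raises(ValueError):
        fold_enrichment(10, 0, 1_000, 0)
    with pytest.raises(ValueError):
        fold_enrichment(10, 100, 1_000, 11)
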