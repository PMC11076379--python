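"""Variant-to-gene proximity classification and DEG-window enrichment.

Coordinates are 0-based half-open internally; VCF positions (1-based) are
converted on entry and printed back 1-based.  "Distance" follows the
annotation convention where a variant immediately adjacent to a gene
boundary is 1 bp away: upstream distance = gene start (1-based) - variant
position, downstream distance = variant position - gene end (1-based),
resolved by gene strand.

The enrichment statistic compares the number of highly differentiated
variants observed inside the merged +/-flank windows around a gene set
(typically DEGs, flank 200 kbp) with the count expected if the same number
of variants were scattered uniformly over the assembled chromosomes:
``expected = n_total * coverage / genome_length``.  The expected count is
rounded to the nearest integer before the headline fold ratio; the
unrounded fold is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GeneModel",
    "ConsequenceCall",
    "WindowSet",
    "EnrichmentSummary",
    "GeneIndex",
    "read_gff3",
    "classify_variant",
    "build_windows",
    "merge_intervals",
    "count_in_windows",
    "variant_gene_table",
    "fold_enrichment",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene span with exon structure; 0-based half-open coordinates."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        last = self.start
        for es, ee in self.exons:
            if es < self.start or ee > self.end:
                raise ValueError(f"{self.gene_id}: exon outside gene span")
            if es < last:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            if es >= ee:
                raise ValueError(f"{self.gene_id}: empty exon")
            last = ee

    @property
    def tss(self) -> int:
        """0-based transcription start: left end on +, right-most base on -."""
        return self.start if self.strand == "+" else self.end - 1


def read_gff3(path: str) -> list[GeneModel]:
    """Load gene models (gene + exon features) from a GFF3 file."""
    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = tuple(
            sorted((e.start - 1, e.end) for e in db.children(g, featuretype="exon"))
        )
        genes.append(
            GeneModel(
                gene_id=g.id,
                symbol=g.attributes.get("Name", [g.id])[0],
                chrom=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand,
                exons=exons,
            )
        )
    return genes


@dataclass(frozen=True)
class ConsequenceCall:
    """Proximity/consequence of one variant with respect to one gene."""

    chrom: str
    pos: int  # 1-based
    gene_id: str | None
    consequence: str  # upstream_gene_variant | downstream_gene_variant |
    #                   intron_variant | exon_variant | intergenic
    distance: int  # bp; 0 for within-gene classes and intergenic


class GeneIndex:
    """Per-chromosome interval index over gene spans."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    def near(self, chrom: str, pos0: int, max_dist: int) -> list[GeneModel]:
        """Genes whose boundary distance to pos0 is <= max_dist (0 if inside)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(pos0 - max_dist, pos0 + max_dist + 1)
        return sorted((iv.data for iv in hits), key=lambda g: (g.start, g.gene_id))


def classify_variant(
    chrom: str, pos: int, index: GeneIndex, max_dist: int = 5000
) -> list[ConsequenceCall]:
    """Classify one variant (1-based position) against every nearby gene.

    Within a gene the call is exon_variant or intron_variant (distance 0);
    outside, upstream/downstream is resolved by the gene's strand and the
    distance is the 1-based gap to the nearest gene boundary.  With no gene
    within ``max_dist`` a single intergenic call is returned.
    """
    pos0 = pos - 1
    calls = []
    for g in index.near(chrom, pos0, max_dist):
        if g.start <= pos0 < g.end:
            inside_exon = any(es <= pos0 < ee for es, ee in g.exons)
            cls = "exon_variant" if inside_exon else "intron_variant"
            calls.append(ConsequenceCall(chrom, pos, g.gene_id, cls, 0))
            continue
        if pos0 < g.start:
            dist = g.start - pos0
            cls = "upstream_gene_variant" if g.strand == "+" else "downstream_gene_variant"
        else:
            dist = pos0 - g.end + 1
            cls = "downstream_gene_variant" if g.strand == "+" else "upstream_gene_variant"
        calls.append(ConsequenceCall(chrom, pos, g.gene_id, cls, dist))
    if not calls:
        return [ConsequenceCall(chrom, pos, None, "intergenic", 0)]
    calls.sort(key=lambda c: (c.distance, c.gene_id))
    return calls


# ---------------------------------------------------------------------------
# windows


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly overlapping half-open intervals into a sorted disjoint set."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


@dataclass
class WindowSet:
    """Merged, clipped +/-flank windows around a set of source genes."""

    source_gene_ids: list[str]
    flank: int
    intervals: dict[str, list[tuple[int, int]]]
    coverage_bp: int = field(init=False)

    def __post_init__(self) -> None:
        self.coverage_bp = sum(e - s for ivs in self.intervals.values() for s, e in ivs)


def build_windows(
    genes: list[GeneModel], flank: int, chrom_lengths: dict[str, int]
) -> WindowSet:
    """Extend each gene by ``flank`` bp on both sides, clip and merge."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    raw: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        if g.chrom not in chrom_lengths:
            raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom!r}")
        s = max(0, g.start - flank)
        e = min(chrom_lengths[g.chrom], g.end + flank)
        raw.setdefault(g.chrom, []).append((s, e))
    merged = {c: merge_intervals(ivs) for c, ivs in sorted(raw.items())}
    return WindowSet([g.gene_id for g in genes], flank, merged)


def _in_windows(chrom: str, pos0: int, windows: WindowSet) -> bool:
    ivs = windows.intervals.get(chrom)
    if not ivs:
        return False
    starts = np.fromiter((s for s, _ in ivs), dtype=np.int64, count=len(ivs))
    i = int(np.searchsorted(starts, pos0, side="right")) - 1
    return i >= 0 and pos0 < ivs[i][1]


def count_in_windows(
    variants: pd.DataFrame, windows: WindowSet
) -> tuple[int, pd.DataFrame]:
    """Count distinct variant positions inside the merged windows.

    ``variants`` needs columns chrom and pos (1-based).  Returns the
    distinct-position count and the subset of rows falling in a window
    (deduplicated by position).
    """
    if variants.empty:
        return 0, variants.iloc[0:0]
    dedup = variants.drop_duplicates(subset=["chrom", "pos"])
    mask = [
        _in_windows(c, p - 1, windows)
        for c, p in zip(dedup["chrom"], dedup["pos"])
    ]
    inside = dedup[np.asarray(mask, dtype=bool)]
    return int(len(inside)), inside.reset_index(drop=True)


def variant_gene_table(
    in_window_variants: pd.DataFrame,
    source_genes: list[GeneModel],
    flank: int,
    de_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per variant-gene pair companion table for in-window variants.

    One row for every source gene within ``flank`` of each in-window variant
    (positions repeat across genes), with the proximity class, distance and,
    when a DE table is given, the gene's log2 fold change and adjusted p.
    """
    index = GeneIndex(source_genes)
    de_map = {}
    if de_table is not None:
        de_map = de_table.set_index("gene_id")[["log2fc", "padj"]].to_dict("index")
    rows = []
    for _, v in in_window_variants.iterrows():
        for call in classify_variant(v["chrom"], int(v["pos"]), index, max_dist=flank):
            if call.gene_id is None:
                continue
            de = de_map.get(call.gene_id, {})
            rows.append(
                {
                    "chrom": v["chrom"],
                    "pos": int(v["pos"]),
                    "ref": v.get("ref", "."),
                    "alt": v.get("alt", "."),
                    "gene_id": call.gene_id,
                    "consequence": call.consequence,
                    "distance": call.distance,
                    "log2fc": de.get("log2fc", np.nan),
                    "padj": de.get("padj", np.nan),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene_id",
            "consequence", "distance", "log2fc", "padj",
        ],
    )


# ---------------------------------------------------------------------------
# fold enrichment


@dataclass(frozen=True)
class EnrichmentSummary:
    """Observed vs expected variants in windows under uniform placement."""

    n_variants_total: int
    coverage_bp: int
    genome_length_bp: int
    observed: int
    expected_raw: float
    expected_rounded: int
    fold: float  # observed / expected_rounded; inf when expected_rounded == 0
    fold_raw: float  # observed / expected_raw

    @property
    def infinite(self) -> bool:
        return math.isinf(self.fold)

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["fold_1dp"] = round(self.fold, 1) if not self.infinite else None
        return d


def fold_enrichment(
    n_total: int, coverage_bp: float, genome_length_bp: float, observed: int
) -> EnrichmentSummary:
    """Fold enrichment of variants in windows over the uniform expectation.

    ``expected_raw = n_total * coverage_bp / genome_length_bp``; the
    headline fold divides the observed count by the expected count rounded
    to the nearest integer (half away from zero), with the unrounded fold
    reported alongside.
    """
    if not 0 < coverage_bp <= genome_length_bp:
        raise ValueError("coverage must be in (0, genome_length]")
    if observed > n_total:
        raise ValueError("observed cannot exceed the total variant count")
    expected_raw = n_total * coverage_bp / genome_length_bp
    expected_rounded = int(math.floor(expected_raw + 0.5))
    fold = observed / expected_rounded if expected_rounded > 0 else math.inf
    fold_raw = observed / expected_raw if expected_raw > 0 else math.inf
    return EnrichmentSummary(
        n_variants_total=n_total,
        coverage_bp=int(coverage_bp),
        genome_length_bp=int(genome_length_bp),
        observed=observed,
        expected_raw=expected_raw,
        expected_rounded=expected_rounded,
        fold=fold,
        fold_raw=fold_raw,
    )
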