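"""Synthetic pooled-WGS study generator.

Emulates the design of the case/control pooled sequencing study the
downstream analysis assumes: one case pool of 22 diploid individuals and
four control pools of 10, sequenced to ~30x mean depth, plus gene models,
a differential-expression results table with planted DEGs, promoter
sequences with planted motif instances, and a co-regulation edge list.

Population allele frequencies follow the Balding-Nichols model: for each
locus an ancestral frequency ``p0`` is drawn uniformly on [0.05, 0.95] and
each pool's population frequency from ``Beta(p0 (1-F)/F, (1-p0)(1-F)/F)``,
so the divergence parameter ``F`` is the expected fixation index between
pools.  Pool sample allele counts are binomial over the pool's ``2N``
chromosomes, sequencing depth is Poisson, and alternate-read counts are
binomial in the pool's sample frequency — the AD field of the emitted VCF
carries exactly these read counts.  Planted fixed-difference loci override
the frequencies to 1 in the case pool and 0 in every control pool, so they
yield FST = 1 downstream whenever called (there is no sequencing-error
model by default).  Loci whose called read counts come out monomorphic are
redrawn, since a variant caller would not have emitted them.

All outputs are deterministic functions of the configuration (including its
seed): same config, byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "simulate_pool_vcf",
    "simulate_study",
    "simulate_annotation_and_de",
    "simulate_promoters",
    "simulate_coreg_edges",
    "write_gff3",
    "DEFAULT_PROMOTER_SPAN",
]

# promoter span around the TSS scanned for motifs: 1500 bp upstream, 500 down
DEFAULT_PROMOTER_SPAN = (1500, 500)

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic pooled-WGS cohort."""

    n_loci: int = 5000
    n_chromosomes: int = 4
    chromosome_length: int = 10_000_000
    case_pool_size: int = 22
    control_pool_sizes: tuple[int, ...] = (10, 10, 10, 10)
    mean_depth: float = 30.0
    divergence_F: float = 0.2
    case_divergence_F: float | None = None  # defaults to divergence_F
    n_fixed_difference_loci: int = 50
    missing_pool_rate: float = 0.0
    error_rate: float = 0.0  # symmetric per-read base error; 0 keeps FST=1 exact
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence_F < 1.0:
            raise ValueError("divergence_F must be in [0, 1)")
        if self.case_divergence_F is not None and not 0.0 <= self.case_divergence_F < 1.0:
            raise ValueError("case_divergence_F must be in [0, 1)")
        if min(self.n_loci, self.n_chromosomes, self.chromosome_length, self.case_pool_size) <= 0:
            raise ValueError("all sizes must be > 0")
        if not self.control_pool_sizes or min(self.control_pool_sizes) <= 0:
            raise ValueError("control pool sizes must be > 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0.0 <= self.missing_pool_rate < 1.0:
            raise ValueError("missing_pool_rate must be in [0, 1)")
        if self.n_fixed_difference_loci > self.n_loci:
            raise ValueError("cannot plant more fixed-difference loci than loci")

    @property
    def pool_names(self) -> list[str]:
        return ["SEIZURE"] + [f"CONTROL{i + 1}" for i in range(len(self.control_pool_sizes))]

    @property
    def pool_sizes(self) -> list[int]:
        return [self.case_pool_size, *self.control_pool_sizes]

    @property
    def chrom_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chromosome_length for c in self.chrom_names}

    @property
    def genome_length(self) -> int:
        return self.n_chromosomes * self.chromosome_length


@dataclass
class PlantedTruth:
    """Ground truth recorded while simulating, for recovery tests."""

    chrom: list[str] = field(default_factory=list)
    pos: list[int] = field(default_factory=list)  # 1-based, as in the VCF
    pool_freqs: list[list[float]] = field(default_factory=list)  # per locus, per pool
    ancestral_freq: list[float] = field(default_factory=list)
    fixed_difference_idx: list[int] = field(default_factory=list)
    planted_deg_ids: list[str] = field(default_factory=list)
    planted_deg_log2fc: dict[str, float] = field(default_factory=dict)
    planted_motif_positions: dict[str, list[int]] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "PlantedTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _balding_nichols(rng: np.random.Generator, p0: np.ndarray, f: float) -> np.ndarray:
    """Population frequencies for one pool given ancestral p0 and divergence F."""
    if f == 0.0:
        return p0.copy()
    scale = (1.0 - f) / f
    return rng.beta(p0 * scale, (1.0 - p0) * scale)


def _draw_locus_batch(rng: np.random.Generator, cfg: SimConfig, n: int):
    """Draw frequencies, depths and read counts for n loci across all pools."""
    n_pools = len(cfg.pool_sizes)
    p0 = rng.uniform(0.05, 0.95, size=n)
    pop = np.empty((n, n_pools))
    f_case = cfg.divergence_F if cfg.case_divergence_F is None else cfg.case_divergence_F
    pop[:, 0] = _balding_nichols(rng, p0, f_case)
    for j in range(1, n_pools):
        pop[:, j] = _balding_nichols(rng, p0, cfg.divergence_F)
    chroms2n = 2 * np.asarray(cfg.pool_sizes)
    sample = rng.binomial(chroms2n[None, :], pop) / chroms2n[None, :]
    depth = rng.poisson(cfg.mean_depth, size=(n, n_pools))
    read_freq = sample * (1.0 - cfg.error_rate) + (1.0 - sample) * cfg.error_rate
    alt = rng.binomial(depth, read_freq)
    missing = rng.random(size=(n, n_pools)) < cfg.missing_pool_rate
    missing |= depth == 0
    return p0, sample, depth, alt, missing


def simulate_pool_vcf(
    cfg: SimConfig,
    out_path: str,
    truth: PlantedTruth | None = None,
    fixed_positions: list[tuple[str, int]] | None = None,
) -> PlantedTruth:
    """Write a multi-sample VCF of pooled allelic depths; return planted truth.

    One VCF sample per pool, FORMAT ``GT:AD``; missing pools are encoded
    ``./.:.``.  Every emitted locus is variable in its called read counts
    (monomorphic draws are rejected and redrawn), so a downstream run with
    all pools called yields one FST row per record.

    ``fixed_positions`` optionally pins some of the planted fixed-difference
    loci to explicit (chrom, 1-based pos) coordinates — used by
    :func:`simulate_study` to co-locate them with planted DEGs; the
    remaining fixed loci and all other loci are placed uniformly.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = truth if truth is not None else PlantedTruth()
    n_pools = len(cfg.pool_sizes)

    # unique sorted positions across chromosomes; pinned fixed loci first
    if fixed_positions:
        if len(fixed_positions) > cfg.n_fixed_difference_loci:
            raise ValueError("more pinned positions than fixed-difference loci")
        lin_given = np.array(
            [cfg.chrom_names.index(c) * cfg.chromosome_length + (p - 1) for c, p in fixed_positions],
            dtype=np.int64,
        )
        if len(set(lin_given.tolist())) != len(lin_given):
            raise ValueError("pinned fixed positions must be unique")
    else:
        lin_given = np.empty(0, dtype=np.int64)
    rand = rng.choice(cfg.genome_length, size=cfg.n_loci, replace=False)
    rand = rand[~np.isin(rand, lin_given)][: cfg.n_loci - len(lin_given)]
    lin = np.sort(np.concatenate([rand, lin_given]))
    chrom_idx = lin // cfg.chromosome_length
    pos = lin % cfg.chromosome_length + 1  # 1-based

    is_fixed = np.isin(lin, lin_given)
    n_extra = cfg.n_fixed_difference_loci - len(lin_given)
    if n_extra > 0:
        extra = rng.choice(np.nonzero(~is_fixed)[0], size=n_extra, replace=False)
        is_fixed[extra] = True
    fixed_idx = np.nonzero(is_fixed)[0]

    p0, sample, depth, alt, missing = _draw_locus_batch(rng, cfg, cfg.n_loci)
    # planted fixed differences: case fixed for ALT, controls fixed for REF
    sample[is_fixed, 0] = 1.0
    sample[is_fixed, 1:] = 0.0
    p0[is_fixed] = np.nan
    alt[is_fixed, 0] = depth[is_fixed, 0]
    alt[is_fixed, 1:] = 0

    # reject loci monomorphic in the called read counts (a caller would not
    # emit them); redraw frequencies and reads until variable
    for _ in range(1000):
        called_alt = np.where(missing, 0, alt)
        called_ref = np.where(missing, 0, depth - alt)
        bad = ((called_alt.sum(axis=1) == 0) | (called_ref.sum(axis=1) == 0)) & ~is_fixed
        if not bad.any():
            break
        nbad = int(bad.sum())
        p0_b, s_b, d_b, a_b, m_b = _draw_locus_batch(rng, cfg, nbad)
        p0[bad], sample[bad], depth[bad], alt[bad], missing[bad] = p0_b, s_b, d_b, a_b, m_b
    else:  # pragma: no cover - astronomically unlikely at sane depths
        raise RuntimeError("could not draw variable loci; check depth/config")

    ref_alleles = _BASES[rng.integers(0, 4, size=cfg.n_loci)]
    alt_alleles = np.array(
        [_BASES[(i + rng.integers(1, 4)) % 4] for i in _BASES.searchsorted(ref_alleles)]
    )

    with open(out_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=poolscan-simulate\n")
        for name in cfg.chrom_names:
            fh.write(f"##contig=<ID={name},length={cfg.chromosome_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cfg.pool_names)
            + "\n"
        )
        chrom_names = cfg.chrom_names
        for i in range(cfg.n_loci):
            fields = [
                chrom_names[chrom_idx[i]],
                str(pos[i]),
                ".",
                ref_alleles[i],
                alt_alleles[i],
                ".",
                "PASS",
                ".",
                "GT:AD",
            ]
            for j in range(n_pools):
                if missing[i, j]:
                    fields.append("./.:.")
                    continue
                a, d = int(alt[i, j]), int(depth[i, j])
                r = d - a
                gt = "0/0" if a == 0 else ("1/1" if r == 0 else "0/1")
                fields.append(f"{gt}:{r},{a}")
            fh.write("\t".join(fields) + "\n")

    truth.chrom = [chrom_names[c] for c in chrom_idx]
    truth.pos = [int(p) for p in pos]
    truth.pool_freqs = [[float(x) for x in row] for row in sample]
    truth.ancestral_freq = [float(x) for x in p0]
    truth.fixed_difference_idx = [int(i) for i in fixed_idx]
    return truth


# ---------------------------------------------------------------------------
# gene models + differential-expression table


def write_gff3(genes, chrom_lengths: dict[str, int], path: str) -> None:
    """Write gene/exon models as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tpoolscan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};Name={g.symbol}\n"
            )
            for k, (es, ee) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tpoolscan\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{k};Parent={g.gene_id}\n"
                )


def _make_exons(rng: np.random.Generator, start: int, end: int) -> list[tuple[int, int]]:
    """2-5 non-overlapping exons inside [start, end)."""
    n_exons = int(rng.integers(2, 6))
    cuts = np.sort(rng.choice(np.arange(start + 1, end), size=2 * n_exons - 1, replace=False))
    bounds = np.concatenate([[start], cuts, [end]])
    return [(int(bounds[2 * k]), int(bounds[2 * k + 1])) for k in range(n_exons)]


def simulate_annotation_and_de(
    cfg: SimConfig,
    n_genes: int,
    n_planted_deg: int,
    *,
    truth: PlantedTruth | None = None,
    gff_path: str | None = None,
    de_path: str | None = None,
    seed_offset: int = 1,
):
    """Simulate non-overlapping gene models and a DE results table.

    Genes are laid out one per equal-width chromosome slot (guaranteeing
    non-overlap) with 2-5 exons and random strand.  Null genes get
    ``log2fc ~ Normal(0, 0.3)`` and uniform p-values; planted DEGs get
    ``|log2fc| >= 2`` and tiny p-values, so they always pass the strict
    filter (|log2fc| > 1, p-adj < 0.001) after Benjamini-Hochberg
    adjustment.  Co-location of fixed-difference loci with planted DEGs is
    the job of :func:`simulate_study`, which plans the genes first and then
    pins loci inside their windows.

    Returns ``(genes, de_table, truth)`` where genes is a list of
    :class:`poolscan.proximity.GeneModel`.
    """
    from .proximity import GeneModel  # deferred: avoid import cycle

    if n_planted_deg > n_genes:
        raise ValueError("cannot plant more DEGs than genes")
    rng = np.random.default_rng(cfg.seed + seed_offset)
    truth = truth if truth is not None else PlantedTruth()

    # one gene per equal-width slot -> non-overlap by construction
    per_chrom = int(np.ceil(n_genes / cfg.n_chromosomes))
    slot_len = cfg.chromosome_length // per_chrom
    if slot_len < 60_000:
        raise ValueError("chromosomes too short for this many genes")
    slots = []  # (chrom, slot_start)
    for ci, chrom in enumerate(cfg.chrom_names):
        for s in range(per_chrom):
            if len(slots) < n_genes:
                slots.append((chrom, s * slot_len))

    planted_set = set(rng.choice(n_genes, size=n_planted_deg, replace=False).tolist())

    genes = []
    margin = 2_000  # keep promoters and exon cuts inside the slot
    for i, (chrom, slot_start) in enumerate(slots):
        length = int(rng.integers(5_000, 50_000))
        max_off = slot_len - length - margin
        off = int(rng.integers(margin, max(max_off, margin + 1)))
        start = slot_start + off
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"GENE{i + 1:04d}"
        genes.append(
            GeneModel(
                gene_id=gene_id,
                symbol=gene_id,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                exons=tuple(_make_exons(rng, start, end)),
            )
        )

    # DE table
    gene_ids = [g.gene_id for g in genes]
    log2fc = rng.normal(0.0, 0.3, size=n_genes)
    pvals = rng.uniform(0.0, 1.0, size=n_genes)
    for i in planted_set:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        log2fc[i] = sign * rng.uniform(2.0, 6.0)
        pvals[i] = rng.uniform(1e-12, 1e-9)
    padj = stats.false_discovery_control(pvals, method="bh")
    de = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": gene_ids,
            "log2fc": np.round(log2fc, 6),
            "pvalue": pvals,
            "padj": padj,
        }
    )

    truth.planted_deg_ids = [gene_ids[i] for i in sorted(planted_set)]
    truth.planted_deg_log2fc = {gene_ids[i]: float(log2fc[i]) for i in sorted(planted_set)}

    if gff_path:
        write_gff3(genes, cfg.chrom_lengths, gff_path)
    if de_path:
        de.to_csv(de_path, sep="\t", index=False)
    return genes, de, truth


# ---------------------------------------------------------------------------
# whole-study orchestration


def simulate_study(
    cfg: SimConfig,
    out_dir: str,
    *,
    n_genes: int = 200,
    n_planted_deg: int = 10,
    colocate_fraction: float = 0.5,
    flank: int = 200_000,
    motif_consensus: str = "TGACGTCATTGG",
    planted_motif_rate: float = 1.0,
):
    """Generate a complete synthetic study into ``out_dir``.

    Writes ``pools.vcf``, ``genes.gff3``, ``de_table.tsv``, ``promoters.fa``,
    ``edges.tsv`` and ``truth.json``.  Gene models and planted DEGs are
    planned first; then a ``colocate_fraction`` of the planted
    fixed-difference loci is pinned to uniform positions inside the
    +/-``flank`` windows of planted DEGs (the remaining loci are uniform
    genome-wide), so the planted enrichment signal is controlled directly.

    Returns ``(genes, de_table, truth)``.
    """
    if not 0.0 <= colocate_fraction <= 1.0:
        raise ValueError("colocate_fraction must be in [0, 1]")
    os.makedirs(out_dir, exist_ok=True)
    p = lambda name: os.path.join(out_dir, name)

    truth = PlantedTruth()
    genes, de, truth = simulate_annotation_and_de(
        cfg, n_genes, n_planted_deg, truth=truth,
        gff_path=p("genes.gff3"), de_path=p("de_table.tsv"),
    )
    planted = [g for g in genes if g.gene_id in set(truth.planted_deg_ids)]

    rng = np.random.default_rng(cfg.seed + 4)
    n_anchor = int(round(colocate_fraction * cfg.n_fixed_difference_loci))
    anchors: list[tuple[str, int]] = []
    used: set[tuple[str, int]] = set()
    for _ in range(n_anchor):
        g = planted[int(rng.integers(len(planted)))]
        lo = max(0, g.start - flank)
        hi = min(cfg.chromosome_length, g.end + flank) - 1
        pos1 = int(rng.integers(lo, hi + 1)) + 1
        while (g.chrom, pos1) in used:
            pos1 = pos1 % (hi + 1) + 1
        used.add((g.chrom, pos1))
        anchors.append((g.chrom, pos1))
    truth = simulate_pool_vcf(cfg, p("pools.vcf"), truth=truth, fixed_positions=anchors)

    simulate_promoters(
        genes, motif_consensus, planted_motif_rate,
        target_gene_ids=truth.planted_deg_ids,
        fasta_path=p("promoters.fa"), truth=truth, seed=cfg.seed + 2,
    )
    non_deg = [g.gene_id for g in genes if g.gene_id not in set(truth.planted_deg_ids)]
    simulate_coreg_edges(
        truth.planted_deg_ids, non_deg,
        core_size=min(6, len(truth.planted_deg_ids)),
        seed=cfg.seed + 3, path=p("edges.tsv"),
    )
    truth.to_json(p("truth.json"))
    return genes, de, truth


# ---------------------------------------------------------------------------
# promoters


def simulate_promoters(
    genes,
    consensus: str,
    planted_rate: float,
    *,
    target_gene_ids: list[str],
    gc: float = 0.5,
    span: tuple[int, int] = DEFAULT_PROMOTER_SPAN,
    fasta_path: str | None = None,
    truth: PlantedTruth | None = None,
    seed: int = 0,
):
    """I.i.d.-background promoter sequences with planted motif instances.

    One record per gene (id = gene id) covering ``span`` = (upstream,
    downstream) bp around the TSS.  In a ``planted_rate`` fraction of the
    target genes the motif consensus is inserted at a uniform random offset;
    planted offsets (relative to the TSS, upstream negative) are recorded in
    the returned truth.
    """
    if not 0.0 <= planted_rate <= 1.0:
        raise ValueError("planted_rate must be in [0, 1]")
    up, down = span
    length = up + down
    if len(consensus) >= length:
        raise ValueError("motif longer than promoter")
    rng = np.random.default_rng(seed)
    truth = truth if truth is not None else PlantedTruth()
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    targets = set(target_gene_ids)
    records = []
    for g in genes:
        seq = rng.choice(_BASES, size=length, p=probs)
        if g.gene_id in targets and rng.random() < planted_rate:
            off = int(rng.integers(0, length - len(consensus) + 1))
            seq[off : off + len(consensus)] = list(consensus)
            truth.planted_motif_positions.setdefault(g.gene_id, []).append(off - up)
        records.append((g.gene_id, "".join(seq)))
    if fasta_path:
        with open(fasta_path, "w") as fh:
            for gene_id, seq in records:
                fh.write(f">{gene_id}\n")
                for k in range(0, len(seq), 70):
                    fh.write(seq[k : k + 70] + "\n")
    return records, truth


# ---------------------------------------------------------------------------
# co-regulation edge list


def simulate_coreg_edges(
    deg_ids: list[str],
    other_ids: list[str],
    *,
    core_size: int = 6,
    n_noise_edges: int = 10,
    seed: int = 0,
    path: str | None = None,
) -> pd.DataFrame:
    """Edge list with one dense co-regulated core of DEGs plus noise edges.

    The core is a clique over ``core_size`` planted DEGs (>= 4, so it
    survives the minimum-component filter); noise edges connect random
    DEG/non-DEG pairs and mostly dissolve once non-DEG nodes are removed.
    """
    if core_size > len(deg_ids):
        raise ValueError("core_size exceeds number of DEGs")
    rng = np.random.default_rng(seed)
    core = list(rng.choice(deg_ids, size=core_size, replace=False))
    edges = [(core[i], core[j]) for i in range(core_size) for j in range(i + 1, core_size)]
    pool = list(deg_ids) + list(other_ids)
    for _ in range(n_noise_edges):
        a, b = rng.choice(pool, size=2, replace=False)
        edges.append((a, b))
    df = pd.DataFrame(edges, columns=["gene_a", "gene_b"])
    if path:
        df.to_csv(path, sep="\t", index=False)
    return df
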