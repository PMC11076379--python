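"""Promoter motif scanning, gene-coverage enrichment and network filtering.

A JASPAR position frequency matrix is converted to a log-odds scoring
matrix with a pseudocount of 0.8 distributed by the background base
composition (uniform by default):

    s[b, j] = log2( (c[b, j] + 0.8 * bg[b]) / (sum_b c[b, j] + 0.8) / bg[b] )

Promoter windows (both strands, every offset) are scored and rescaled to a
*relative score* in [0, 1] between the matrix's minimum and maximum
achievable scores; windows at or above the threshold (default 0.8) are
hits.  Gene-coverage enrichment then asks whether a larger fraction of
target-gene promoters than background-gene promoters carries at least one
hit, via a two-sided Fisher exact test on the 2x2 table, with the coverage
log2 ratio reported as the effect size.  This is a documented, standard
PWM approximation of the scan-and-test procedure; it does not reproduce
any specific tool's proprietary scoring internals.

Co-regulation networks are filtered by restricting the edge list to a DEG
set first and then discarding connected components with fewer than four
nodes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio import motifs as bio_motifs
from scipy import stats

__all__ = [
    "MotifModel",
    "MotifHit",
    "CoverageEnrichment",
    "CoregNetwork",
    "load_pfm",
    "load_pfms",
    "write_pfm",
    "scan_promoter",
    "scan_fasta",
    "coverage_enrichment",
    "filter_network",
]

_BASE_TO_ROW = {"A": 0, "C": 1, "G": 2, "T": 3}
_ROWS = "ACGT"


@dataclass
class MotifModel:
    """A PFM with its derived log-odds scoring matrix.

    counts: 4 x w array, rows A, C, G, T.
    """

    motif_id: str
    name: str
    counts: np.ndarray
    pseudocount: float = 0.8
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    log_odds: np.ndarray = field(init=False)
    min_score: float = field(init=False)
    max_score: float = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValueError(f"{self.motif_id}: counts must be 4 x w with w >= 1")
        if (self.counts < 0).any():
            raise ValueError(f"{self.motif_id}: negative counts")
        bg = np.asarray(self.background, dtype=float)
        col_tot = self.counts.sum(axis=0)
        probs = (self.counts + self.pseudocount * bg[:, None]) / (col_tot + self.pseudocount)
        self.log_odds = np.log2(probs / bg[:, None])
        self.min_score = float(self.log_odds.min(axis=0).sum())
        self.max_score = float(self.log_odds.max(axis=0).sum())

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_ROWS[i] for i in self.log_odds.argmax(axis=0))

    def relative_score(self, seq: str) -> float:
        """Score of one w-length sequence rescaled into [0, 1]."""
        if len(seq) != self.width:
            raise ValueError("sequence length must equal motif width")
        s = sum(self.log_odds[_BASE_TO_ROW[b], j] for j, b in enumerate(seq.upper()))
        return (s - self.min_score) / (self.max_score - self.min_score)


def load_pfms(source, pseudocount: float = 0.8, background=None) -> list[MotifModel]:
    """Parse every motif from JASPAR-format text (path, handle or str)."""
    if isinstance(source, str) and "\n" not in source:
        handle = open(source)
    elif isinstance(source, str):
        handle = io.StringIO(source)
    else:
        handle = source
    try:
        parsed = bio_motifs.parse(handle, "jaspar")
    except Exception as exc:  # normalise Biopython's parse failures
        raise ValueError(f"malformed JASPAR input: {exc}") from exc
    finally:
        if handle is not source:
            handle.close()
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in _ROWS], dtype=float)
        if counts.shape[1] < 1:
            raise ValueError(f"motif {m.matrix_id}: empty matrix")
        out.append(
            MotifModel(
                motif_id=m.matrix_id or m.name,
                name=m.name or m.matrix_id,
                counts=counts,
                pseudocount=pseudocount,
                background=np.full(4, 0.25) if background is None else np.asarray(background),
            )
        )
    if not out:
        raise ValueError("no motifs found in JASPAR input")
    return out


def load_pfm(source, **kwargs) -> MotifModel:
    """Parse a single JASPAR motif (error if the input holds several)."""
    models = load_pfms(source, **kwargs)
    if len(models) != 1:
        raise ValueError(f"expected one motif, found {len(models)}")
    return models[0]


def write_pfm(model: MotifModel, path: str) -> None:
    """Write a motif back to JASPAR text format."""
    with open(path, "w") as fh:
        fh.write(f">{model.motif_id} {model.name}\n")
        for i, b in enumerate(_ROWS):
            row = " ".join(f"{int(v)}" if float(v).is_integer() else f"{v}" for v in model.counts[i])
            fh.write(f"{b}  [ {row} ]\n")


# ---------------------------------------------------------------------------
# scanning


@dataclass(frozen=True)
class MotifHit:
    """One motif match in a promoter window."""

    gene_id: str
    strand: str  # '+' or '-'
    offset: int  # window start relative to the TSS (upstream negative)
    score: float  # relative score in [0, 1]


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(arr.size, -1, dtype=np.int64)
    for b, i in _BASE_TO_ROW.items():
        code[arr == ord(b)] = i
    return code


def scan_promoter(
    seq: str,
    motif: MotifModel,
    threshold: float = 0.8,
    gene_id: str = "",
    tss_offset: int = 1500,
) -> list[MotifHit]:
    """Scan one promoter sequence on both strands for motif hits.

    ``tss_offset`` is the number of upstream bases at the start of ``seq``;
    reported offsets are window starts relative to the TSS.  Windows
    containing any non-ACGT base are skipped.  Returns hits with relative
    score >= threshold, ordered by offset then strand.
    """
    w = motif.width
    code = _encode(seq)
    n = code.size - w + 1
    if n <= 0:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(code, w)
    valid = (windows >= 0).all(axis=1)
    span = motif.max_score - motif.min_score
    lo = motif.log_odds
    lo_rc = lo[::-1, ::-1]  # complement rows (A<->T, C<->G) and reverse columns
    cols = np.arange(w)
    safe = np.where(windows >= 0, windows, 0)
    fwd = lo[safe, cols].sum(axis=1)
    rev = lo_rc[safe, cols].sum(axis=1)
    hits = []
    for strand, scores in (("+", fwd), ("-", rev)):
        rel = (scores - motif.min_score) / span
        for i in np.nonzero(valid & (rel >= threshold))[0]:
            hits.append(MotifHit(gene_id, strand, int(i) - tss_offset, float(rel[i])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_fasta(
    fasta_path: str,
    motif: MotifModel,
    threshold: float = 0.8,
    tss_offset: int = 1500,
) -> dict[str, list[MotifHit]]:
    """Scan every record of a promoter FASTA (record id = gene id)."""
    from Bio import SeqIO

    out: dict[str, list[MotifHit]] = {}
    for rec in SeqIO.parse(fasta_path, "fasta"):
        out[rec.id] = scan_promoter(
            str(rec.seq), motif, threshold, gene_id=rec.id, tss_offset=tss_offset
        )
    return out


# ---------------------------------------------------------------------------
# gene-coverage enrichment


@dataclass(frozen=True)
class CoverageEnrichment:
    """2x2 gene-coverage test: promoters with >= 1 hit, target vs background."""

    motif_id: str
    a: int  # target genes with a hit
    A: int  # target genes total
    b: int  # background genes with a hit
    B: int  # background genes total
    log2_enrichment: float  # log2((a/A) / (b/B)); +/-inf flags zero cells
    pvalue: float


def coverage_enrichment(
    target_genes,
    background_genes,
    hits_by_gene: dict[str, list[MotifHit]],
    motif_id: str = "",
    alternative: str = "two-sided",
) -> CoverageEnrichment:
    """Fisher-exact test of motif coverage in target vs background promoters."""
    targets = set(target_genes)
    background = set(background_genes)
    if not targets or not background:
        raise ValueError("target and background gene sets must be non-empty")
    if targets & background:
        raise ValueError("target and background gene sets must be disjoint")
    covered = {g for g, hits in hits_by_gene.items() if hits}
    a, A = len(targets & covered), len(targets)
    b, B = len(background & covered), len(background)
    if a == 0:
        log2_enr = -np.inf if b > 0 else np.nan
    elif b == 0:
        log2_enr = np.inf
    else:
        log2_enr = float(np.log2((a / A) / (b / B)))
    _, p = stats.fisher_exact([[a, A - a], [b, B - b]], alternative=alternative)
    return CoverageEnrichment(motif_id, a, A, b, B, log2_enr, float(p))


# ---------------------------------------------------------------------------
# co-regulation network


@dataclass
class CoregNetwork:
    """Co-regulation graph restricted to DEGs, small components discarded."""

    graph: nx.Graph
    components: list[frozenset]
    n_self_loops_dropped: int
    n_edges_input: int

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.graph.nodes)


def filter_network(
    edges, deg_genes, min_nodes: int = 4
) -> CoregNetwork:
    """Restrict an edge list to DEG nodes and keep components of >= min_nodes.

    ``edges`` is an iterable of (gene_a, gene_b) pairs or a DataFrame whose
    first two columns are the endpoints.  Self-loops are ignored with a
    count.  Restriction happens before the component-size rule, so a
    component can dissolve once its non-DEG nodes are removed.
    """
    if hasattr(edges, "itertuples"):
        pairs = [(str(r[1]), str(r[2])) for r in edges.itertuples()]
    else:
        pairs = [(str(a), str(b)) for a, b in edges]
    degs = set(deg_genes)
    n_self = sum(1 for a, b in pairs if a == b)
    g = nx.Graph()
    g.add_edges_from((a, b) for a, b in pairs if a != b and a in degs and b in degs)
    keep_components = [frozenset(c) for c in nx.connected_components(g) if len(c) >= min_nodes]
    keep_nodes = set().union(*keep_components) if keep_components else set()
    return CoregNetwork(
        graph=g.subgraph(keep_nodes).copy(),
        components=sorted(keep_components, key=lambda c: (-len(c), sorted(c))),
        n_self_loops_dropped=n_self,
        n_edges_input=len(pairs),
    )
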