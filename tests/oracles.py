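"""Independent brute-force oracles used to cross-check the implementation.

These deliberately mirror the written definitions step by step (scalar
arithmetic, exhaustive scans, exact enumeration) and share no code with the
package paths they verify.
"""

from math import comb


def fst_brute(p_se: float, p_co: float, n_se: int, n_co: int) -> float:
    """Step-by-step evaluation of the weighted two-pool FST formula."""
    pbar = (n_se * p_se + n_co * p_co) / (n_se + n_co)
    total = pbar * (1 - pbar)
    within = (n_se * p_se * (1 - p_se) + n_co * p_co * (1 - p_co)) / (n_se + n_co)
    if total == 0:
        return float("nan")
    return (total - within) / total


def fisher_two_sided(a: int, A: int, b: int, B: int) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Table [[a, A-a], [b, B-b]]: sums the probabilities of all tables with
    the same margins whose probability does not exceed the observed one.
    """
    k = a + b
    denom = comb(A + B, k)

    def pmf(x: int) -> float:
        return comb(A, x) * comb(B, k - x) / denom

    p_obs = pmf(a)
    return sum(
        pmf(x)
        for x in range(max(0, k - B), min(k, A) + 1)
        if pmf(x) <= p_obs * (1 + 1e-9)
    )


def naive_in_windows(chrom: str, pos1: int, intervals: dict) -> bool:
    """Linear scan interval membership (0-based half-open intervals)."""
    return any(s <= pos1 - 1 < e for s, e in intervals.get(chrom, []))


def naive_classify(chrom, pos1, genes, max_dist):
    """Brute-force scan over every gene; mirrors the distance conventions."""
    pos0 = pos1 - 1
    calls = []
    for g in genes:
        if g.chrom != chrom:
            continue
        if g.start <= pos0 < g.end:
            cls = "exon_variant" if any(s <= pos0 < e for s, e in g.exons) else "intron_variant"
            calls.append((g.gene_id, cls, 0))
        elif pos0 < g.start and g.start - pos0 <= max_dist:
            cls = "upstream_gene_variant" if g.strand == "+" else "downstream_gene_variant"
            calls.append((g.gene_id, cls, g.start - pos0))
        elif pos0 >= g.end and pos0 - g.end + 1 <= max_dist:
            cls = "downstream_gene_variant" if g.strand == "+" else "upstream_gene_variant"
            calls.append((g.gene_id, cls, pos0 - g.end + 1))
    if not calls:
        return [(None, "intergenic", 0)]
    return sorted(calls, key=lambda c: (c[2], c[0]))


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_pwm_hits(seq, log_odds, min_score, max_score, threshold):
    """Per-offset rescoring of both strands with explicit loops."""
    base_row = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = log_odds.shape[1]
    hits = []
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        if any(b not in base_row for b in window):
            continue
        fwd = sum(log_odds[base_row[b], j] for j, b in enumerate(window))
        rc = "".join(_COMP[b] for b in reversed(window))
        rev = sum(log_odds[base_row[b], j] for j, b in enumerate(rc))
        for strand, s in (("+", fwd), ("-", rev)):
            rel = (s - min_score) / (max_score - min_score)
            if rel >= threshold:
                hits.append((i, strand, rel))
    return hits
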