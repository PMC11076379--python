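"""Threshold filters over a differential-expression results table.

Three gene sets are derived from one table of per-gene log2 fold changes
and p-values (e.g. DESeq2 output):

* strict DEGs:   |log2FC| > 1 and adjusted p < 0.001 (candidate set)
* relaxed DEGs:  |log2FC| > 1 and raw p < 0.01 (clustering / network set)
* background:    |log2FC| < 0.5 (motif-enrichment background)

All inequalities are strict.  Rows lacking the p-value a filter needs
(e.g. adjusted p set to NA by independent filtering) are excluded from
that filter and counted, so pass + fail + missing = input rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilterResult",
    "read_de_table",
    "filter_strict",
    "filter_relaxed",
    "background_set",
]

DE_COLUMNS = ["gene_id", "symbol", "log2fc", "pvalue", "padj"]


@dataclass(frozen=True)
class FilterResult:
    """Outcome of one threshold filter, with conserving counts."""

    genes: tuple[str, ...]
    n_input: int
    n_pass: int
    n_fail: int
    n_missing: int  # rows lacking the value the filter tests

    def __post_init__(self) -> None:
        assert self.n_pass + self.n_fail + self.n_missing == self.n_input

    @property
    def gene_set(self) -> frozenset:
        return frozenset(self.genes)


def read_de_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"DE table {path!r} lacks required columns {missing}")
    return df


def _apply(table: pd.DataFrame, required: list[str], mask_fn) -> FilterResult:
    n = len(table)
    ok = np.ones(n, dtype=bool)
    for col in required:
        ok &= table[col].notna().to_numpy()
    passed = np.zeros(n, dtype=bool)
    if ok.any():
        passed[ok] = mask_fn(table[ok]).to_numpy()
    genes = tuple(table.loc[passed, "gene_id"].astype(str))
    return FilterResult(
        genes=genes,
        n_input=n,
        n_pass=int(passed.sum()),
        n_fail=int((ok & ~passed).sum()),
        n_missing=int((~ok).sum()),
    )


def filter_strict(table: pd.DataFrame) -> FilterResult:
    """Strict DEG set: |log2FC| > 1 and adjusted p < 0.001."""
    return _apply(
        table,
        ["log2fc", "padj"],
        lambda t: (t["log2fc"].abs() > 1.0) & (t["padj"] < 0.001),
    )


def filter_relaxed(table: pd.DataFrame) -> FilterResult:
    """Relaxed DEG set: |log2FC| > 1 and raw p < 0.01."""
    return _apply(
        table,
        ["log2fc", "pvalue"],
        lambda t: (t["log2fc"].abs() > 1.0) & (t["pvalue"] < 0.01),
    )


def background_set(table: pd.DataFrame) -> FilterResult:
    """Motif-enrichment background: |log2FC| < 0.5."""
    return _apply(table, ["log2fc"], lambda t: t["log2fc"].abs() < 0.5)
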