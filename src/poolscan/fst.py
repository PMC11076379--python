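"""Pool-seq allele frequencies and the case-vs-virtual-control FST estimator.

Allele frequencies are estimated per pool directly from the allelic depths
(AD) of a multi-sample VCF: ``p_k = R_alt / (R_ref + R_alt)``.  The control
pools genotyped at a locus are merged into a single *virtual control pool*
whose frequency is the unweighted mean of the called control-pool
frequencies and whose size is the sum of their individual counts.  The
locus-wise fixation index between the case (seizure) pool and the virtual
control pool is then

    FST = [ pbar(1-pbar) - (n_SE p_SE(1-p_SE) + n_CO p_CO(1-p_CO))/(n_SE+n_CO) ]
          / [ pbar(1-pbar) ]

with the weighted mean frequency ``pbar = (n_SE p_SE + n_CO p_CO)/(n_SE+n_CO)``.
The weights are individual counts (22 cases; 10 per control pool, up to 40),
not chromosome counts.  By concavity of p(1-p) the numerator is
non-negative, so FST is confined to [0, 1]; it is 0 when the two pools agree
and 1 exactly at a fixed difference.  Loci monomorphic overall
(pbar in {0, 1}) have an undefined FST and are dropped with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = [
    "PoolSpec",
    "RunCounts",
    "estimate_pool_freq",
    "virtual_control",
    "fst_locus",
    "run_fst",
    "filter_high_fst",
    "read_pool_specs",
]

FST_COLUMNS = ["chrom", "pos", "ref", "alt", "p_SE", "p_CO", "n_CO", "p_bar", "fst"]


@dataclass(frozen=True)
class PoolSpec:
    """One sequenced DNA pool: VCF sample name, role and individual count."""

    name: str
    role: str  # "seizure" or "control"
    n: int

    def __post_init__(self) -> None:
        if self.role not in ("seizure", "control"):
            raise ValueError(f"pool {self.name!r}: role must be 'seizure' or 'control'")
        if self.n <= 0:
            raise ValueError(f"pool {self.name!r}: individual count must be > 0")


def validate_pools(pools: list[PoolSpec]) -> tuple[PoolSpec, list[PoolSpec]]:
    """Split specs into (seizure pool, control pools); exactly one seizure pool."""
    seizure = [p for p in pools if p.role == "seizure"]
    controls = [p for p in pools if p.role == "control"]
    if len(seizure) != 1:
        raise ValueError(f"exactly one seizure pool required, got {len(seizure)}")
    if not controls:
        raise ValueError("at least one control pool required")
    return seizure[0], controls


def read_pool_specs(path: str) -> list[PoolSpec]:
    """Read a pool-spec TSV with columns name, role, n (header required)."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "role", "n"}
    if not required.issubset(df.columns):
        raise ValueError(f"pool spec file needs columns {sorted(required)}")
    return [PoolSpec(str(r["name"]), str(r["role"]), int(r["n"])) for _, r in df.iterrows()]


def estimate_pool_freq(r_ref: int, r_alt: int) -> float:
    """Alternative-allele frequency of one pool from its allelic depths.

    Raises ``ValueError`` at zero total depth; callers treat such pools as
    missing rather than assigning a frequency.
    """
    total = r_ref + r_alt
    if r_ref < 0 or r_alt < 0:
        raise ValueError("allelic depths must be non-negative")
    if total <= 0:
        raise ValueError("zero total depth: pool is missing at this locus")
    return r_alt / total


def virtual_control(
    control_freqs: list[float] | np.ndarray, control_sizes: list[int] | np.ndarray
) -> tuple[float, int]:
    """Aggregate the called control pools into one virtual pool.

    Returns ``(p_CO, n_CO)``: the unweighted mean of the called control-pool
    frequencies and the summed individual count of those pools.
    """
    freqs = np.asarray(control_freqs, dtype=float)
    sizes = np.asarray(control_sizes, dtype=int)
    if freqs.size == 0:
        raise ValueError("no called control pools: locus must be skipped")
    if freqs.size != sizes.size:
        raise ValueError("control frequency and size lists differ in length")
    return float(freqs.mean()), int(sizes.sum())


def fst_locus(p_se, p_co, n_se, n_co):
    """Locus-wise FST between the case pool and the virtual control pool.

    Accepts scalars or numpy arrays (broadcast).  Returns NaN where the
    weighted mean frequency is 0 or 1 (monomorphic overall): the estimator
    has a zero denominator there and the locus is not variable.
    """
    p_se = np.asarray(p_se, dtype=float)
    p_co = np.asarray(p_co, dtype=float)
    n_se = np.asarray(n_se, dtype=float)
    n_co = np.asarray(n_co, dtype=float)
    n_tot = n_se + n_co
    p_bar = (n_se * p_se + n_co * p_co) / n_tot
    total_var = p_bar * (1.0 - p_bar)
    # numerator rewritten via the exact two-group variance decomposition
    # pbar(1-pbar) - within = n_SE n_CO (p_SE - p_CO)^2 / (n_SE + n_CO)^2,
    # which avoids catastrophic cancellation and is 0/1-exact at the corners
    between = n_se * n_co * (p_se - p_co) ** 2 / n_tot**2
    fst = np.where(total_var > 0.0, between / np.where(total_var > 0.0, total_var, 1.0), np.nan)
    fst = np.where(total_var > 0.0, np.clip(fst, 0.0, 1.0), np.nan)
    if fst.ndim == 0:
        return float(fst)
    return fst


def weighted_mean_freq(p_se, p_co, n_se, n_co):
    """The weighted mean frequency pbar used by the estimator."""
    n_se = np.asarray(n_se, dtype=float)
    n_co = np.asarray(n_co, dtype=float)
    out = (n_se * np.asarray(p_se, float) + n_co * np.asarray(p_co, float)) / (n_se + n_co)
    return float(out) if out.ndim == 0 else out


@dataclass
class RunCounts:
    """Per-stage accounting for one FST run (reconciles to the record total)."""

    n_records: int = 0
    n_non_snp: int = 0
    n_seizure_missing: int = 0
    n_insufficient_controls: int = 0
    n_monomorphic: int = 0
    n_rows: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)

    def reconciles(self) -> bool:
        return (
            self.n_non_snp
            + self.n_seizure_missing
            + self.n_insufficient_controls
            + self.n_monomorphic
            + self.n_rows
            == self.n_records
        )


def _pool_depths(ad_row) -> tuple[int, int] | None:
    """(ref, alt) depths for one sample, or None if the pool is not called."""
    if ad_row is None:
        return None
    r_ref, r_alt = int(ad_row[0]), int(ad_row[1])
    if r_ref < 0 or r_alt < 0:  # cyvcf2 encodes missing AD as negative
        return None
    if r_ref + r_alt <= 0:
        return None
    return r_ref, r_alt


def run_fst(
    vcf_path: str,
    pools: list[PoolSpec],
    min_control_pools: int = 1,
    min_depth: int = 1,
) -> tuple[pd.DataFrame, RunCounts]:
    """Estimate FST for every eligible biallelic SNP in a multi-sample VCF.

    A locus is eligible when the seizure pool and at least
    ``min_control_pools`` control pools are called (non-missing genotype with
    total allelic depth >= ``min_depth``).  Multi-allelic records and
    non-SNPs are skipped; all exclusions are counted in the returned
    :class:`RunCounts`.
    """
    seizure, controls = validate_pools(pools)
    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    missing = [p.name for p in pools if p.name not in samples]
    if missing:
        raise ValueError(f"pool samples absent from VCF: {missing}")
    se_idx = samples.index(seizure.name)
    co_idx = [samples.index(p.name) for p in controls]
    co_sizes = np.array([p.n for p in controls], dtype=int)

    counts = RunCounts()
    rows = []
    for var in vcf:
        counts.n_records += 1
        if len(var.ALT) != 1 or not var.is_snp:
            counts.n_non_snp += 1
            continue
        ad = var.format("AD")
        if ad is None:
            counts.n_seizure_missing += 1
            continue
        se_ad = _pool_depths(ad[se_idx])
        if se_ad is None or sum(se_ad) < min_depth:
            counts.n_seizure_missing += 1
            continue
        co_freqs, co_ns = [], []
        for j, idx in enumerate(co_idx):
            d = _pool_depths(ad[idx])
            if d is None or sum(d) < min_depth:
                continue
            co_freqs.append(estimate_pool_freq(*d))
            co_ns.append(co_sizes[j])
        if len(co_freqs) < max(min_control_pools, 1):
            counts.n_insufficient_controls += 1
            continue
        p_se = estimate_pool_freq(*se_ad)
        p_co, n_co = virtual_control(co_freqs, co_ns)
        value = fst_locus(p_se, p_co, seizure.n, n_co)
        if np.isnan(value):
            counts.n_monomorphic += 1
            continue
        counts.n_rows += 1
        rows.append(
            (
                var.CHROM,
                var.POS,
                var.REF,
                var.ALT[0],
                p_se,
                p_co,
                n_co,
                weighted_mean_freq(p_se, p_co, seizure.n, n_co),
                value,
            )
        )
    df = pd.DataFrame(rows, columns=FST_COLUMNS)
    logger.info(
        "fst: %d records, %d rows, skipped: %d non-SNP, %d seizure-missing, "
        "%d insufficient-controls, %d monomorphic",
        counts.n_records,
        counts.n_rows,
        counts.n_non_snp,
        counts.n_seizure_missing,
        counts.n_insufficient_controls,
        counts.n_monomorphic,
    )
    return df, counts


def filter_high_fst(results: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Rows with ``fst >= threshold`` (inclusive), in stable genomic order."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    out = results[results["fst"] >= threshold].copy()
    chrom_order = {c: i for i, c in enumerate(pd.unique(results["chrom"]))}
    out = out.sort_values(
        ["chrom", "pos"], key=lambda s: s.map(chrom_order) if s.name == "chrom" else s, kind="stable"
    )
    return out.reset_index(drop=True)
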