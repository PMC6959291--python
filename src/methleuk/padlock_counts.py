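"""Padlock bisulfite capture count processing.

Downstream of read mapping, a padlock methylation library reduces to
per-read records (cpg_id, sample_id, umi, methylated).  This module covers
the record-level steps: UMI deduplication (reads sharing a UMI within one
CpG/sample collapse to a single molecule), methylation-frequency extraction
(beta = methylated / total molecules), the coverage exclusion filter
(a CpG is dropped when *any* sample has fewer than ``min_reads`` molecules),
and bisulfite conversion-efficiency estimation from non-CpG cytosines.

UMI collisions between a methylated and an unmethylated read are resolved
by a first-seen-after-sort rule: records are stably sorted by
(cpg_id, sample_id, umi) and the first record of each UMI group survives.
The choice is a convention — the underlying chemistry does not dictate a
winner — but it makes deduplication deterministic and idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConversionCounts",
    "dedup_reads",
    "dedup_umis",
    "methylation_frequency",
    "coverage_filter",
    "conversion_efficiency",
]

RAW_COLUMNS = ["cpg_id", "sample_id", "umi", "methylated"]
AGG_COLUMNS = ["cpg_id", "sample_id", "meth_reads", "total_reads"]


def _check_raw(reads: pd.DataFrame) -> None:
    missing = [c for c in RAW_COLUMNS if c not in reads.columns]
    if missing:
        raise ValueError(f"raw read table is missing columns: {missing}")


def dedup_reads(reads: pd.DataFrame) -> pd.DataFrame:
    """Collapse PCR duplicates: keep one record per (cpg, sample, UMI).

    Stable-sorts by (cpg_id, sample_id, umi) and keeps the first record of
    each group, so the result is deterministic and a fixed point of the
    operation.
    """
    _check_raw(reads)
    ordered = reads.sort_values(["cpg_id", "sample_id", "umi"], kind="stable")
    return ordered.drop_duplicates(
        subset=["cpg_id", "sample_id", "umi"], keep="first"
    ).reset_index(drop=True)


def dedup_umis(reads: pd.DataFrame) -> pd.DataFrame:
    """UMI-deduplicate and aggregate to per-(CpG, sample) molecule counts.

    Returns a table with columns cpg_id, sample_id, meth_reads, total_reads
    where total_reads counts UMI-distinct molecules.
    """
    surviving = dedup_reads(reads)
    agg = (
        surviving.groupby(["cpg_id", "sample_id"], sort=True)["methylated"]
        .agg(meth_reads="sum", total_reads="count")
        .reset_index()
    )
    agg["meth_reads"] = agg["meth_reads"].astype(int)
    agg["total_reads"] = agg["total_reads"].astype(int)
    return agg


def methylation_frequency(counts: pd.DataFrame) -> pd.DataFrame:
    """Beta matrix (CpG × sample) from deduplicated counts.

    beta = meth_reads / total_reads; cells with zero (or absent) coverage
    are missing (NaN), never zero.
    """
    missing = [c for c in AGG_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"aggregated count table is missing columns: {missing}")
    if (counts["meth_reads"] > counts["total_reads"]).any():
        raise ValueError("meth_reads exceeds total_reads")
    counts = counts.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        counts["beta"] = np.where(
            counts["total_reads"] > 0,
            counts["meth_reads"] / counts["total_reads"].replace(0, np.nan),
            np.nan,
        )
    beta = counts.pivot(index="cpg_id", columns="sample_id", values="beta")
    beta.index.name = "cpg_id"
    beta.columns.name = None
    return beta


def coverage_filter(
    counts: pd.DataFrame, min_reads: int = 20
) -> tuple[set, set]:
    """Partition CpGs into (kept, dropped) by the any-sample coverage rule.

    A CpG is dropped iff its molecule count is below ``min_reads`` in at
    least one sample of the table; a (cpg, sample) pair absent from the
    table counts as zero coverage.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    missing = [c for c in AGG_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"aggregated count table is missing columns: {missing}")
    totals = counts.pivot_table(
        index="cpg_id", columns="sample_id", values="total_reads",
        aggfunc="sum", fill_value=0,
    )
    worst = totals.min(axis=1)
    kept = set(worst.index[worst >= min_reads])
    dropped = set(worst.index[worst < min_reads])
    return kept, dropped


@dataclass
class ConversionCounts:
    """Non-CpG cytosine conversion tallies for one library."""

    non_cpg_converted: int
    non_cpg_total: int

    def __post_init__(self) -> None:
        if self.non_cpg_total <= 0:
            raise ValueError("non_cpg_total must be positive")
        if not (0 <= self.non_cpg_converted <= self.non_cpg_total):
            raise ValueError("converted count must be between 0 and total")


def conversion_efficiency(cc: ConversionCounts) -> float:
    """Bisulfite conversion efficiency as a percentage.

    The fraction of non-CpG (CH-context) cytosines read as thymine; a
    per-library quality metric, typically expected above ~99.8%.
    """
    return 100.0 * cc.non_cpg_converted / cc.non_cpg_total
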