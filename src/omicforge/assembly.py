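"""Assembly-level summary statistics and expression-presence accounting.

Covers the descriptive layer of a de novo transcriptome resource: contig
length statistics (N50, mean/median, length-threshold counts), the arithmetic
behind a BUSCO completeness report, per-tissue expression-presence counts
(shared vs tissue-exclusive transcripts at an FPKM threshold) and the global
tissue-tissue correlation structure.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from ._cluster import linkage_matrix
from ._utils import percent, round_half_away, spearman_rows

__all__ = [
    "ContigStats",
    "BuscoSummary",
    "PresenceReport",
    "contig_stats",
    "busco_summary",
    "expression_presence",
    "tissue_correlation",
    "percent",
]


@dataclasses.dataclass(frozen=True)
class ContigStats:
    n_contigs: int
    n50_bp: int
    mean_bp: int
    median_bp: int
    max_bp: int
    n_gt_500: int
    n_gt_1000: int
    total_bp: int
    pct_gt_500: float
    pct_gt_1000: float

    def to_series(self) -> pd.Series:
        return pd.Series(dataclasses.asdict(self))


def contig_stats(lengths: Sequence[int]) -> ContigStats:
    """Summary statistics of contig lengths.

    N50 is the length L such that contigs of length >= L cumulatively cover at
    least half of the total assembled bases (descending-sort convention).
    Mean and median are rounded to whole base pairs (half away from zero;
    the median of an even count is the midpoint of the two central values).
    """
    arr = np.asarray(list(lengths), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("contig_stats requires at least one contig length")
    if (arr <= 0).any():
        raise ValueError("contig lengths must be positive integers")
    total = int(arr.sum())
    desc = np.sort(arr)[::-1]
    cum = np.cumsum(desc)
    n50 = int(desc[np.searchsorted(cum, total / 2.0)])
    n_gt_500 = int((arr > 500).sum())
    n_gt_1000 = int((arr > 1000).sum())
    return ContigStats(
        n_contigs=int(arr.size),
        n50_bp=n50,
        mean_bp=int(round_half_away(arr.mean())),
        median_bp=int(round_half_away(float(np.median(arr)))),
        max_bp=int(arr.max()),
        n_gt_500=n_gt_500,
        n_gt_1000=n_gt_1000,
        total_bp=total,
        pct_gt_500=percent(n_gt_500, arr.size, 1),
        pct_gt_1000=percent(n_gt_1000, arr.size, 1),
    )


@dataclasses.dataclass(frozen=True)
class BuscoSummary:
    total_groups: int
    complete_single: int
    complete_duplicated: int
    fragmented: int
    missing: int
    pct_single: float
    pct_duplicated: float
    pct_fragmented: float
    pct_missing: float
    completeness_percent: int


def busco_summary(total: int, single: int, duplicated: int, fragmented: int) -> BuscoSummary:
    """Derive the missing count and report percentages of a BUSCO tally.

    ``completeness_percent`` is the rounded percentage of complete (single +
    duplicated) ortholog groups.
    """
    if total <= 0:
        raise ValueError("total ortholog groups must be positive")
    if single + duplicated + fragmented > total:
        raise ValueError("BUSCO category counts exceed the total")
    missing = total - single - duplicated - fragmented
    return BuscoSummary(
        total_groups=total,
        complete_single=single,
        complete_duplicated=duplicated,
        fragmented=fragmented,
        missing=missing,
        pct_single=percent(single, total, 1),
        pct_duplicated=percent(duplicated, total, 1),
        pct_fragmented=percent(fragmented, total, 1),
        pct_missing=percent(missing, total, 1),
        completeness_percent=int(round_half_away((single + duplicated) / total * 100.0)),
    )


@dataclasses.dataclass(frozen=True)
class PresenceReport:
    n_genes: int
    per_tissue_active: pd.Series
    shared: int
    exclusive: int
    shared_pct: float
    exclusive_pct: float


def expression_presence(em: pd.DataFrame, active_threshold: float = 0.0) -> PresenceReport:
    """Count transcriptionally active genes per tissue and across tissues.

    A gene is active in a tissue when its FPKM is strictly greater than
    ``active_threshold``.  ``shared`` counts genes active in every tissue,
    ``exclusive`` genes active in exactly one; both are also reported as
    percentages of all genes (two decimals).
    """
    active = em.to_numpy() > active_threshold
    per_tissue = pd.Series(active.sum(axis=0), index=em.columns, name="active_genes")
    n_active_tissues = active.sum(axis=1)
    shared = int((n_active_tissues == em.shape[1]).sum())
    exclusive = int((n_active_tissues == 1).sum())
    n = em.shape[0]
    return PresenceReport(
        n_genes=n,
        per_tissue_active=per_tissue,
        shared=shared,
        exclusive=exclusive,
        shared_pct=percent(shared, n, 2),
        exclusive_pct=percent(exclusive, n, 2),
    )


def tissue_correlation(em: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Tissue-by-tissue Spearman correlation with average-linkage grouping.

    Returns the symmetric correlation matrix (unit diagonal) and a scipy
    linkage matrix over the tissues on distance 1 - rho.  Constant tissue
    columns yield undefined correlations, reported as NaN with a warning and
    treated as maximally distant for the grouping.
    """
    if em.shape[1] < 2:
        raise ValueError("tissue correlation requires at least two tissues")
    corr = spearman_rows(em.to_numpy().T)
    corr_df = pd.DataFrame(corr, index=em.columns, columns=em.columns)
    if np.isnan(corr).any():
        constant = [t for t, sd in zip(em.columns, em.to_numpy().std(axis=0)) if sd == 0]
        warnings.warn(
            f"constant expression in tissue(s) {constant}: correlations undefined",
            stacklevel=2,
        )
    dist = 1.0 - np.nan_to_num(corr, nan=-1.0)
    np.fill_diagonal(dist, 0.0)
    dist[dist < 1e-12] = 0.0
    return corr_df, linkage_matrix(dist, method="average")
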