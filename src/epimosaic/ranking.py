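"""Shared region ranking and permutation-FDR machinery.

Both region callers rank called regions by a summary statistic (cumulative
score for the trio caller, CpG count for the read-level caller) and estimate
a false discovery rate by re-running the full calling procedure on permuted
null datasets: for each unique statistic value ``s`` observed in the real
data, the FDR at threshold ``s`` is the average over permutations of

    (# null regions with statistic >= s) / (# real regions with statistic >= s)

capped at 1 and made monotone (a higher-scoring region never carries a
larger FDR than a lower-scoring one) by a step-up cumulative minimum from
the least strict threshold.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd


def rank_descending(stats: np.ndarray) -> np.ndarray:
    """Competition ranks for a statistic ranked high-to-low.

    Ties share the best ("lowest") rank: rank(v) = 1 + #{values > v}.
    """
    stats = np.asarray(stats)
    order = np.sort(stats)  # ascending
    # number of values strictly greater than v
    n_greater = len(stats) - np.searchsorted(order, stats, side="right")
    return (n_greater + 1).astype(int)


def _count_ge(sorted_stats: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """#{x in sorted_stats : x >= t} for each threshold (stats sorted asc)."""
    return len(sorted_stats) - np.searchsorted(sorted_stats, thresholds, side="left")


def permutation_fdr(
    real_stats: np.ndarray, null_stat_sets: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """FDR per unique real threshold, averaged over permutations.

    Returns ``(thresholds_desc, fdr)``.  Empty real input yields empty
    arrays; empty null sets contribute zero false positives.
    """
    real_stats = np.asarray(real_stats, dtype=float)
    if real_stats.size == 0:
        return np.empty(0), np.empty(0)
    thresholds = np.unique(real_stats)[::-1]  # descending: strictest first
    real_sorted = np.sort(real_stats)
    n_real = _count_ge(real_sorted, thresholds).astype(float)
    fdr = np.zeros_like(thresholds, dtype=float)
    n_perm = len(null_stat_sets)
    if n_perm:
        for null_stats in null_stat_sets:
            null_sorted = np.sort(np.asarray(null_stats, dtype=float))
            fdr += np.minimum(_count_ge(null_sorted, thresholds) / n_real, 1.0)
        fdr /= n_perm
    # monotone: fdr at a strict threshold never exceeds that at a looser one
    fdr = np.minimum.accumulate(fdr[::-1])[::-1]
    return thresholds, fdr


def attach_rank_and_fdr(
    regions: pd.DataFrame,
    null_stat_sets: Sequence[np.ndarray],
    stat_column: str,
) -> pd.DataFrame:
    """Annotate a region table with ``rank`` and ``fdr`` columns.

    ``null_stat_sets`` holds, per permutation, the statistic values of the
    regions called from that permuted dataset with identical parameters.
    A zero-region input returns an empty annotated table.
    """
    regions = regions.copy()
    if len(regions) == 0:
        regions["rank"] = pd.Series(dtype=int)
        regions["fdr"] = pd.Series(dtype=float)
        return regions
    stats = regions[stat_column].to_numpy(dtype=float)
    regions["rank"] = rank_descending(stats)
    thresholds, fdr = permutation_fdr(stats, null_stat_sets)
    # map each region to the FDR of its own statistic threshold
    idx = np.searchsorted(thresholds[::-1], stats, side="left")
    regions["fdr"] = fdr[::-1][idx]
    return regions.sort_values(["rank", "chrom", "start"], kind="mergesort").reset_index(drop=True)
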