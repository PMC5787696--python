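"""Cross-method and locus-level region analyses.

Covers three downstream questions: how much do two region sets (e.g. the
trio-based and the read-level calls) overlap; how quickly does a ranked
region list recover the known germline ASMs; and how does mean methylation
over the gASM intervals differ between cell lines (paired rank tests with
Bonferroni correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import overlaps_any


@dataclass(frozen=True)
class OverlapSummary:
    n_a: int
    n_b: int
    n_a_overlapping_b: int
    n_b_overlapping_a: int

    @property
    def fraction_a(self) -> float:
        return self.n_a_overlapping_b / self.n_a if self.n_a else float("nan")

    @property
    def fraction_b(self) -> float:
        return self.n_b_overlapping_a / self.n_b if self.n_b else float("nan")


def overlap_regions(set_a: pd.DataFrame, set_b: pd.DataFrame) -> OverlapSummary:
    """Count regions of each set sharing >= 1 base with any region of the
    other (1-based inclusive coordinates in both)."""
    return OverlapSummary(
        n_a=len(set_a),
        n_b=len(set_b),
        n_a_overlapping_b=int(overlaps_any(set_a, set_b).sum()),
        n_b_overlapping_a=int(overlaps_any(set_b, set_a).sum()),
    )


def recovery_curve(ranked_regions: pd.DataFrame, gasm_intervals: pd.DataFrame) -> pd.DataFrame:
    """Proportion of gASM intervals overlapped by >= 1 region of rank <= r,
    for every rank r present in the region table.  Non-decreasing in r."""
    ranks = np.sort(ranked_regions["rank"].unique())
    # best (lowest) rank of any region overlapping each interval
    best = np.full(len(gasm_intervals), np.inf)
    for r in ranks[::-1]:
        sub = ranked_regions[ranked_regions["rank"] <= r]
        hit = overlaps_any(gasm_intervals, sub)
        best[hit] = r
    props = [(int(r), float(np.mean(best <= r))) for r in ranks]
    return pd.DataFrame(props, columns=["rank", "proportion_identified"])


def mean_interval_methylation(sites: pd.DataFrame, chrom: str, start: int, end: int) -> float:
    """Unweighted mean methylation fraction over covered CpGs inside the
    1-based inclusive interval; NaN when no CpG is covered."""
    sub = sites[(sites["chrom"] == chrom) & (sites["pos"] >= start) & (sites["pos"] <= end)]
    if len(sub) == 0:
        return float("nan")
    frac = sub["meth_count"].to_numpy() / sub["total_count"].to_numpy()
    return float(np.mean(frac))


def interval_methylation_matrix(
    samples: Mapping[str, pd.DataFrame], intervals: pd.DataFrame
) -> pd.DataFrame:
    """Per-interval mean methylation for each sample: rows = interval names,
    columns = sample labels."""
    out = {}
    for label, sites in samples.items():
        out[label] = [
            mean_interval_methylation(sites, ivl.chrom, ivl.start, ivl.end)
            for ivl in intervals.itertuples(index=False)
        ]
    return pd.DataFrame(out, index=list(intervals["name"]))


def compare_gasm_methylation(means: pd.DataFrame) -> pd.DataFrame:
    """Pairwise paired Wilcoxon signed-rank tests between condition columns
    of a per-interval methylation matrix, Bonferroni-adjusted over the
    number of pairs.

    Intervals with a missing value in either member of a pair are dropped
    for that pair.  Identical paired vectors give p = 1.
    """
    conditions = list(means.columns)
    if len(conditions) < 2:
        raise ValueError("need >= 2 conditions to compare")
    n_pairs = len(list(combinations(conditions, 2)))
    rows = []
    for a, b in combinations(conditions, 2):
        paired = means[[a, b]].dropna()
        n = len(paired)
        if n < 5:
            warnings.warn(
                f"only {n} matched intervals for {a} vs {b}; rank test has little power",
                stacklevel=2,
            )
        diffs = paired[a].to_numpy() - paired[b].to_numpy()
        if n == 0 or np.allclose(diffs, 0.0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(paired[a], paired[b]).pvalue)
        rows.append((a, b, n, p, min(1.0, p * n_pairs)))
    return pd.DataFrame(rows, columns=["condition_a", "condition_b", "n", "p_value", "p_bonferroni"])
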