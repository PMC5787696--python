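"""Interval-membership and overlap queries over 1-based inclusive tables."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


def build_trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    """One IntervalTree per chromosome from a (chrom, start, end[, name])
    table; 1-based inclusive coordinates become half-open tree intervals."""
    trees: dict[str, IntervalTree] = {}
    for row in intervals.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end + 1, getattr(row, "name", None))
    return trees


def interval_membership(
    chroms: Sequence[str] | pd.Series,
    positions: Sequence[int] | pd.Series,
    intervals: pd.DataFrame,
) -> np.ndarray:
    """Boolean vector: does each (chrom, pos) point fall inside any interval?"""
    trees = build_trees(intervals)
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    out = np.zeros(len(chroms), dtype=bool)
    for chrom, tree in trees.items():
        mask = chroms == chrom
        if not mask.any():
            continue
        out[mask] = [bool(tree[p]) for p in positions[mask]]
    return out


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query interval: shares >= 1 base with any subject interval."""
    trees = build_trees(subject)
    out = np.zeros(len(query), dtype=bool)
    for i, row in enumerate(query.itertuples(index=False)):
        tree = trees.get(row.chrom)
        if tree is not None and tree.overlap(row.start, row.end + 1):
            out[i] = True
    return out
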