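"""NORED: detection of non-restored, DNMT1-dependent methylation regions.

The caller consumes a trio of methylation profiles from wild-type (WT),
DNMT1-null (1KO) and DNMT1-rescued (r1KO) cells.  A CpG is *non-restored*
when it is methylated in WT, loses essentially all methylation in the
knockout, and fails to regain it after DNMT1 re-expression — the behaviour
of germline allele-specific methylation (imprinting control regions), whose
one-allele methylation cannot be re-established by maintenance
methyltransferase activity alone.

Pipeline:

1. per-CpG criteria (defaults: WT >= 0.25, 1KO <= 0.05, r1KO <= 0.125, all
   inclusive) over the 5x-coverage-filtered autosomal CpG universe;
2. cutoff calibration by an ROC-like sweep whose false positive rate comes
   from label-swap permutations (condition labels shuffled independently at
   every CpG, 20 null datasets) and whose true positive rate is measured on
   known germline ASM intervals;
3. neighbourhood scoring: 2 points for a criteria-meeting CpG plus 1 point
   for each of its two preceding and two following criteria-meeting CpGs
   (maximum 6);
4. bump-hunting-style clustering of CpGs scoring >= 3 into regions, ranked
   by cumulative score;
5. permutation FDR: the identical score-and-cluster procedure applied to
   each label-swapped null dataset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .intervals import interval_membership
from .ranking import attach_rank_and_fdr

TRIPLET_COLUMNS = ["chrom", "pos", "m_wt", "m_ko", "m_rescue"]

#: the 6 ways of assigning three values to the three condition slots
_LABEL_PERMUTATIONS = np.array(list(itertools.permutations(range(3))))


@dataclass(frozen=True)
class NoredThresholds:
    """Per-CpG criteria for a non-restored call (all comparisons inclusive)."""

    wt_min: float = 0.25
    ko_max: float = 0.05
    rescue_max: float = 0.125
    min_coverage: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.ko_max <= self.rescue_max <= self.wt_min <= 1.0:
            raise ValueError(
                f"need 0 <= ko_max <= rescue_max <= wt_min <= 1, got "
                f"({self.wt_min}, {self.ko_max}, {self.rescue_max})"
            )


@dataclass(frozen=True)
class FprGridSpec:
    """Cutoff grid for the ROC-like permutation calibration.

    The rescue (r1KO) maximum is swept from each KO maximum up to each WT
    minimum in ``rescue_step`` increments.
    """

    wt_min_candidates: tuple[float, ...] = (0.25, 0.30)
    ko_max_candidates: tuple[float, ...] = (0.03, 0.05)
    rescue_step: float = 0.005
    n_permutations: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rescue_step <= 0:
            raise ValueError("rescue_step must be > 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def triplets_from_counts(
    counts: "dict[str, pd.DataFrame]",
    min_coverage: int = 5,
    wt: str = "WT", ko: str = "1KO", rescue: str = "r1KO",
    autosomes_only: bool = True,
) -> pd.DataFrame:
    """Coverage-filter destranded count tables for the three conditions and
    return the per-CpG methylation-fraction triplet table."""
    from .methio import filter_sites

    universe = filter_sites(counts, min_coverage=min_coverage,
                            required_samples=[wt, ko, rescue],
                            autosomes_only=autosomes_only)
    return triplets_from_universe(universe, wt=wt, ko=ko, rescue=rescue)


def triplets_from_universe(
    universe: pd.DataFrame, wt: str = "WT", ko: str = "1KO", rescue: str = "r1KO"
) -> pd.DataFrame:
    """Extract the (chrom, pos, m_wt, m_ko, m_rescue) table from a
    coverage-filtered universe built by :func:`epimosaic.methio.filter_sites`."""
    df = universe.reset_index()[["chrom", "pos"]].copy()
    df["m_wt"] = universe[f"frac_{wt}"].to_numpy()
    df["m_ko"] = universe[f"frac_{ko}"].to_numpy()
    df["m_rescue"] = universe[f"frac_{rescue}"].to_numpy()
    return df


def _validate_fractions(*arrays: np.ndarray) -> None:
    for arr in arrays:
        if arr.size and (np.nanmin(arr) < 0.0 or np.nanmax(arr) > 1.0):
            raise ValueError("methylation fractions must lie in [0, 1]")


def meets_nored_criteria(
    m_wt: np.ndarray | float,
    m_ko: np.ndarray | float,
    m_rescue: np.ndarray | float,
    thresholds: NoredThresholds = NoredThresholds(),
) -> np.ndarray | bool:
    """Inclusive three-way criteria test; vectorized over CpGs."""
    m_wt = np.asarray(m_wt, dtype=float)
    m_ko = np.asarray(m_ko, dtype=float)
    m_rescue = np.asarray(m_rescue, dtype=float)
    _validate_fractions(m_wt, m_ko, m_rescue)
    out = (
        (m_wt >= thresholds.wt_min)
        & (m_ko <= thresholds.ko_max)
        & (m_rescue <= thresholds.rescue_max)
    )
    return bool(out) if out.ndim == 0 else out


def permute_condition_labels(
    values: np.ndarray, n_permutations: int, seed: int
) -> Iterator[np.ndarray]:
    """Yield label-swapped null datasets.

    ``values`` is an (n_cpg, 3) array of (WT, KO, rescue) fractions.  For
    each permutation and each CpG independently the three values are
    reassigned to the three condition slots by a uniformly random label
    permutation, preserving the per-CpG value multiset.  Each permutation
    uses its own deterministic sub-stream of ``seed`` so permutation k is
    reproducible in isolation.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != 3:
        raise ValueError("values must have shape (n_cpg, 3)")
    row_idx = np.arange(len(values))[:, None]
    for child in np.random.SeedSequence(seed).spawn(n_permutations):
        rng = np.random.default_rng(child)
        choice = rng.integers(0, 6, size=len(values))
        yield values[row_idx, _LABEL_PERMUTATIONS[choice]]


def fraction_meeting(values: np.ndarray, thresholds: NoredThresholds) -> float:
    flags = meets_nored_criteria(values[:, 0], values[:, 1], values[:, 2], thresholds)
    return float(np.mean(flags))


def estimate_fpr_grid(triplets: pd.DataFrame, grid: FprGridSpec = FprGridSpec()) -> pd.DataFrame:
    """ROC-like calibration table over the cutoff grid.

    For every (wt_min, ko_max, rescue_max) combination, reports the fraction
    of universe CpGs meeting the criteria in the real data and the mean
    fraction over label-swapped null datasets (the FPR: every null positive
    is a false positive, every null negative a true negative).
    """
    if len(triplets) == 0:
        raise ValueError("empty CpG universe")
    values = triplets[["m_wt", "m_ko", "m_rescue"]].to_numpy(dtype=float)
    nulls = list(permute_condition_labels(values, grid.n_permutations, grid.seed))
    rows = []
    for wt_min in grid.wt_min_candidates:
        for ko_max in grid.ko_max_candidates:
            rescue_values = np.arange(ko_max, wt_min + grid.rescue_step / 2, grid.rescue_step)
            rescue_values = np.minimum(rescue_values.round(10), wt_min)
            for rescue_max in rescue_values:
                thr = NoredThresholds(wt_min=wt_min, ko_max=ko_max,
                                      rescue_max=float(rescue_max))
                real = fraction_meeting(values, thr)
                fpr = float(np.mean([fraction_meeting(nv, thr) for nv in nulls]))
                rows.append((wt_min, ko_max, float(rescue_max), real, fpr))
    return pd.DataFrame(
        rows,
        columns=["wt_min", "ko_max", "rescue_max", "fraction_meeting_real", "fpr"],
    )


def tpr_on_intervals(
    triplets: pd.DataFrame,
    thresholds: NoredThresholds,
    gasm_intervals: pd.DataFrame,
) -> tuple[float, int]:
    """Fraction of universe CpGs inside known gASM intervals that meet the
    criteria.  Returns ``(fraction, n_cpgs_in_intervals)``; the fraction is
    NaN when no universe CpG falls in any interval."""
    inside = interval_membership(triplets["chrom"], triplets["pos"], gasm_intervals)
    n_inside = int(inside.sum())
    if n_inside == 0:
        return float("nan"), 0
    sub = triplets[inside]
    flags = meets_nored_criteria(
        sub["m_wt"].to_numpy(), sub["m_ko"].to_numpy(), sub["m_rescue"].to_numpy(), thresholds
    )
    return float(np.mean(flags)), n_inside


# ---------------------------------------------------------------------------
# scoring and clustering
# ---------------------------------------------------------------------------

def score_cpgs(meets: np.ndarray) -> np.ndarray:
    """Neighbourhood score per CpG for one chromosome's ordered universe.

    score(i) = 2 * meets(i) + sum of meets over the two preceding and two
    following universe CpGs (fewer at chromosome ends).  Range 0..6.
    """
    f = np.asarray(meets, dtype=np.int64)
    if f.ndim != 1:
        raise ValueError("meets must be a 1-D flag vector")
    score = 2 * f
    n = len(f)
    if n == 0:
        return score
    for offset in (-2, -1, 1, 2):
        if offset > 0:
            score[: n - offset] += f[offset:] if offset < n else 0
        else:
            score[-offset:] += f[:offset]
    return score


def cluster_scored_cpgs(
    positions: np.ndarray,
    scores: np.ndarray,
    chrom: str,
    inclusion_cutoff: int = 3,
    max_gap: int = 300,
) -> pd.DataFrame:
    """Cluster CpGs scoring >= ``inclusion_cutoff`` into regions.

    Members are maximal position-ordered runs of qualifying CpGs whose
    consecutive members lie <= ``max_gap`` bp apart.  Region bounds are the
    first/last member CpG positions; ``cumulative_score`` sums member scores.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be > 0")
    positions = np.asarray(positions)
    scores = np.asarray(scores)
    keep = scores >= inclusion_cutoff
    pos_k = positions[keep]
    sc_k = scores[keep]
    cols = ["chrom", "start", "end", "n_cpg", "cumulative_score"]
    if pos_k.size == 0:
        return pd.DataFrame(columns=cols).astype(
            {"chrom": str, "start": int, "end": int, "n_cpg": int, "cumulative_score": int}
        )
    group = np.concatenate(([0], np.cumsum(np.diff(pos_k) > max_gap)))
    df = pd.DataFrame({"group": group, "pos": pos_k, "score": sc_k})
    agg = df.groupby("group").agg(
        start=("pos", "min"), end=("pos", "max"),
        n_cpg=("pos", "size"), cumulative_score=("score", "sum"),
    )
    agg.insert(0, "chrom", chrom)
    return agg.reset_index(drop=True)


def _regions_from_flags(triplets: pd.DataFrame, flags: np.ndarray,
                        inclusion_cutoff: int, max_gap: int) -> pd.DataFrame:
    parts = []
    chroms = triplets["chrom"].to_numpy()
    positions = triplets["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        scores = score_cpgs(flags[mask])
        parts.append(cluster_scored_cpgs(positions[mask], scores, str(chrom),
                                         inclusion_cutoff, max_gap))
    if not parts:
        return cluster_scored_cpgs(np.empty(0), np.empty(0), "", inclusion_cutoff, max_gap)
    return pd.concat(parts, ignore_index=True)


def rank_and_fdr_nored(
    real_regions: pd.DataFrame, null_region_sets: Sequence[pd.DataFrame | np.ndarray]
) -> pd.DataFrame:
    """Rank regions by descending cumulative score (ties share the best
    rank) and attach the permutation FDR at each region's score threshold."""
    null_stats = [
        (ns["cumulative_score"].to_numpy() if isinstance(ns, pd.DataFrame) else np.asarray(ns))
        for ns in null_region_sets
    ]
    return attach_rank_and_fdr(real_regions, null_stats, "cumulative_score")


@dataclass
class NoredResult:
    regions: pd.DataFrame
    per_cpg: pd.DataFrame
    null_regions: list[pd.DataFrame] = field(default_factory=list)


def call_nored(
    triplets: pd.DataFrame,
    thresholds: NoredThresholds = NoredThresholds(),
    n_permutations: int = 20,
    seed: int = 0,
    inclusion_cutoff: int = 3,
    max_gap: int = 300,
) -> NoredResult:
    """Full trio pipeline: criteria -> scores -> regions -> permutation FDR.

    ``triplets`` must be sorted by (chrom, pos) and coverage-filtered.
    """
    triplets = triplets.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    values = triplets[["m_wt", "m_ko", "m_rescue"]].to_numpy(dtype=float)
    flags = np.asarray(meets_nored_criteria(values[:, 0], values[:, 1], values[:, 2], thresholds))
    real_regions = _regions_from_flags(triplets, flags, inclusion_cutoff, max_gap)
    null_regions = []
    for null_values in permute_condition_labels(values, n_permutations, seed):
        null_flags = np.asarray(meets_nored_criteria(
            null_values[:, 0], null_values[:, 1], null_values[:, 2], thresholds))
        null_regions.append(_regions_from_flags(triplets, null_flags, inclusion_cutoff, max_gap))
    regions = rank_and_fdr_nored(real_regions, null_regions)
    per_cpg = triplets[["chrom", "pos"]].copy()
    per_cpg["meets"] = flags
    scores = np.empty(len(triplets), dtype=int)
    chroms = triplets["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        scores[mask] = score_cpgs(flags[mask])
    per_cpg["score"] = scores
    return NoredResult(regions=regions, per_cpg=per_cpg, null_regions=null_regions)
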