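"""MethylMosaic: genotype-free detection of bimodal read-level methylation.

At a locus with allele-specific methylation each sequencing read reports a
single DNA molecule, so roughly half the reads are nearly fully methylated
(the methylated allele) and half nearly unmethylated.  For every CpG site a
window of ±300 bp is examined and two quantities are computed over the reads
overlapping the window:

* hypomethylation index: proportion of reads with read-level methylation
  <= 10% (a read's methylation being methylated calls / total calls over the
  whole read);
* hypermethylation index: proportion of reads with read-level methylation
  >= 90%.

A CpG is *bimodal* when both indices fall inside [0.2, 0.75].  Consecutive
bimodal CpGs are merged into regions ranked by CpG count, and the FDR is
estimated from null datasets in which the methylation calls at each CpG are
shuffled among the reads covering it — a shuffle that preserves every
per-CpG methylation level exactly and can only destroy read-level
(molecule-level) structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .methio import MethRead
from .ranking import attach_rank_and_fdr

PERCPG_COLUMNS = ["chrom", "pos", "n_reads", "hypo_index", "hyper_index", "is_bimodal", "callable"]


@dataclass(frozen=True)
class IndexBounds:
    """Window geometry and cutoffs for the bimodality call."""

    flank: int = 300
    hypo_read_max: float = 0.10
    hyper_read_min: float = 0.90
    index_lower: float = 0.2
    index_upper: float = 0.75
    min_reads: int = 1
    min_cpgs_per_read: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.hypo_read_max < self.hyper_read_min <= 1.0:
            raise ValueError("need 0 <= hypo_read_max < hyper_read_min <= 1")
        if not 0.0 <= self.index_lower <= self.index_upper <= 1.0:
            raise ValueError("need 0 <= index_lower <= index_upper <= 1")
        if self.flank <= 0:
            raise ValueError("flank must be > 0")
        if self.min_reads < 1 or self.min_cpgs_per_read < 1:
            raise ValueError("min_reads and min_cpgs_per_read must be >= 1")


def read_methylation_fraction(read: MethRead) -> float:
    """Methylated calls / total calls over the whole read (not only calls
    inside any particular window)."""
    return read.methylation_fraction()


# ---------------------------------------------------------------------------
# flat per-chromosome representation
# ---------------------------------------------------------------------------

class ReadMatrix:
    """Column-oriented view of one chromosome's reads for fast windowing.

    Holds per-read span/call-count arrays and flat per-call arrays
    (position, state, owning read index).  The per-read methylation fraction
    is recomputed from the call states, so the same object can serve both
    the observed data and its within-CpG shuffles.
    """

    def __init__(self, chrom: str, span_start: np.ndarray, span_end: np.ndarray,
                 call_pos: np.ndarray, call_state: np.ndarray, call_read: np.ndarray):
        self.chrom = chrom
        self.span_start = span_start
        self.span_end = span_end
        self.call_pos = call_pos
        self.call_state = call_state
        self.call_read = call_read
        self.n_reads = len(span_start)
        self.n_calls_per_read = np.bincount(call_read, minlength=self.n_reads)

    @classmethod
    def from_reads(cls, reads: Sequence[MethRead], chrom: str) -> "ReadMatrix":
        sel = [r for r in reads if r.chrom == chrom and r.calls]
        span_start = np.array([r.span[0] for r in sel], dtype=np.int64)
        span_end = np.array([r.span[1] for r in sel], dtype=np.int64)
        call_pos = np.array([p for r in sel for p, _ in r.calls], dtype=np.int64)
        call_state = np.array([s for r in sel for _, s in r.calls], dtype=bool)
        call_read = np.array([i for i, r in enumerate(sel) for _ in r.calls], dtype=np.int64)
        return cls(chrom, span_start, span_end, call_pos, call_state, call_read)

    def fractions(self) -> np.ndarray:
        meth = np.bincount(self.call_read, weights=self.call_state, minlength=self.n_reads)
        with np.errstate(invalid="ignore"):
            return meth / self.n_calls_per_read

    def universe(self) -> np.ndarray:
        """Sorted unique CpG positions covered by at least one call."""
        return np.unique(self.call_pos)

    def shuffled(self, rng: np.random.Generator) -> "ReadMatrix":
        """Within-CpG shuffle: permute the call states at each CpG position
        among the reads covering it; read structure untouched."""
        n = len(self.call_pos)
        noise = rng.random(n)
        # random order within each position group vs canonical stable order
        random_within = np.lexsort((noise, self.call_pos))
        canonical = np.lexsort((np.arange(n), self.call_pos))
        new_state = np.empty(n, dtype=bool)
        new_state[canonical] = self.call_state[random_within]
        return ReadMatrix(self.chrom, self.span_start, self.span_end,
                          self.call_pos, new_state, self.call_read)

    def window_index_table(self, bounds: IndexBounds) -> pd.DataFrame:
        """Hypo/hyper indices for every universe CpG on this chromosome."""
        centers = self.universe()
        eligible = self.n_calls_per_read >= bounds.min_cpgs_per_read
        frac = self.fractions()
        lo = centers - bounds.flank
        hi = centers + bounds.flank

        def overlap_counts(mask: np.ndarray) -> np.ndarray:
            # reads overlap [lo, hi] iff span_start <= hi and span_end >= lo;
            # since start <= end, {end < lo} is a subset of {start <= hi}
            starts = np.sort(self.span_start[mask])
            ends = np.sort(self.span_end[mask])
            return (np.searchsorted(starts, hi, side="right")
                    - np.searchsorted(ends, lo, side="left"))

        n_all = overlap_counts(eligible)
        n_hypo = overlap_counts(eligible & (frac <= bounds.hypo_read_max))
        n_hyper = overlap_counts(eligible & (frac >= bounds.hyper_read_min))
        callable_ = n_all >= bounds.min_reads
        with np.errstate(invalid="ignore", divide="ignore"):
            hypo = np.where(callable_, n_hypo / n_all, np.nan)
            hyper = np.where(callable_, n_hyper / n_all, np.nan)
        bimodal = (
            callable_
            & (hypo >= bounds.index_lower) & (hypo <= bounds.index_upper)
            & (hyper >= bounds.index_lower) & (hyper <= bounds.index_upper)
        )
        return pd.DataFrame({
            "chrom": self.chrom, "pos": centers, "n_reads": n_all,
            "hypo_index": hypo, "hyper_index": hyper,
            "is_bimodal": bimodal, "callable": callable_,
        })

    def to_reads(self, read_ids: Sequence[str] | None = None) -> list[MethRead]:
        order = np.lexsort((self.call_pos, self.call_read))
        out: list[MethRead] = []
        boundaries = np.searchsorted(self.call_read[order], np.arange(self.n_reads + 1))
        for i in range(self.n_reads):
            sl = order[boundaries[i]:boundaries[i + 1]]
            calls = [(int(p), bool(s)) for p, s in zip(self.call_pos[sl], self.call_state[sl])]
            rid = read_ids[i] if read_ids is not None else f"read{i}"
            out.append(MethRead(rid, self.chrom, int(self.span_start[i]), "+", calls))
        return out


def _chromosomes(reads: Sequence[MethRead]) -> list[str]:
    seen: dict[str, None] = {}
    for r in reads:
        if r.calls:
            seen.setdefault(r.chrom, None)
    return sorted(seen)


def compute_window_indices(
    reads: Sequence[MethRead], center_pos: int, bounds: IndexBounds = IndexBounds(),
    chrom: str | None = None,
) -> dict:
    """Indices for a single window (±flank around ``center_pos``).

    Returns a dict with ``n_reads``, ``hypo_index``, ``hyper_index``,
    ``is_bimodal`` and ``callable``; the indices are NaN (and the CpG is
    uncallable, which is distinct from non-bimodal) when fewer than
    ``min_reads`` reads overlap the window.
    """
    if chrom is None:
        chroms = _chromosomes(reads)
        if len(chroms) != 1:
            raise ValueError("chrom must be given when reads span multiple chromosomes")
        chrom = chroms[0]
    rm = ReadMatrix.from_reads(reads, chrom)
    eligible = rm.n_calls_per_read >= bounds.min_cpgs_per_read
    frac = rm.fractions()
    in_window = (rm.span_start <= center_pos + bounds.flank) & \
                (rm.span_end >= center_pos - bounds.flank) & eligible
    n = int(in_window.sum())
    if n < bounds.min_reads:
        return {"n_reads": n, "hypo_index": float("nan"), "hyper_index": float("nan"),
                "is_bimodal": False, "callable": False}
    hypo = float(np.mean(frac[in_window] <= bounds.hypo_read_max))
    hyper = float(np.mean(frac[in_window] >= bounds.hyper_read_min))
    bimodal = (bounds.index_lower <= hypo <= bounds.index_upper
               and bounds.index_lower <= hyper <= bounds.index_upper)
    return {"n_reads": n, "hypo_index": hypo, "hyper_index": hyper,
            "is_bimodal": bimodal, "callable": True}


def window_index_table(reads: Sequence[MethRead], bounds: IndexBounds = IndexBounds()) -> pd.DataFrame:
    """Per-CpG diagnostic table over all chromosomes:
    ``chrom pos n_reads hypo_index hyper_index is_bimodal callable``."""
    parts = [ReadMatrix.from_reads(reads, c).window_index_table(bounds)
             for c in _chromosomes(reads)]
    if not parts:
        return pd.DataFrame(columns=PERCPG_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def shuffle_calls_within_cpg(reads: Sequence[MethRead], seed: int) -> list[MethRead]:
    """Null model: at every CpG position independently, permute the
    methylation calls among the reads covering it.

    Per-CpG methylated counts are exactly preserved; each read keeps its id,
    span and covered positions.  Chromosomes are processed in sorted order
    with deterministic sub-streams of ``seed``.
    """
    chroms = _chromosomes(reads)
    children = np.random.SeedSequence(seed).spawn(max(len(chroms), 1))
    out: list[MethRead] = []
    for chrom, child in zip(chroms, children):
        rm = ReadMatrix.from_reads(reads, chrom)
        ids = [r.read_id for r in reads if r.chrom == chrom and r.calls]
        out.extend(rm.shuffled(np.random.default_rng(child)).to_reads(ids))
    return out


# ---------------------------------------------------------------------------
# clustering, ranking, FDR
# ---------------------------------------------------------------------------

def cluster_consecutive_bimodal(per_cpg: pd.DataFrame, max_gap: int | None = None) -> pd.DataFrame:
    """Merge runs of consecutive bimodal CpGs into regions.

    Runs are taken over the *callable* universe: a callable non-bimodal CpG
    breaks a run, an uncallable (too few reads) CpG does not — missing data
    is evidence of nothing.  With a finite ``max_gap``, members further
    apart than that also split.  Region bounds are member CpG positions.
    """
    cols = ["chrom", "start", "end", "n_cpg"]
    parts = []
    for chrom, sub in per_cpg.groupby("chrom", sort=True):
        sub = sub[sub["callable"]].sort_values("pos")
        pos = sub["pos"].to_numpy()
        flags = sub["is_bimodal"].to_numpy(dtype=bool)
        if len(pos) == 0 or not flags.any():
            continue
        # run id increments wherever a callable non-bimodal CpG intervened
        run_id = np.cumsum(~flags)
        pos_b = pos[flags]
        run_b = run_id[flags]
        breaks = run_b[1:] != run_b[:-1]
        if max_gap is not None:
            breaks = breaks | (np.diff(pos_b) > max_gap)
        group = np.concatenate(([0], np.cumsum(breaks)))
        df = pd.DataFrame({"group": group, "pos": pos_b})
        agg = df.groupby("group").agg(start=("pos", "min"), end=("pos", "max"),
                                      n_cpg=("pos", "size"))
        agg.insert(0, "chrom", chrom)
        parts.append(agg.reset_index(drop=True))
    if not parts:
        return pd.DataFrame(columns=cols).astype(
            {"chrom": str, "start": int, "end": int, "n_cpg": int})
    return pd.concat(parts, ignore_index=True)


def rank_and_fdr_mosaic(
    real_regions: pd.DataFrame, null_region_sets: Sequence[pd.DataFrame | np.ndarray]
) -> pd.DataFrame:
    """Rank bimodal regions by descending CpG count (ties share the lowest
    rank) and attach the permutation FDR at each region's CpG-count
    threshold."""
    null_stats = [
        (ns["n_cpg"].to_numpy() if isinstance(ns, pd.DataFrame) else np.asarray(ns))
        for ns in null_region_sets
    ]
    return attach_rank_and_fdr(real_regions, null_stats, "n_cpg")


@dataclass
class MosaicResult:
    regions: pd.DataFrame
    per_cpg: pd.DataFrame
    null_regions: list[pd.DataFrame] = field(default_factory=list)


def call_mosaic(
    reads: Sequence[MethRead],
    bounds: IndexBounds = IndexBounds(),
    n_permutations: int = 10,
    seed: int = 0,
    max_gap: int | None = None,
) -> MosaicResult:
    """Full read-level pipeline: indices -> bimodal CpGs -> regions ->
    within-CpG-shuffle permutation FDR."""
    chroms = _chromosomes(reads)
    matrices = {c: ReadMatrix.from_reads(reads, c) for c in chroms}
    per_cpg = pd.concat(
        [matrices[c].window_index_table(bounds) for c in chroms], ignore_index=True
    ) if chroms else pd.DataFrame(columns=PERCPG_COLUMNS)
    real_regions = cluster_consecutive_bimodal(per_cpg, max_gap)
    null_regions = []
    for perm_seq in np.random.SeedSequence(seed).spawn(n_permutations):
        children = perm_seq.spawn(max(len(chroms), 1))
        null_parts = []
        for chrom, child in zip(chroms, children):
            null_rm = matrices[chrom].shuffled(np.random.default_rng(child))
            null_parts.append(null_rm.window_index_table(bounds))
        null_per_cpg = pd.concat(null_parts, ignore_index=True) if null_parts \
            else pd.DataFrame(columns=PERCPG_COLUMNS)
        null_regions.append(cluster_consecutive_bimodal(null_per_cpg, max_gap))
    regions = rank_and_fdr_mosaic(real_regions, null_regions)
    return MosaicResult(regions=regions, per_cpg=per_cpg, null_regions=null_regions)


def roc_select_bounds(
    reads: Sequence[MethRead],
    gasm_intervals: pd.DataFrame,
    lower_candidates: Sequence[float] = (0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3),
    upper_candidates: Sequence[float] = (0.5, 0.6, 0.7, 0.75, 0.8, 0.9, 1.0),
    bounds: IndexBounds = IndexBounds(),
    n_permutations: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """ROC table over candidate (lower, upper) index bounds.

    TPR = fraction of gASM intervals containing >= 1 bimodal CpG; FPR = mean
    over within-CpG-shuffle null datasets of the bimodal fraction of the
    callable CpG universe.  The same bounds apply to both indices.
    """
    chroms = _chromosomes(reads)
    matrices = {c: ReadMatrix.from_reads(reads, c) for c in chroms}
    real = pd.concat([matrices[c].window_index_table(bounds) for c in chroms],
                     ignore_index=True)
    nulls = []
    for perm_seq in np.random.SeedSequence(seed).spawn(n_permutations):
        children = perm_seq.spawn(max(len(chroms), 1))
        parts = [matrices[c].shuffled(np.random.default_rng(child)).window_index_table(bounds)
                 for c, child in zip(chroms, children)]
        nulls.append(pd.concat(parts, ignore_index=True))

    has_gasm = len(gasm_intervals) > 0

    def bimodal_mask(tab: pd.DataFrame, lower: float, upper: float) -> np.ndarray:
        return (
            tab["callable"].to_numpy()
            & (tab["hypo_index"].to_numpy() >= lower) & (tab["hypo_index"].to_numpy() <= upper)
            & (tab["hyper_index"].to_numpy() >= lower) & (tab["hyper_index"].to_numpy() <= upper)
        )

    rows = []
    for lower in lower_candidates:
        for upper in upper_candidates:
            if lower > upper:
                continue
            real_mask = bimodal_mask(real, lower, upper)
            if has_gasm:
                hits = 0
                sub = real[real_mask]
                for ivl in gasm_intervals.itertuples(index=False):
                    inside = sub[(sub["chrom"] == ivl.chrom)
                                 & (sub["pos"] >= ivl.start) & (sub["pos"] <= ivl.end)]
                    hits += int(len(inside) > 0)
                tpr = hits / len(gasm_intervals)
            else:
                tpr = float("nan")
            fprs = []
            for tab in nulls:
                mask = bimodal_mask(tab, lower, upper)
                n_callable = int(tab["callable"].sum())
                fprs.append(mask.sum() / n_callable if n_callable else 0.0)
            rows.append((lower, upper, tpr, float(np.mean(fprs)) if fprs else 0.0))
    return pd.DataFrame(rows, columns=["index_lower", "index_upper", "tpr", "fpr"])
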