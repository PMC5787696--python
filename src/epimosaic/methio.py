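"""Input/output and preprocessing for methylation call data.

This module owns the data formats every other module consumes:

* Bismark-style cytosine reports (per-cytosine counts, stranded), which are
  destranded into per-CpG count tables;
* a per-read methylation call TSV (one line per sequencing read, with the
  ordered CpG positions and their methylated/unmethylated states);
* BED interval files for known germline ASMs (gASMs) and for called regions.

Coordinate conventions
----------------------
Internally every position is 1-based and intervals are 1-based inclusive,
matching the ``chrN:start-end`` notation used for methylation regions in the
literature.  BED files are read and written in the standard 0-based
half-open convention and converted at the boundary.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FORWARD = "+"
REVERSE = "-"

#: chromosome names treated as autosomes by default ("chr7", "12", ...)
AUTOSOME_PATTERN = r"^(chr)?\d+$"

SITE_COLUMNS = ["chrom", "pos", "meth_count", "total_count"]


class CytosineReportError(ValueError):
    """Raised when a cytosine report line cannot be parsed."""


@dataclass(frozen=True)
class StrandedCytosineRecord:
    """One cytosine's methylation counts on one strand.

    ``pos`` is the 1-based coordinate of the cytosine itself; ``context`` is
    the trinucleotide context tag from the report (only ``CG`` records are
    retained downstream).
    """

    chrom: str
    pos: int
    strand: str
    meth_count: int
    unmeth_count: int
    context: str = "CG"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.meth_count < 0 or self.unmeth_count < 0:
            raise ValueError("negative methylation count")
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class MethRead:
    """A single sequencing read's ordered CpG methylation calls.

    ``calls`` is a list of ``(pos, state)`` with ``state`` True for
    methylated, sorted by position with no duplicates.  ``start`` is the
    first *sequenced* base of the read: for reverse-orientation reads this is
    the highest genomic coordinate, so that edge trimming can be expressed in
    the sequencing direction.
    """

    read_id: str
    chrom: str
    start: int
    orientation: str = FORWARD
    calls: list[tuple[int, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.calls]
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise ValueError(f"read {self.read_id}: calls must be position-sorted and unique")
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(f"read {self.read_id}: bad orientation {self.orientation!r}")

    @property
    def span(self) -> tuple[int, int]:
        """(min pos, max pos) over the read's calls; undefined if empty."""
        if not self.calls:
            raise ValueError(f"read {self.read_id} has no calls")
        return self.calls[0][0], self.calls[-1][0]

    @property
    def n_calls(self) -> int:
        return len(self.calls)

    def methylation_fraction(self) -> float:
        """Methylated calls / total calls over the whole read."""
        if not self.calls:
            raise ValueError(f"read {self.read_id} has no calls")
        return sum(state for _, state in self.calls) / len(self.calls)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

def read_cytosine_report(path: str | Path) -> Iterator[StrandedCytosineRecord]:
    """Stream a Bismark-style cytosine report.

    Expected columns (tab-separated):
    ``chrom  pos(1-based)  strand(+/-)  count_methylated  count_unmethylated
    context``.  Non-CpG contexts are passed through with their context tag so
    callers can filter.  Gzip input is handled transparently.
    """
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise CytosineReportError(
                    f"{path}: line {lineno}: expected >= 6 tab-separated fields, got {len(fields)}"
                )
            chrom, pos_s, strand, meth_s, unmeth_s, context = fields[:6]
            if strand not in (FORWARD, REVERSE):
                raise CytosineReportError(
                    f"{path}: line {lineno}: unknown strand symbol {strand!r}"
                )
            try:
                record = StrandedCytosineRecord(
                    chrom=chrom,
                    pos=int(pos_s),
                    strand=strand,
                    meth_count=int(meth_s),
                    unmeth_count=int(unmeth_s),
                    context=context,
                )
            except ValueError as exc:
                raise CytosineReportError(f"{path}: line {lineno}: {exc}") from exc
            yield record


def write_cytosine_report(records: Iterable[StrandedCytosineRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.strand}\t{rec.meth_count}\t"
                f"{rec.unmeth_count}\t{rec.context}\n"
            )


def destrand_cpgs(records: Iterable[StrandedCytosineRecord]) -> pd.DataFrame:
    """Merge strand-symmetric CpG calls into destranded per-CpG sites.

    A reverse-strand cytosine at position ``p`` belongs to the CpG dyad whose
    forward-strand C sits at ``p - 1``; counts from both strands are summed
    and reported at the forward-strand coordinate.  Non-CpG-context records
    are ignored.  Reverse-strand records with no forward partner are still
    emitted at ``pos - 1`` (logged), never dropped, so the total call count
    is conserved.

    Returns a DataFrame with columns ``chrom, pos, meth_count, total_count``
    sorted by (chrom, pos).
    """
    rows: dict[tuple[str, int], list[int]] = {}
    forward_seen: set[tuple[str, int]] = set()
    reverse_keys: list[tuple[str, int]] = []
    for rec in records:
        if rec.context != "CG":
            continue
        key = (rec.chrom, rec.pos if rec.strand == FORWARD else rec.pos - 1)
        if rec.strand == FORWARD:
            forward_seen.add(key)
        else:
            reverse_keys.append(key)
        counts = rows.setdefault(key, [0, 0])
        counts[0] += rec.meth_count
        counts[1] += rec.meth_count + rec.unmeth_count
    n_orphans = sum(1 for key in reverse_keys if key not in forward_seen)
    if n_orphans:
        logger.info("destrand_cpgs: %d reverse-strand records had no forward partner; "
                    "kept as their own sites at pos-1", n_orphans)
    if not rows:
        return pd.DataFrame(columns=SITE_COLUMNS).astype(
            {"chrom": str, "pos": int, "meth_count": int, "total_count": int}
        )
    data = sorted((c, p, m, t) for (c, p), (m, t) in rows.items())
    return pd.DataFrame(data, columns=SITE_COLUMNS)


def is_autosome(chroms: Sequence[str] | pd.Series, pattern: str = AUTOSOME_PATTERN) -> np.ndarray:
    regex = re.compile(pattern)
    return np.fromiter((bool(regex.match(c)) for c in chroms), dtype=bool, count=len(chroms))


def filter_sites(
    samples: Mapping[str, pd.DataFrame],
    min_coverage: int = 5,
    required_samples: Sequence[str] | None = None,
    autosomes_only: bool = True,
    autosome_pattern: str = AUTOSOME_PATTERN,
) -> pd.DataFrame:
    """Build the CpG universe: sites covered >= ``min_coverage`` in every
    required sample, optionally restricted to autosomes.

    ``samples`` maps sample label -> destranded site table.  Returns a wide
    DataFrame indexed by ``(chrom, pos)`` with per-sample ``meth_<label>``,
    ``total_<label>`` and ``frac_<label>`` columns.
    """
    if required_samples is None:
        required_samples = list(samples)
    missing = [s for s in required_samples if s not in samples]
    if missing:
        raise KeyError(f"required sample(s) missing: {missing}")
    merged: pd.DataFrame | None = None
    for label in required_samples:
        df = samples[label]
        part = df.set_index(["chrom", "pos"])[["meth_count", "total_count"]].rename(
            columns={"meth_count": f"meth_{label}", "total_count": f"total_{label}"}
        )
        merged = part if merged is None else merged.join(part, how="inner")
    assert merged is not None
    keep = np.ones(len(merged), dtype=bool)
    for label in required_samples:
        keep &= merged[f"total_{label}"].to_numpy() >= min_coverage
    merged = merged[keep]
    if autosomes_only and len(merged):
        chroms = merged.index.get_level_values("chrom")
        merged = merged[is_autosome(chroms, autosome_pattern)]
    merged = merged.sort_index()
    for label in required_samples:
        merged[f"frac_{label}"] = merged[f"meth_{label}"] / merged[f"total_{label}"]
    return merged


# ---------------------------------------------------------------------------
# per-read methylation calls
# ---------------------------------------------------------------------------

def trim_read_edge_calls(read: MethRead, n_bases: int = 8) -> MethRead:
    """Drop calls within the first ``n_bases`` of the read, counted from the
    sequencing start (guards against end-of-read methylation bias).

    Forward reads lose calls at ``start <= pos < start + n_bases``; reverse
    reads lose calls at ``start - n_bases < pos <= start``.  A read left with
    zero calls is returned empty; callers should exclude it.
    """
    if n_bases < 0:
        raise ValueError(f"n_bases must be >= 0, got {n_bases}")
    if n_bases == 0:
        return read
    if read.orientation == FORWARD:
        kept = [(p, s) for p, s in read.calls if p >= read.start + n_bases]
    else:
        kept = [(p, s) for p, s in read.calls if p <= read.start - n_bases]
    return replace(read, calls=kept)


def read_meth_reads(path: str | Path) -> list[MethRead]:
    """Parse the per-read call TSV:
    ``read_id  chrom  read_start  orientation  pos1:state1,pos2:state2,...``
    with state ``M`` (methylated) or ``U``.
    """
    reads: list[MethRead] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}: line {lineno}: expected 5 fields, got {len(fields)}")
            read_id, chrom, start_s, orientation, calls_s = fields
            calls: list[tuple[int, bool]] = []
            if calls_s:
                for token in calls_s.split(","):
                    pos_s, _, state = token.partition(":")
                    if state not in ("M", "U"):
                        raise ValueError(f"{path}: line {lineno}: bad call state {state!r}")
                    calls.append((int(pos_s), state == "M"))
            try:
                reads.append(MethRead(read_id, chrom, int(start_s), orientation, calls))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return reads


def write_meth_reads(reads: Iterable[MethRead], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for read in reads:
            calls = ",".join(f"{p}:{'M' if s else 'U'}" for p, s in read.calls)
            handle.write(f"{read.read_id}\t{read.chrom}\t{read.start}\t{read.orientation}\t{calls}\n")


# ---------------------------------------------------------------------------
# intervals and regions
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED6 into a 1-based inclusive interval table
    (``chrom, start, end, name``)."""
    rows = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: BED needs >= 3 columns")
            chrom, start0, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start0 + 1}-{end}"
            rows.append((chrom, start0 + 1, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]).astype(
        {"chrom": str, "start": int, "end": int, "name": str}
    )


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write a 1-based inclusive interval table as BED (0-based half-open)."""
    with _open_text(path, "wt") as handle:
        for row in intervals.itertuples(index=False):
            name = getattr(row, "name", None) or f"{row.chrom}:{row.start}-{row.end}"
            handle.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{name}\n")


def write_regions_bed(regions: pd.DataFrame, path: str | Path, stat_column: str = "cumulative_score") -> None:
    """Write called regions as BED6+ with extra columns
    ``n_cpg, <stat>, rank, fdr``; ordered by rank then coordinate."""
    df = regions.sort_values(["rank", "chrom", "start"], kind="mergesort")
    with _open_text(path, "wt") as handle:
        for row in df.itertuples(index=False):
            stat = getattr(row, stat_column)
            handle.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.chrom}:{row.start}-{row.end}\t"
                f"0\t.\t{row.n_cpg}\t{stat:g}\t{row.rank}\t{row.fdr:.6g}\n"
            )


def write_region_table(regions: pd.DataFrame, path: str | Path, stat_column: str = "cumulative_score") -> None:
    """Write the 1-based inclusive region table
    (``chrom start end n_cpg <stat> rank fdr``)."""
    cols = ["chrom", "start", "end", "n_cpg", stat_column, "rank", "fdr"]
    cols = list(dict.fromkeys(cols))  # stat may itself be n_cpg
    df = regions.sort_values(["rank", "chrom", "start"], kind="mergesort")
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_region_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
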