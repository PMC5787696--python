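"""Synthetic WGBS data with planted methylation locus classes.

The generator emulates the WT / DNMT1-null (1KO) / DNMT1-rescued (r1KO)
embryonic stem cell trio the region callers were designed for.  A simulated
chromosome carries:

* **restorable background** — normally methylated CpGs (WT ~0.8) that lose
  methylation in the knockout (~0.01) and regain roughly half of it after
  rescue (~0.45), mirroring the published genome-wide averages (WT 0.727,
  1KO 0.176 over all CpGs including resistant loci; r1KO 0.369, about half
  of WT);
* **non-restored loci** — methylated in WT, lost in 1KO and *not* recovered
  in r1KO (~0.02), the gASM/imprinting-control behaviour;
* **bimodal epiallele loci** — each DNA molecule carries either a
  hypermethylated (per-CpG 0.95) or a hypomethylated (0.05) epiallele, half
  and half, giving ~0.5 bulk methylation in WT with strongly bimodal
  read-level methylation;
* **uniform hypo / hyper loci** — single-epiallele controls.

Planted loci are CpG-island-like: CpG density inside a locus is a multiple
(default 8x) of the background density, as it is at real imprinting control
regions.  Bisulfite conversion failure and sequencing error are collapsed
into one symmetric call-flip probability.  Everything is deterministic
given the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import methio
from .methio import MethRead, StrandedCytosineRecord

BACKGROUND = "background_restorable"
NORED_LOCUS = "nored_locus"
BIMODAL_LOCUS = "bimodal_locus"
UNIFORM_HYPO = "uniform_hypo"
UNIFORM_HYPER = "uniform_hyper"
EXCHANGEABLE = "exchangeable_null"

CONDITIONS = ("WT", "1KO", "r1KO")

#: per-class, per-condition methylation probabilities (bulk level).  The
#: bimodal class bulk value is the epiallele mixture mean and is replaced by
#: molecule-level sampling in read simulation.
CLASS_METH_PROBS: dict[str, dict[str, float]] = {
    BACKGROUND: {"WT": 0.80, "1KO": 0.01, "r1KO": 0.45},
    NORED_LOCUS: {"WT": 0.80, "1KO": 0.01, "r1KO": 0.02},
    BIMODAL_LOCUS: {"WT": 0.50, "1KO": 0.01, "r1KO": 0.02},
    UNIFORM_HYPO: {"WT": 0.05, "1KO": 0.01, "r1KO": 0.05},
    UNIFORM_HYPER: {"WT": 0.95, "1KO": 0.01, "r1KO": 0.45},
}


@dataclass(frozen=True)
class Locus:
    cls: str
    start: int  # 1-based inclusive
    end: int


@dataclass
class SimScenario:
    """Study conditions for one simulated chromosome."""

    chrom: str = "chr1"
    chrom_length: int = 2_000_000
    cpg_density: float = 10.0          # expected background CpGs per kb
    locus_density_multiplier: float = 8.0  # CpG-island-like density in planted loci
    locus_plan: list[Locus] = field(default_factory=list)
    boundary_taper: int = 500  # linear ramp (bp) from background to locus methylation
    read_length: int = 100
    mean_coverage: float = 30.0
    bisulfite_error: float = 0.005     # symmetric call-flip probability
    epiallele_fraction: float = 0.5    # P(read carries the hyper epiallele)
    hyper_epiallele_p: float = 0.95
    hypo_epiallele_p: float = 0.05
    class_meth_probs: dict = field(default_factory=lambda: {
        cls: dict(p) for cls, p in CLASS_METH_PROBS.items()})
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.bisulfite_error, self.epiallele_fraction,
                  self.hyper_epiallele_p, self.hypo_epiallele_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.mean_coverage <= 0:
            raise ValueError("coverage must be > 0")
        spans = sorted((l.start, l.end) for l in self.locus_plan)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("planted locus spans must not overlap")


def planted_locus_plan(
    chrom_length: int = 2_000_000,
    locus_span: int = 2_000,
    n_nored: int = 20,
    n_bimodal: int = 20,
    n_uniform_hypo: int = 10,
    n_uniform_hyper: int = 10,
    margin: int = 10_000,
) -> list[Locus]:
    """Evenly spaced, interleaved plan of planted loci on one chromosome."""
    classes = ([NORED_LOCUS] * n_nored + [BIMODAL_LOCUS] * n_bimodal
               + [UNIFORM_HYPO] * n_uniform_hypo + [UNIFORM_HYPER] * n_uniform_hyper)
    # interleave classes so no class clusters at one chromosome end
    order = np.argsort(np.arange(len(classes)) % 4, kind="stable")
    interleaved = [classes[i] for i in np.argsort(order, kind="stable")]
    n = len(interleaved)
    if n == 0:
        return []
    starts = np.linspace(margin, chrom_length - margin - locus_span, n).astype(int)
    if n > 1 and np.any(np.diff(starts) <= locus_span):
        raise ValueError("chromosome too short for the requested locus plan")
    return [Locus(cls, int(s), int(s) + locus_span - 1)
            for cls, s in zip(interleaved, starts)]


def mosaic_benchmark_scenario(seed: int = 0, chrom_length: int = 2_000_000) -> SimScenario:
    """Standard read-level benchmark: 20 planted bimodal epiallele loci and
    20 single-epiallele control loci (10 hypo, 10 hyper) on one 2 Mb
    chromosome at 30x coverage."""
    plan = planted_locus_plan(chrom_length, n_nored=0, n_bimodal=20,
                              n_uniform_hypo=10, n_uniform_hyper=10)
    return SimScenario(chrom_length=chrom_length, locus_plan=plan, seed=seed)


def nored_benchmark_scenario(seed: int = 0, chrom_length: int = 2_000_000) -> SimScenario:
    """Standard trio benchmark: 20 planted non-restored loci against a
    restorable background on one 2 Mb chromosome at 30x coverage."""
    plan = planted_locus_plan(chrom_length, n_nored=20, n_bimodal=0,
                              n_uniform_hypo=0, n_uniform_hyper=0)
    return SimScenario(chrom_length=chrom_length, locus_plan=plan, seed=seed)


def truth_table(scenario: SimScenario) -> pd.DataFrame:
    """Planted-locus ground truth (SimTruth): class and span per locus."""
    rows = [(scenario.chrom, l.start, l.end, l.cls) for l in scenario.locus_plan]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _rng(scenario: SimScenario, stream: str) -> np.random.Generator:
    # independent deterministic sub-stream per component
    root = np.random.SeedSequence(scenario.seed)
    offsets = {"positions": 0, "counts": 1, "reads": 2, "null": 3}
    return np.random.default_rng(root.spawn(4)[offsets[stream]])


def _locus_class_per_position(scenario: SimScenario, positions: np.ndarray) -> np.ndarray:
    classes = np.array([BACKGROUND] * len(positions), dtype=object)
    for locus in scenario.locus_plan:
        classes[(positions >= locus.start) & (positions <= locus.end)] = locus.cls
    return classes


def _locus_weights(scenario: SimScenario, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-position locus class and taper weight.

    Methylation boundaries in real genomes are not step functions; the
    taper blends locus and background probabilities linearly over
    ``boundary_taper`` bp at each locus edge (weight 1 = pure locus).
    """
    classes = _locus_class_per_position(scenario, positions)
    w = np.zeros(len(positions))
    for locus in scenario.locus_plan:
        mask = (positions >= locus.start) & (positions <= locus.end)
        if scenario.boundary_taper > 0:
            dist = np.minimum(positions[mask] - locus.start + 1,
                              locus.end - positions[mask] + 1)
            w[mask] = np.clip(dist / scenario.boundary_taper, 0.0, 1.0)
        else:
            w[mask] = 1.0
    return classes, w


def _condition_probabilities(
    scenario: SimScenario, positions: np.ndarray, condition: str
) -> np.ndarray:
    classes, w = _locus_weights(scenario, positions)
    cls_p = np.array([scenario.class_meth_probs[c][condition] for c in classes])
    bg = scenario.class_meth_probs[BACKGROUND][condition]
    return w * cls_p + (1.0 - w) * bg


def simulate_cpg_positions(scenario: SimScenario) -> np.ndarray:
    """CpG dyad positions (forward-strand C, 1-based) from a Poisson point
    process at the background density, with the planted-locus density
    multiplier applied inside loci.  Positions are sorted, unique and >= 2 bp
    apart so neighbouring dyads never share a base."""
    if scenario.cpg_density <= 0:
        raise ValueError("cpg_density must be > 0")
    rng = _rng(scenario, "positions")
    per_bp = scenario.cpg_density / 1000.0
    segments: list[tuple[int, int, float]] = []
    cursor = 1
    for locus in sorted(scenario.locus_plan, key=lambda l: l.start):
        if locus.start > cursor:
            segments.append((cursor, locus.start - 1, per_bp))
        segments.append((locus.start, locus.end, per_bp * scenario.locus_density_multiplier))
        cursor = locus.end + 1
    if cursor <= scenario.chrom_length:
        segments.append((cursor, scenario.chrom_length, per_bp))
    positions: list[np.ndarray] = []
    for start, end, rate in segments:
        length = end - start + 1
        if length <= 0:
            continue
        n = rng.poisson(rate * length)
        positions.append(rng.integers(start, end + 1, size=n))
    if not positions:
        return np.empty(0, dtype=np.int64)
    pos = np.unique(np.concatenate(positions)).astype(np.int64)
    pos = pos[pos <= scenario.chrom_length - 1]  # leave room for the reverse-strand C
    keep = np.concatenate(([True], np.diff(pos) >= 2))
    pos = pos[keep]
    for locus in scenario.locus_plan:
        if not np.any((pos >= locus.start) & (pos <= locus.end)):
            import warnings
            warnings.warn(f"planted locus {locus} received zero CpGs", stacklevel=2)
    return pos


def effective_p(p: float, error: float) -> float:
    """Methylation probability after the symmetric call-flip error."""
    return p * (1.0 - error) + (1.0 - p) * error


def simulate_condition_counts(
    scenario: SimScenario, positions: np.ndarray | None = None
) -> dict[str, pd.DataFrame]:
    """Destranded per-CpG count tables for the three conditions.

    Per CpG and condition, the total count is Poisson(mean_coverage) and the
    methylated count Binomial(total, class probability adjusted by the flip
    error).  Returns ``{condition: site table}``.
    """
    if positions is None:
        positions = simulate_cpg_positions(scenario)
    rng = _rng(scenario, "counts")
    out: dict[str, pd.DataFrame] = {}
    for condition in CONDITIONS:
        p = effective_p(_condition_probabilities(scenario, positions, condition),
                        scenario.bisulfite_error)
        totals = rng.poisson(scenario.mean_coverage, size=len(positions))
        meth = rng.binomial(totals, p)
        out[condition] = pd.DataFrame({
            "chrom": scenario.chrom, "pos": positions,
            "meth_count": meth, "total_count": totals,
        })
    return out


def counts_to_stranded_records(
    sites: pd.DataFrame, seed: int = 0
) -> list[StrandedCytosineRecord]:
    """Split destranded per-CpG counts into forward/reverse cytosine-report
    records (the reverse-strand C at pos+1), for writing realistic stranded
    reports that destrand back to the input."""
    rng = np.random.default_rng(seed)
    records: list[StrandedCytosineRecord] = []
    for row in sites.itertuples(index=False):
        total_fwd = rng.binomial(row.total_count, 0.5)
        meth_fwd = rng.hypergeometric(row.meth_count, row.total_count - row.meth_count,
                                      total_fwd) if row.total_count else 0
        total_rev = row.total_count - total_fwd
        meth_rev = row.meth_count - meth_fwd
        records.append(StrandedCytosineRecord(row.chrom, int(row.pos), "+",
                                              int(meth_fwd), int(total_fwd - meth_fwd)))
        records.append(StrandedCytosineRecord(row.chrom, int(row.pos) + 1, "-",
                                              int(meth_rev), int(total_rev - meth_rev)))
    return records


def simulate_reads(
    scenario: SimScenario, positions: np.ndarray | None = None
) -> list[MethRead]:
    """WT read-level methylation calls.

    Reads are placed uniformly at mean_coverage.  Methylation probability is
    positional: each call is drawn at the WT probability of its CpG's locus
    class, so a molecule straddling a locus boundary carries the boundary
    within it (as real molecules do).  The one molecule-level property is
    the epiallele: each read is assigned hyper with probability
    ``epiallele_fraction``, and its calls *inside bimodal loci* are drawn
    from that epiallele's probability instead.  The flip error is then
    applied per call.  Reads with zero CpG calls are dropped.
    """
    if positions is None:
        positions = simulate_cpg_positions(scenario)
    rng = _rng(scenario, "reads")
    n_reads = int(round(scenario.chrom_length * scenario.mean_coverage / scenario.read_length))
    starts = np.sort(rng.integers(1, scenario.chrom_length - scenario.read_length + 2,
                                  size=n_reads))
    pos_classes, pos_w = _locus_weights(scenario, positions)
    pos_p = _condition_probabilities(scenario, positions, "WT")
    pos_is_bimodal = pos_classes == BIMODAL_LOCUS
    bg_wt = scenario.class_meth_probs[BACKGROUND]["WT"]
    hyper_allele = rng.random(n_reads) < scenario.epiallele_fraction
    allele_p = np.where(hyper_allele, scenario.hyper_epiallele_p, scenario.hypo_epiallele_p)
    lo = np.searchsorted(positions, starts, side="left")
    hi = np.searchsorted(positions, starts + scenario.read_length - 1, side="right")
    reads: list[MethRead] = []
    for i in range(n_reads):
        sl = slice(lo[i], hi[i])
        cpgs = positions[sl]
        if len(cpgs) == 0:
            continue
        # epiallele is the molecule-level property, tapered like any other
        # class effect at the locus edges
        p = np.where(pos_is_bimodal[sl],
                     pos_w[sl] * allele_p[i] + (1.0 - pos_w[sl]) * bg_wt,
                     pos_p[sl])
        meth = rng.random(len(cpgs)) < p
        flip = rng.random(len(cpgs)) < scenario.bisulfite_error
        meth = meth ^ flip
        reads.append(MethRead(f"r{i}", scenario.chrom, int(starts[i]), "+",
                              [(int(p_), bool(m)) for p_, m in zip(cpgs, meth)]))
    return reads


def exchangeable_null_counts(
    n_cpg: int, mean_coverage: float = 30.0, seed: int = 0,
    chrom: str = "chr1", beta_a: float = 0.4, beta_b: float = 0.4,
) -> pd.DataFrame:
    """A condition-exchangeable trio for FPR calibration checks.

    Each CpG draws three i.i.d. true methylation levels from a U-shaped
    Beta(a, b) (the bimodal landscape typical of WGBS) — one per condition —
    so the real data are distributionally identical to any label-swapped
    version of themselves.  Returns a triplet table (chrom, pos, m_wt, m_ko,
    m_rescue) of observed fractions at Poisson coverage.
    """
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(np.arange(1, max(10 * n_cpg, n_cpg + 1)),
                                   size=n_cpg, replace=False))
    p = rng.beta(beta_a, beta_b, size=(n_cpg, 3))
    totals = np.maximum(rng.poisson(mean_coverage, size=(n_cpg, 3)), 5)
    meth = rng.binomial(totals, p)
    frac = meth / totals
    return pd.DataFrame({
        "chrom": chrom, "pos": positions,
        "m_wt": frac[:, 0], "m_ko": frac[:, 1], "m_rescue": frac[:, 2],
    })


def write_simulation(scenario: SimScenario, out_dir: str | Path) -> dict[str, Path]:
    """Emit the full synthetic dataset: stranded cytosine reports per
    condition, the WT per-read call TSV, the truth BED and the scenario
    parameters.  Deterministic given the scenario seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    positions = simulate_cpg_positions(scenario)
    counts = simulate_condition_counts(scenario, positions)
    paths: dict[str, Path] = {}
    strand_rng = np.random.SeedSequence(scenario.seed).spawn(5)[4]
    strand_seeds = np.random.default_rng(strand_rng).integers(0, 2**31, size=len(CONDITIONS))
    for (condition, sites), sseed in zip(counts.items(), strand_seeds):
        path = out_dir / f"{condition}.cytosine_report.tsv"
        methio.write_cytosine_report(counts_to_stranded_records(sites, int(sseed)), path)
        paths[condition] = path
    reads = simulate_reads(scenario, positions)
    paths["reads"] = out_dir / "WT.reads.tsv"
    methio.write_meth_reads(reads, paths["reads"])
    paths["truth"] = out_dir / "truth.bed"
    methio.write_bed(truth_table(scenario), paths["truth"])
    paths["scenario"] = out_dir / "scenario.json"
    import json
    with open(paths["scenario"], "w") as handle:
        json.dump({**{k: v for k, v in asdict(scenario).items() if k != "locus_plan"},
                   "locus_plan": [asdict(l) for l in scenario.locus_plan]},
                  handle, indent=2)
    return paths
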