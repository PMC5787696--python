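# Methods

## Data model and coordinates

All positions are 1-based; intervals are 1-based inclusive internally and
converted to 0-based half-open at the BED boundary. Stranded cytosine
reports (Bismark layout: `chrom pos strand meth unmeth context`) are
destranded by summing the forward-strand C at *p* with the reverse-strand C
at *p + 1* into one CpG site at *p*. A reverse-strand record without a
forward partner is still emitted at *p − 1* (and logged) so that call
counts are conserved; silent loss would bias coverage filtering.
Destranding precedes the coverage filter — the filter is meant to act on
per-dyad depth, and the two orders differ only for dyads whose strands
individually fall below threshold. Both steps are independently callable,
so the other order remains available.

The CpG universe for the trio caller is the set of autosomal CpGs (name
whitelist, default regex `^(chr)?\d+$`, because "autosome" is a
genome-specific notion) with depth ≥ 5 in every one of WT, 1KO and r1KO.
Read-level data use a per-read TSV
(`read_id chrom read_start orientation pos:M|U,...`); `read_start` is the
first *sequenced* base, so edge trimming (default 8 bp, guarding against
end-of-read methylation bias) is defined in the sequencing direction for
either orientation.

## Trio caller (NORED)

A CpG is non-restored when m_WT ≥ `wt_min`, m_1KO ≤ `ko_max` and
m_r1KO ≤ `rescue_max` (defaults 0.25 / 0.05 / 0.125). All comparisons are
inclusive: the thresholds are phrased as "at least / at most" quantities.
The calibration sweep evaluates WT ∈ {0.25, 0.30}, 1KO ∈ {0.03, 0.05} and
the rescue bound from the 1KO to the WT value in 0.005 steps; for each
combination it reports the genome-wide fraction of CpGs meeting the
criteria in the observed data and the average fraction across 20 label-swap
permutations (the FPR — on permuted data every positive is false). The
permutation reassigns, independently at each CpG, the three observed
fractions to the three condition slots uniformly at random, preserving the
per-CpG value multiset exactly. TPR for the sweep is measured as the
criteria-meeting fraction of universe CpGs inside known germline-ASM
intervals.

Scoring: score(i) = 2·meets(i) + Σ meets(j) over the two preceding and two
following universe CpGs on the chromosome (maximum 6; chromosome ends
simply have fewer neighbours). Neighbourhood is adjacency in the filtered
universe with no distance cap — distance enters only at clustering. CpGs
with score ≥ 3 are clustered into maximal runs whose consecutive members
are ≤ `max_gap` apart (default 300 bp, the conventional bump-hunting gap;
no gap value is canonical, so it is exposed in the interface). Region
bounds are member CpG positions; the cumulative score (sum of member
scores) ranks regions, capturing both region size and the density of
criteria-meeting CpGs.

## Read-level caller (MethylMosaic)

A read's methylation is methylated calls / total calls over the *whole*
read, not only calls inside a window — read-level methylation is a
molecule property. For each CpG in the covered universe, reads overlapping
±`flank` (300 bp) by span contribute to the hypomethylation index
(proportion with read methylation ≤ 0.10) and hypermethylation index
(proportion ≥ 0.90); a CpG is bimodal when both indices lie within
[0.2, 0.75] — the same bounds for both indices. Windows with fewer than
`min_reads` reads are *uncallable*, which is distinct from non-bimodal:
an uncallable CpG does not break a run of consecutive bimodal CpGs
(missing data is evidence of nothing), while a callable non-bimodal CpG
does. `min_cpgs_per_read` defaults to 1; a ≥ 3-CpG read filter is useful
for display but discards most short-read information at ordinary CpG
densities. Single-CpG regions are retained and ranked last — the FDR
threshold, not a hard filter, removes them. Regions are ranked by CpG
count with ties sharing the best rank.

The null model shuffles, independently at every CpG position, the
methylation calls among the reads covering that position. Per-CpG
methylation levels are preserved exactly; only the co-occurrence of calls
along molecules can change, which is precisely the signal being tested.

## Ranking and permutation FDR

Both callers share one mechanism. Regions are ranked by their statistic
(cumulative score / CpG count) descending, ties sharing the best rank. For
each unique statistic value *s* in the real data,

FDR(*s*) = mean over permutations of
(#null regions with statistic ≥ *s*) / (#real regions ≥ *s*),

with each ratio capped at 1. The raw curve is made monotone — a
higher-scoring region never carries a larger FDR than a lower-scoring one —
by a step-up cumulative minimum from the least strict threshold, which only
ever lowers estimates. Each region receives the FDR of its own statistic.
Every permutation stream derives from one master seed via `SeedSequence`
spawning (one sub-stream per permutation, then per chromosome), so any
permutation is reproducible in isolation without generating the others.

## Synthetic WGBS generator

The generator emulates the WT/1KO/r1KO design on one chromosome with five
locus classes; defaults were fixed once from the published bulk methylation
levels of this system and typical mammalian genome geometry:

| parameter | default | rationale |
|---|---|---|
| background CpG density | 10 / kb | genome-wide mammalian average (~1 CpG / 100 bp) |
| locus density multiplier | 8× | planted loci are CpG-island-like, as imprinting control regions are |
| locus span | 2 kb | typical ICR scale |
| WT methylation | 0.80 | methylated-compartment level consistent with a 0.727 genome-wide mean that includes unmethylated islands |
| 1KO methylation | 0.01 | near-complete maintenance loss |
| r1KO background | 0.45 | rescue to roughly half of WT bulk (0.369 genome-wide vs 0.727) |
| r1KO non-restored | 0.02 | essentially no recovery at gASM-like loci (~0.05 observed) |
| epialleles | 0.95 / 0.05 at fraction 0.5 | one methylated and one unmethylated allele per cell |
| coverage | 30× Poisson per CpG and condition | ordinary WGBS depth |
| read length | 100 bp | short-read WGBS |
| call-flip error | 0.005 | bisulfite conversion failure and sequencing error collapsed into one symmetric probability, since the callers model neither explicitly |
| boundary taper | 500 bp linear | methylation boundaries in real genomes are gradual, not step functions |

Methylation probability is positional (each call drawn at its column's
class probability), so a molecule spanning a locus boundary carries the
boundary within it, as real molecules do. The single molecule-level
property is the epiallele: each read is assigned hyper or hypo once, and
its calls inside bimodal loci follow that allele (tapered at the edges
like every other class effect). Without the taper, a step boundary at an
unmethylated locus places pure-hypo and pure-hyper molecules in one
window — spatial mixing that the window indices cannot distinguish from
allelic mixing, and an asymmetry the shuffle null does not fully
reproduce; tapering removes the artifact at the source rather than
special-casing the caller. The island-level CpG density inside planted
loci matters for the same reason: with ~1 call per read, every read is
trivially "fully" methylated or unmethylated and the read-shuffle null
cannot be distinguished from the data.

Count tables are emitted as *stranded* cytosine reports (per-dyad totals
split binomially between strands, methylated calls hypergeometrically) so
the destranding path is exercised end to end; reads are emitted as the
per-read TSV; the planted-locus ground truth as BED. Everything is
deterministic given the scenario seed, with independent sub-streams for
positions, counts, reads and strand splitting.

A separate condition-exchangeable generator (each CpG draws three i.i.d.
true levels from a U-shaped Beta(0.4, 0.4), the typical WGBS methylation
landscape) provides data on which the label-swap FPR estimate must match
the realized positive fraction in expectation — the calibration check.

What the simulator does **not** emulate: sequence context and actual CpG
spacing of a reference genome, SNPs and strain hybrids, paired-end
fragment geometry, PCR duplicates, coverage biases, sloppy or asymmetric
conversion error, and partially methylated domains. Passing recovery tests
on these data therefore demonstrates the correctness and calibration of
the algorithms under their own model assumptions, not caller performance
on real WGBS libraries.

## Study conditions for the recovery benchmarks

The standard benchmarks (used by the test suite and `scripts/acceptance.py`)
run one 2 Mb chromosome at 30× with 20 planted loci of the focal class —
non-restored loci against restorable background for the trio caller
(recovery demanded at FDR ≤ 0.05 with CpG-level precision ≥ 0.95), bimodal
loci plus 20 single-epiallele control loci for the read-level caller
(recovery at FDR ≤ 0.2, the published operating point, with no control
locus called across five generator seeds). A 2 Mb chromosome keeps the
full pipeline — simulation, both callers, all permutations — at desk scale
while leaving ≥ 20 000 background CpGs for stable permutation tails.

## Numerical and degenerate-input conventions

* Inclusive comparisons at every threshold boundary.
* Methylation fractions are defined only where total counts are positive;
  windows below `min_reads` report NaN indices rather than zeros.
* Zero called regions is an empty result, not an error; an empty null
  region set contributes zero false positives.
* Region tables are sorted by (rank, chrom, start); equal-rank regions
  appear in coordinate order, making every output byte-deterministic.
* The FPR rescue-bound sweep rounds grid values to 10 decimals and clips
  at the WT bound to avoid floating-point overshoot.
* Paired Wilcoxon comparisons of per-interval means drop intervals missing
  in either member, return p = 1 for identical vectors, warn below 5
  matched intervals, and apply Bonferroni over the number of condition
  pairs.

## Known limitations

* The read-level caller's FDR is estimated at region-size thresholds; in
  data with strong spatial correlation of window indices, background runs
  of moderate size can sit near the 0.2 boundary (they do not in the
  benchmark conditions, but a stricter operating point costs little
  sensitivity at true epiallele loci).
* The window-overlap rule counts any span-overlapping read, including
  reads contributing no call inside the window; this matches the window
  definition but slightly dilutes indices at sharp coverage edges.
* TPR for calibration counts a gASM as identified by ≥ 1 bimodal CpG (or
  ≥ 1 criteria-meeting CpG) inside the interval; region-level definitions
  would be stricter.
* The FPR denominator is the callable/filtered universe, not all genomic
  CpGs; with deep uniform coverage the two converge.
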