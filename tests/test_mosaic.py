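"""Read-level indices, within-CpG shuffle null, clustering and region FDR."""

import numpy as np
import pandas as pd
import pytest

from epimosaic import mosaic
from epimosaic.mosaic import IndexBounds

from conftest import make_read, random_read_set


def naive_window_indices(reads, center, bounds):
    """Brute-force oracle: rescan every read against the window."""
    fractions = []
    for read in reads:
        if not read.calls or read.n_calls < bounds.min_cpgs_per_read:
            continue
        lo, hi = read.span
        if lo <= center + bounds.flank and hi >= center - bounds.flank:
            fractions.append(read.methylation_fraction())
    n = len(fractions)
    if n < bounds.min_reads:
        return {"n_reads": n, "hypo_index": float("nan"), "hyper_index": float("nan"),
                "is_bimodal": False, "callable": False}
    hypo = sum(f <= bounds.hypo_read_max for f in fractions) / n
    hyper = sum(f >= bounds.hyper_read_min for f in fractions) / n
    return {"n_reads": n, "hypo_index": hypo, "hyper_index": hyper,
            "is_bimodal": (bounds.index_lower <= hypo <= bounds.index_upper
                           and bounds.index_lower <= hyper <= bounds.index_upper),
            "callable": True}


def reads_with_fractions(fractions, center=1000, n_calls=20):
    """One read per requested methylation fraction, all overlapping center."""
    reads = []
    for i, frac in enumerate(fractions):
        n_meth = round(frac * n_calls)
        positions = center - 50 + np.arange(n_calls) * 5
        states = [True] * n_meth + [False] * (n_calls - n_meth)
        reads.append(make_read(f"r{i}", positions, states))
    return reads


class TestReadFraction:
    @pytest.mark.parametrize("states, expected", [
        ([True, True, True, False], 0.75),
        ([False, False], 0.0),
        ([True], 1.0),
    ])
    def test_fraction(self, states, expected):
        read = make_read("r", np.arange(1, len(states) + 1) * 10, states)
        assert mosaic.read_methylation_fraction(read) == expected

    def test_empty_read_is_error(self):
        with pytest.raises(ValueError):
            mosaic.read_methylation_fraction(make_read("r", [], []))


class TestIndexBounds:
    @pytest.mark.parametrize("kwargs", [
        {"hypo_read_max": 0.95},            # crosses hyper_read_min
        {"index_lower": 0.8},               # above index_upper
        {"flank": 0},
        {"min_reads": 0},
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            IndexBounds(**kwargs)


class TestWindowIndices:
    def test_mixed_window_is_bimodal(self):
        reads = reads_with_fractions([0.0] * 3 + [1.0] * 3 + [0.5] * 4)
        out = mosaic.compute_window_indices(reads, 1000)
        assert out["hypo_index"] == pytest.approx(0.3)
        assert out["hyper_index"] == pytest.approx(0.3)
        assert out["is_bimodal"]

    def test_uniformly_methylated_is_not_bimodal(self):
        out = mosaic.compute_window_indices(reads_with_fractions([1.0] * 10), 1000)
        assert out["hyper_index"] == 1.0 and not out["is_bimodal"]

    def test_extreme_epialleles_at_half(self):
        reads = reads_with_fractions([0.05, 0.05, 0.95, 0.95])
        out = mosaic.compute_window_indices(reads, 1000)
        assert out["hypo_index"] == out["hyper_index"] == 0.5
        assert out["is_bimodal"]

    def test_too_few_reads_is_uncallable_not_nonbimodal(self):
        reads = reads_with_fractions([0.5])
        out = mosaic.compute_window_indices(reads, 1000, IndexBounds(min_reads=2))
        assert not out["callable"] and np.isnan(out["hypo_index"])

    def test_matches_naive_rescan(self, rng):
        for _ in range(50):
            reads = random_read_set(rng, n_reads=40, n_cpgs=30, spacing=37)
            center = int(rng.integers(1, 1200))
            got = mosaic.compute_window_indices(reads, center, chrom="chr1")
            expected = naive_window_indices(reads, center, IndexBounds())
            assert got["n_reads"] == expected["n_reads"]
            assert got["is_bimodal"] == expected["is_bimodal"]
            for key in ("hypo_index", "hyper_index"):
                assert got[key] == pytest.approx(expected[key], nan_ok=True)

    def test_table_agrees_with_single_center_queries(self, rng):
        reads = random_read_set(rng, n_reads=60, n_cpgs=25)
        table = mosaic.window_index_table(reads)
        for row in table.sample(10, random_state=0).itertuples(index=False):
            single = mosaic.compute_window_indices(reads, row.pos, chrom="chr1")
            assert single["n_reads"] == row.n_reads
            assert single["hypo_index"] == pytest.approx(row.hypo_index, nan_ok=True)

    def test_index_sum_bounded_by_one(self, rng):
        for _ in range(20):
            table = mosaic.window_index_table(random_read_set(rng))
            callable_rows = table[table["callable"]]
            total = callable_rows["hypo_index"] + callable_rows["hyper_index"]
            assert (total <= 1.0 + 1e-12).all()


class TestShuffle:
    def per_cpg_meth_counts(self, reads):
        counts = {}
        for read in reads:
            for pos, state in read.calls:
                key = (read.chrom, pos)
                m, t = counts.get(key, (0, 0))
                counts[key] = (m + int(state), t + 1)
        return counts

    def test_preserves_per_cpg_counts_and_read_structure(self, rng):
        reads = random_read_set(rng, n_reads=50, n_cpgs=20)
        shuffled = mosaic.shuffle_calls_within_cpg(reads, seed=5)
        assert self.per_cpg_meth_counts(shuffled) == self.per_cpg_meth_counts(reads)
        for before, after in zip(reads, shuffled):
            assert before.read_id == after.read_id
            assert [p for p, _ in before.calls] == [p for p, _ in after.calls]

    def test_single_covering_read_unchanged(self):
        reads = [make_read("a", [100], [True])]
        assert mosaic.shuffle_calls_within_cpg(reads, seed=0)[0].calls == [(100, True)]

    def test_two_read_column_swaps(self):
        # R1=(M,M), R2=(U,U): null outcomes are per-column swaps; the
        # per-column multiset {M, U} is always preserved and both columns
        # get swapped for some seed.
        reads = [make_read("a", [10, 20], [True, True]),
                 make_read("b", [10, 20], [False, False])]
        seen = set()
        for seed in range(40):
            shuffled = mosaic.shuffle_calls_within_cpg(reads, seed=seed)
            states = tuple(s for r in shuffled for _, s in r.calls)
            assert states[0] != states[2] and states[1] != states[3]
            seen.add(states)
        assert len(seen) == 4  # all 2x2 column-swap combinations occur

    def test_reproducible(self, rng):
        reads = random_read_set(rng)
        a = mosaic.shuffle_calls_within_cpg(reads, seed=11)
        b = mosaic.shuffle_calls_within_cpg(reads, seed=11)
        assert a == b


def percpg_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "is_bimodal", "callable"]).assign(
        n_reads=10, hypo_index=0.5, hyper_index=0.5)


class TestClusterConsecutive:
    def test_consecutive_run(self):
        table = percpg_frame([("chr1", p, True, True) for p in (10, 20, 30)])
        regions = mosaic.cluster_consecutive_bimodal(table)
        assert regions.to_dict("records") == [
            {"chrom": "chr1", "start": 10, "end": 30, "n_cpg": 3}]

    def test_callable_nonbimodal_interrupts(self):
        table = percpg_frame([("chr1", 10, True, True), ("chr1", 20, False, True),
                              ("chr1", 30, True, True)])
        regions = mosaic.cluster_consecutive_bimodal(table)
        assert regions["n_cpg"].tolist() == [1, 1]

    def test_uncallable_does_not_interrupt(self):
        table = percpg_frame([("chr1", 10, True, True), ("chr1", 20, False, False),
                              ("chr1", 30, True, True)])
        regions = mosaic.cluster_consecutive_bimodal(table)
        assert regions.to_dict("records") == [
            {"chrom": "chr1", "start": 10, "end": 30, "n_cpg": 2}]

    def test_finite_max_gap_splits(self):
        table = percpg_frame([("chr1", 10, True, True), ("chr1", 5000, True, True)])
        assert len(mosaic.cluster_consecutive_bimodal(table, max_gap=300)) == 2
        assert len(mosaic.cluster_consecutive_bimodal(table)) == 1


class TestRankAndFdrMosaic:
    def region_frame(self, n_cpgs):
        n = len(n_cpgs)
        return pd.DataFrame({"chrom": "chr1", "start": np.arange(n) * 100 + 1,
                             "end": np.arange(n) * 100 + 50, "n_cpg": n_cpgs})

    def test_min_rank_ties(self):
        annotated = mosaic.rank_and_fdr_mosaic(self.region_frame([5, 3, 3, 1]), [])
        assert sorted(annotated["rank"].tolist()) == [1, 2, 2, 4]

    def test_worked_fdr_example(self):
        annotated = mosaic.rank_and_fdr_mosaic(
            self.region_frame([5, 3, 3, 1]), [np.array([1, 1])])
        by_n = annotated.set_index("n_cpg")["fdr"]
        assert by_n[5] == 0.0
        assert by_n[3].max() == 0.0
        assert by_n[1] == pytest.approx(0.5)

    def test_empty_nulls(self):
        annotated = mosaic.rank_and_fdr_mosaic(self.region_frame([4, 2]),
                                               [np.empty(0)] * 3)
        assert (annotated["fdr"] == 0.0).all()


class TestRocSelectBounds:
    @pytest.fixture
    def bimodal_reads(self, rng):
        # epiallele mixture around two CpG clusters
        reads = reads_with_fractions([0.0] * 5 + [1.0] * 5, center=1000)
        reads += [make_read(f"s{i}", 2000 + np.arange(10) * 6, [i % 2 == 0] * 10)
                  for i in range(10)]
        return reads

    def test_vacuous_bounds_hit_everything(self, bimodal_reads):
        gasm = pd.DataFrame([("chr1", 900, 1100, "g1")],
                            columns=["chrom", "start", "end", "name"])
        table = mosaic.roc_select_bounds(bimodal_reads, gasm,
                                         lower_candidates=[0.0], upper_candidates=[1.0],
                                         n_permutations=2, seed=0)
        assert table.iloc[0]["tpr"] == 1.0
        assert table.iloc[0]["fpr"] == 1.0

    def test_contradictory_bounds_call_nothing(self, bimodal_reads):
        gasm = pd.DataFrame([("chr1", 900, 1100, "g1")],
                            columns=["chrom", "start", "end", "name"])
        table = mosaic.roc_select_bounds(bimodal_reads, gasm,
                                         lower_candidates=[0.6], upper_candidates=[1.0],
                                         n_permutations=2, seed=0)
        # hypo + hyper <= 1 makes both indices > 0.5 impossible
        assert table.iloc[0]["tpr"] == 0.0 and table.iloc[0]["fpr"] == 0.0

    def test_empty_gasm_reports_fpr_only(self, bimodal_reads):
        table = mosaic.roc_select_bounds(
            bimodal_reads, pd.DataFrame(columns=["chrom", "start", "end", "name"]),
            lower_candidates=[0.2], upper_candidates=[0.75], n_permutations=2, seed=0)
        assert np.isnan(table.iloc[0]["tpr"]) and np.isfinite(table.iloc[0]["fpr"])


class TestCallMosaic:
    def test_planted_mixture_detected_and_uniform_not(self):
        # cluster A: epiallele mixture; cluster B: uniformly methylated
        reads = []
        for i in range(20):
            frac = 1.0 if i % 2 else 0.0
            states = [frac > 0.5] * 8
            reads.append(make_read(f"a{i}", 1000 + np.arange(8) * 40, states))
        for i in range(20):
            reads.append(make_read(f"b{i}", 9000 + np.arange(8) * 40, [True] * 8))
        result = mosaic.call_mosaic(reads, n_permutations=5, seed=2)
        assert len(result.regions) == 1
        region = result.regions.iloc[0]
        assert region["start"] == 1000 and region["n_cpg"] == 8
        assert region["fdr"] == 0.0
        uncalled = result.per_cpg[result.per_cpg["pos"] >= 9000]
        assert not uncalled["is_bimodal"].any()

    def test_empty_input(self):
        result = mosaic.call_mosaic([], n_permutations=2, seed=0)
        assert len(result.regions) == 0
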