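import math

import numpy as np
import pytest

from tilearray import (
    Cluster,
    GenomeLayout,
    InfeasibleRandomizationError,
    Interval,
    IntervalSet,
    McConfig,
    ValidationError,
    enrichment_test,
    exact_null_enumeration,
    mc_significance,
    overlap_bases,
    overlap_test,
    peaks_in_ranges,
    randomize_intervals,
)
from tilearray.interval_mc import cluster_peaks_by_chrom


def brute_force_overlap(a, b, length):
    """Per-base boolean membership oracle for overlap_bases."""
    cov_a = np.zeros(length, dtype=bool)
    cov_b = np.zeros(length, dtype=bool)
    for iv in a:
        cov_a[iv.start:iv.end] = True
    for iv in b:
        cov_b[iv.start:iv.end] = True
    return int((cov_a & cov_b).sum())


class TestRandomizeIntervals:
    def test_full_chromosome_interval_is_pinned(self, rng):
        layout = GenomeLayout([("c", 10)])
        iset = IntervalSet([Interval("c", 0, 10)], layout=layout)
        for _ in range(20):
            out = randomize_intervals(iset, layout, rng)
            assert out.intervals == [Interval("c", 0, 10)]

    def test_conservation_of_counts_and_lengths(self, tiny_layout, rng):
        ivs = [Interval("chrI", s, s + l) for s, l in
               [(0, 500), (1000, 250), (5000, 1250)]]
        ivs += [Interval("chrII", s, s + l) for s, l in [(10, 40), (100, 40)]]
        iset = IntervalSet(ivs, layout=tiny_layout)
        want = {c: sorted(a[:, 1] - a[:, 0]) for c, a in iset.by_chrom().items()}
        for _ in range(200):
            out = randomize_intervals(iset, tiny_layout, rng)
            got = out.by_chrom()
            assert set(got) == set(want)
            for c, arr in got.items():
                assert sorted(arr[:, 1] - arr[:, 0]) == want[c]
                assert (arr[:, 0] >= 0).all()
                assert (arr[:, 1] <= tiny_layout.length(c)).all()
                assert (arr[1:, 0] >= arr[:-1, 1]).all()  # pairwise disjoint

    def test_single_interval_start_is_uniform(self):
        """Length-1 interval on a length-5 chromosome: each start has
        frequency 1/5 within 3 sigma over 10,000 draws (exact-uniform oracle)."""
        layout = GenomeLayout([("c", 5)])
        iset = IntervalSet([Interval("c", 2, 3)], layout=layout)
        rng = np.random.default_rng(42)
        counts = np.zeros(5)
        n = 10_000
        for _ in range(n):
            out = randomize_intervals(iset, layout, rng)
            counts[out.intervals[0].start] += 1
        sigma = math.sqrt(0.2 * 0.8 / n)
        np.testing.assert_allclose(counts / n, 0.2, atol=3 * sigma)

    def test_infeasible_randomization_names_chromosome(self, rng):
        layout = GenomeLayout([("tight", 10)])
        iset = IntervalSet([Interval("tight", 0, 6), Interval("tight", 6, 10)])
        with pytest.raises(InfeasibleRandomizationError, match="tight"):
            randomize_intervals(
                IntervalSet(iset.intervals + [Interval("tight", 0, 1)]),
                layout, rng)


class TestScores:
    def test_peaks_in_ranges_direct(self):
        layout = GenomeLayout([("c", 100)])
        ranges = IntervalSet([Interval("c", 0, 10), Interval("c", 20, 30)],
                             layout=layout)
        assert peaks_in_ranges({"c": np.array([5, 15, 25])}, ranges) == 2

    def test_half_open_end_not_counted(self):
        layout = GenomeLayout([("c", 100)])
        ranges = IntervalSet([Interval("c", 0, 10)], layout=layout)
        assert peaks_in_ranges({"c": np.array([10])}, ranges) == 0
        assert peaks_in_ranges({"c": np.array([9])}, ranges) == 1

    def test_no_peaks(self):
        layout = GenomeLayout([("c", 100)])
        ranges = IntervalSet([Interval("c", 0, 10)], layout=layout)
        assert peaks_in_ranges({}, ranges) == 0

    def test_overlap_bases_examples(self):
        layout = GenomeLayout([("c", 100)])
        a = IntervalSet([Interval("c", 0, 10)], layout=layout)
        b = IntervalSet([Interval("c", 5, 15)], layout=layout)
        assert overlap_bases(a, b) == 5
        assert overlap_bases(a, a) == 10

    def test_overlap_bases_matches_per_base_oracle(self, rng):
        layout = GenomeLayout([("c", 200)])
        for _ in range(50):
            a = [Interval("c", int(s), int(s) + int(l))
                 for s, l in zip(rng.integers(0, 190, 20), rng.integers(1, 10, 20))]
            b = [Interval("c", int(s), int(s) + int(l))
                 for s, l in zip(rng.integers(0, 190, 20), rng.integers(1, 10, 20))]
            sa, sb = IntervalSet(a, layout=layout), IntervalSet(b, layout=layout)
            assert overlap_bases(sa, sb) == brute_force_overlap(a, b, 200)


class TestMcSignificance:
    def test_closed_form_z_two(self):
        null = np.array([10.0] * 2)  # mean/sd supplied through synthetic draws
        # construct null draws with mean 10 and sd 2 exactly
        null = np.array([8.0, 12.0, 8.0, 12.0, 8.0, 12.0, 8.0, 12.0])
        sd = null.std(ddof=1)
        res = mc_significance(10 + 2 * sd, null, direction="enrichment")
        assert res.z == pytest.approx(2.0)
        assert res.p_normal == pytest.approx(0.02275, abs=2e-5)
        assert res.ratio == pytest.approx((10 + 2 * sd) / 10)

    def test_observed_equals_mean(self):
        res = mc_significance(5.0, [4.0, 6.0, 5.0, 5.0], direction="enrichment")
        assert res.z == 0.0
        assert res.p_normal == 0.5

    def test_degenerate_identical_null(self):
        res = mc_significance(7.0, [7.0] * 10)
        assert res.degenerate
        assert res.p_normal == 1.0
        assert res.p_empirical == 1.0

    def test_empirical_p_never_zero(self):
        res = mc_significance(1e9, np.arange(100.0), direction="enrichment")
        assert res.p_empirical == pytest.approx(1 / 101)

    def test_depletion_direction(self):
        null = np.array([8.0, 12.0] * 50)
        res = mc_significance(4.0, null, direction="auto")
        assert res.direction == "depletion"
        assert res.p_normal < 0.05

    def test_too_few_null_scores_rejected(self):
        with pytest.raises(ValidationError):
            mc_significance(1.0, [1.0])


class TestExactEnumeration:
    def test_toy_instance(self):
        layout = GenomeLayout([("c", 6)])
        iset = IntervalSet([Interval("c", 0, 3)], layout=layout)
        mean, sd = exact_null_enumeration(iset, {"c": np.array([0, 4])}, layout)
        assert mean == pytest.approx(0.75)
        assert sd == pytest.approx(math.sqrt(0.1875), abs=1e-9)

    def test_no_fixed_peaks(self):
        layout = GenomeLayout([("c", 6)])
        iset = IntervalSet([Interval("c", 0, 3)], layout=layout)
        assert exact_null_enumeration(iset, {}, layout) == (0.0, 0.0)

    def test_pinned_interval_has_zero_sd(self):
        layout = GenomeLayout([("c", 6)])
        iset = IntervalSet([Interval("c", 0, 6)], layout=layout)
        mean, sd = exact_null_enumeration(iset, {"c": np.array([2])}, layout)
        assert (mean, sd) == (1.0, 0.0)

    def test_bases_score_against_mc(self):
        layout = GenomeLayout([("c", 50)])
        iset = IntervalSet([Interval("c", 0, 7)], layout=layout)
        fixed = IntervalSet([Interval("c", 10, 20), Interval("c", 35, 40)],
                            layout=layout)
        mean, sd = exact_null_enumeration(iset, fixed, layout, score="bases")
        rng = np.random.default_rng(3)
        draws = np.array([
            overlap_bases(randomize_intervals(iset, layout, rng), fixed)
            for _ in range(4000)
        ])
        assert draws.mean() == pytest.approx(mean, abs=3 * sd / math.sqrt(4000))

    def test_too_many_placements_rejected(self):
        layout = GenomeLayout([("c", 1_000_000)])
        iset = IntervalSet([Interval("c", 0, 10)], layout=layout)
        with pytest.raises(ValidationError, match="Monte-Carlo"):
            exact_null_enumeration(iset, {}, layout)


class TestEnrichmentTest:
    def test_mc_matches_exact_toy_instance(self):
        layout = GenomeLayout([("c", 6)])
        features = IntervalSet([Interval("c", 0, 3)], layout=layout)
        peaks = {"c": np.array([0, 4])}
        res = enrichment_test(peaks, features, layout,
                              McConfig(n_randomizations=1000, seed=11))
        se_mean = 0.4330 / math.sqrt(1000)
        assert res.null_mean == pytest.approx(0.75, abs=3 * se_mean)
        assert res.null_sd == pytest.approx(0.4330, abs=3 * 0.4330 / math.sqrt(2 * 999))

    def test_whole_genome_features_degenerate(self):
        layout = GenomeLayout([("c", 100)])
        features = IntervalSet([Interval("c", 0, 100)], layout=layout)
        res = enrichment_test({"c": np.array([1, 50, 99])}, features, layout,
                              McConfig(n_randomizations=50, seed=0))
        assert res.degenerate
        assert res.observed == 3

    def test_zero_peaks_degenerate(self):
        layout = GenomeLayout([("c", 100)])
        features = IntervalSet([Interval("c", 0, 10)], layout=layout)
        res = enrichment_test({}, features, layout, McConfig(n_randomizations=50, seed=0))
        assert res.degenerate and res.observed == 0

    def test_seed_reproducibility_bit_identical(self):
        layout = GenomeLayout([("c", 10_000)])
        features = IntervalSet([Interval("c", s, s + 100) for s in
                                range(0, 3000, 500)], layout=layout)
        peaks = {"c": np.arange(0, 10_000, 777)}
        cfg = McConfig(n_randomizations=200, seed=123)
        r1 = enrichment_test(peaks, features, layout, cfg)
        r2 = enrichment_test(peaks, features, layout, cfg)
        assert np.array_equal(r1.null_scores, r2.null_scores)
        assert r1.to_dict() == r2.to_dict()

    def test_randomize_peaks_mode(self):
        layout = GenomeLayout([("c", 10_000)])
        features = IntervalSet([Interval("c", 0, 1000)], layout=layout)
        clusters = [
            Cluster(Interval("c", s, s + 200), peak=s + 50, max_signal=1.0, min_p=0.01)
            for s in (100, 2000, 5000, 8000)
        ]
        res = enrichment_test(clusters, features, layout,
                              McConfig(n_randomizations=300, seed=5),
                              randomize="peaks")
        # each cluster's peak lands in [0,1000) with prob ~ (1000+..)/10000
        assert 0 < res.null_mean < 4
        assert res.observed == 1


class TestOverlapTest:
    def test_self_overlap_is_enriched_both_ways(self):
        layout = GenomeLayout([("c", 10_000)])
        a = IntervalSet([Interval("c", s, s + 500) for s in range(0, 10_000, 1000)],
                        layout=layout)
        res_a, res_b = overlap_test(a, a, layout, McConfig(n_randomizations=200, seed=9))
        assert res_a.observed == res_b.observed == 5000
        assert res_a.z > 0 and res_b.z > 0

    def test_disjoint_singletons_not_enriched(self):
        layout = GenomeLayout([("c", 100_000)])
        a = IntervalSet([Interval("c", 10, 11)], layout=layout)
        b = IntervalSet([Interval("c", 50_000, 50_001)], layout=layout)
        res_a, _ = overlap_test(a, b, layout,
                                McConfig(n_randomizations=200, seed=2,
                                         direction="enrichment"))
        assert res_a.observed == 0
        assert res_a.p_empirical > 0.9

    def test_results_reported_independently(self):
        layout = GenomeLayout([("c", 50_000)])
        a = IntervalSet([Interval("c", s, s + 2000) for s in range(0, 20_000, 4000)],
                        layout=layout)
        b = IntervalSet([Interval("c", s + 500, s + 1500) for s in
                         range(0, 20_000, 4000)], layout=layout)
        res_a, res_b = overlap_test(a, b, layout, McConfig(n_randomizations=150, seed=4))
        assert res_a.observed == res_b.observed
        assert not np.array_equal(res_a.null_scores, res_b.null_scores)


class TestClusterPeaksByChrom:
    def test_grouping(self):
        cls = [Cluster(Interval("b", 0, 10), 5, 1.0, 0.1),
               Cluster(Interval("a", 0, 10), 2, 1.0, 0.1),
               Cluster(Interval("a", 20, 30), 25, 1.0, 0.1)]
        got = cluster_peaks_by_chrom(cls)
        assert got["a"].tolist() == [2, 25]
        assert got["b"].tolist() == [5]
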