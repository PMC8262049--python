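import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from itertools import product
from scipy import stats

from _oracles import quantile_type7, welch_reference
from poresig.errors import DegenerateInputError, PatternError
from poresig.extract import SignalInstance
from poresig.summaries import (average_group, match_kmers, normalize_length,
                               rank_kmers, summarize_kmer, welch_t_test)

ALL_KMERS = ["".join(p) for p in product("ACGT", repeat=5)]


class TestSummarizeKmer:
    def test_odd_length_exact_quantiles(self):
        s = summarize_kmer([1, 2, 3, 4, 5], "AAAAA")
        assert (s.q1, s.median, s.q3) == (2, 3, 4)
        assert (s.whisker_low, s.whisker_high) == (1, 5)

    def test_single_distance_degenerates(self):
        s = summarize_kmer([7.5], "AAAAA")
        assert s.q1 == s.median == s.q3 == 7.5
        assert s.kde_points is None

    def test_quantiles_match_sort_based_reference(self):
        rng = np.random.default_rng(12)
        d = rng.gamma(2.0, 10.0, size=4950)
        s = summarize_kmer(d, "GACCT", n_instances=100)
        assert s.n_pairs == 4950
        for got, q in ((s.q1, 0.25), (s.median, 0.5), (s.q3, 0.75)):
            assert got == pytest.approx(quantile_type7(d, q), abs=1e-12)

    def test_whiskers_follow_tukey_convention(self):
        d = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 100.0])
        s = summarize_kmer(d, "AAAAA")
        iqr = s.q3 - s.q1
        inside = d[(d >= s.q1 - 1.5 * iqr) & (d <= s.q3 + 1.5 * iqr)]
        assert s.whisker_low == inside.min()
        assert s.whisker_high == inside.max()
        assert s.whisker_high < 100.0  # the outlier is excluded

    def test_kde_payload_matches_scipy_gaussian_kde(self):
        rng = np.random.default_rng(13)
        d = rng.normal(50, 5, 200)
        s = summarize_kmer(d, "AAAAA", n_instances=21)
        xs = np.array([x for x, _ in s.kde_points])
        ys = np.array([y for _, y in s.kde_points])
        assert len(xs) == 64
        ref = stats.gaussian_kde(d, bw_method="scott")(xs)
        np.testing.assert_allclose(ys, ref, rtol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_kmer([], "AAAAA")


class TestRankKmers:
    def test_median_mode_sorts_ascending(self):
        a = summarize_kmer([9.0], "AAAAA")
        c = summarize_kmer([5.0], "CCCCC")
        assert [s.kmer for s in rank_kmers([a, c], "median")] == \
            ["CCCCC", "AAAAA"]

    def test_equal_medians_break_alphabetically(self):
        a = summarize_kmer([5.0], "TTTTT")
        b = summarize_kmer([5.0], "AAAAA")
        assert [s.kmer for s in rank_kmers([a, b], "median")] == \
            ["AAAAA", "TTTTT"]

    def test_matches_reference_stable_sort(self):
        rng = np.random.default_rng(14)
        kmers = rng.permutation(ALL_KMERS)[:50]
        summaries = [summarize_kmer([float(rng.integers(0, 9))], k)
                     for k in kmers]
        got = [s.kmer for s in rank_kmers(summaries, "median")]
        ref = [s.kmer for s in
               sorted(summaries, key=lambda s: (s.median, s.kmer))]
        assert got == ref
        alpha = [s.kmer for s in rank_kmers(summaries, "alphabetical")]
        assert alpha == sorted(kmers)


class TestMatchKmers:
    def test_terminal_wildcard_expands_to_four(self):
        got = match_kmers(ALL_KMERS, "AACA*")
        assert got == ["AACAA", "AACAC", "AACAG", "AACAT"]

    def test_all_wildcards_match_everything(self):
        assert match_kmers(ALL_KMERS, "*****") == ALL_KMERS

    def test_prefix_matches_against_regex_reference(self):
        import re

        got = match_kmers(ALL_KMERS, "GAC")
        ref = [k for k in ALL_KMERS if re.match("GAC", k)]
        assert got == ref
        assert len(got) == 16

    def test_invalid_character_raises(self):
        with pytest.raises(PatternError):
            match_kmers(ALL_KMERS, "AAXA*")
        with pytest.raises(PatternError):
            match_kmers(ALL_KMERS, "AAAAAA")


class TestNormalizeLength:
    def test_linear_midpoint(self):
        np.testing.assert_allclose(normalize_length([0.0, 10.0], 3),
                                   [0.0, 5.0, 10.0])

    def test_identity_when_already_target_length(self):
        v = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        np.testing.assert_array_equal(normalize_length(v, 5), v)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        values=st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=50),
        L=st.integers(2, 100),
    )
    def test_endpoints_and_range_preserved(self, values, L):
        out = normalize_length(values, L)
        assert out.size == L
        assert out[0] == values[0]
        assert out[-1] == values[-1]
        assert out.min() >= min(values) - 1e-9
        assert out.max() <= max(values) + 1e-9

    def test_idempotent_at_fixed_length(self):
        rng = np.random.default_rng(15)
        v = rng.normal(100, 10, 37)
        once = normalize_length(v, 100)
        twice = normalize_length(once, 100)
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_too_short_target_rejected(self):
        with pytest.raises(ValueError):
            normalize_length([1.0, 2.0], 1)


def _instances(arrays, kmer="ACAGT", label=None):
    return [SignalInstance(f"n{i}", kmer, np.asarray(v, float), "r", 0, label)
            for i, v in enumerate(arrays)]


class TestAverageGroup:
    def test_single_instance_band_collapses_onto_center(self):
        v = np.array([1.0, 2.0, 8.0, 3.0])
        avg = average_group(_instances([v]), L=4)
        np.testing.assert_array_equal(avg.center, v)
        np.testing.assert_array_equal(avg.band_low, v)
        np.testing.assert_array_equal(avg.band_high, v)

    def test_recovers_level_offset_between_classes(self):
        rng = np.random.default_rng(16)
        lo = [rng.normal(80, 5, rng.integers(20, 31)) for _ in range(100)]
        hi = [rng.normal(100, 5, rng.integers(20, 31)) for _ in range(100)]
        a = average_group(_instances(lo), L=25)
        b = average_group(_instances(hi), L=25)
        diff = float(np.mean(b.center - a.center))
        se = np.sqrt(25 / 100 + 25 / 100)
        assert abs(diff - 20.0) < 3 * se

    def test_center_tracks_known_template_under_symmetric_noise(self):
        rng = np.random.default_rng(17)
        template = np.sin(np.linspace(0, 2 * np.pi, 30)) * 10 + 100
        arrays = [template + rng.normal(0, 2, 30) for _ in range(200)]
        avg = average_group(_instances(arrays), L=30)
        np.testing.assert_allclose(avg.center, template, atol=1.0)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(18)
        arrays = [rng.normal(100, 5, rng.integers(5, 15)) for _ in range(9)]
        insts = _instances(arrays)
        fwd = average_group(insts, L=10)
        rev = average_group(list(reversed(insts)), L=10)
        np.testing.assert_array_equal(fwd.center, rev.center)
        np.testing.assert_array_equal(fwd.band_low, rev.band_low)

    def test_band_brackets_center_with_mean_mode(self):
        rng = np.random.default_rng(19)
        arrays = [rng.normal(100, 5, 10) for _ in range(20)]
        avg = average_group(_instances(arrays), L=10, center="mean")
        assert (avg.band_low <= avg.center).all()
        assert (avg.center <= avg.band_high).all()


class TestWelch:
    def test_identical_samples_null(self):
        r = welch_t_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.t_statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_textbook_example_to_1e10(self):
        a = [1.0, 2, 3, 4, 5]
        b = [2.0, 3, 4, 5, 6]
        r = welch_t_test(a, b)
        t_ref, df_ref, p_ref = welch_reference(a, b)
        assert r.t_statistic == pytest.approx(t_ref, abs=1e-10)
        assert r.df == pytest.approx(df_ref, abs=1e-10)
        assert r.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_matches_scipy_on_random_inputs(self):
        rng = np.random.default_rng(20)
        for _ in range(25):
            a = rng.normal(0, rng.uniform(0.5, 3), rng.integers(3, 40))
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 3),
                           rng.integers(3, 40))
            r = welch_t_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert r.t_statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert r.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_length_contrast_is_significant(self):
        rng = np.random.default_rng(21)
        a = rng.normal(15, 3, 100)
        b = rng.normal(35, 5, 100)
        assert welch_t_test(a, b).p_value < 0.001

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(22)
        a = rng.normal(0, 1, 20)
        b = rng.normal(1, 2, 30)
        fwd = welch_t_test(a, b)
        rev = welch_t_test(b, a)
        assert fwd.t_statistic == pytest.approx(-rev.t_statistic)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_degenerate_equal_constants_rejected(self):
        with pytest.raises(DegenerateInputError):
            welch_t_test([5.0, 5.0, 5.0], [5.0, 5.0])
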