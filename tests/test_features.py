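"""Tests for the 15-feature extraction, rank-sum test and normalization."""

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st
from scipy.stats import mannwhitneyu

from snvforest.candidate_screen import screen_site
from snvforest.features import (
    FEATURE_NAMES, BackgroundMedians, MEDIAN_EPSILON, extract_features,
    median_normalize, rank_sum_test, sample_background,
)
from conftest import make_obs, make_record, uniform_site
from oracles import fisher_exact_oracle, ranksum_exact_oracle
from snvforest.pileup_io import SitePair


class TestRankSum:
    def test_identical_samples_p1(self):
        assert rank_sum_test([3, 1, 2], [2, 1, 3]) == pytest.approx(1.0)

    def test_small_separated_matches_enumeration(self):
        # 20 rank assignments; only the two extremes reach |U - mu| = 9
        assert rank_sum_test([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)
        assert rank_sum_test([1, 2, 3], [10, 11, 12]) == pytest.approx(
            ranksum_exact_oracle([1, 2, 3], [10, 11, 12]))

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1, 2])

    @given(xs=st.lists(st.integers(0, 50), min_size=1, max_size=6),
           ys=st.lists(st.integers(0, 50), min_size=1, max_size=6),
           c=st.integers(-20, 20))
    @settings(max_examples=100, deadline=None)
    def test_shift_invariance(self, xs, ys, c):
        assert rank_sum_test(xs, ys) == pytest.approx(
            rank_sum_test([x + c for x in xs], [y + c for y in ys]), abs=1e-12)

    @given(xs=st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=4),
           ys=st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=4))
    @settings(max_examples=80, deadline=None)
    def test_matches_exact_enumeration_small(self, xs, ys):
        """Exact-path p equals the brute-force permutation oracle."""
        if len(set(xs) | set(ys)) < len(xs) + len(ys):
            return  # exact path requires no ties
        assert rank_sum_test(xs, ys) == pytest.approx(
            ranksum_exact_oracle(xs, ys), abs=1e-12)

    def test_large_sample_tracks_scipy_normal_approximation(self):
        rng = np.random.default_rng(5)
        xs = rng.normal(0, 1, 40)
        ys = rng.normal(0.7, 1, 55)
        ours = rank_sum_test(xs, ys)
        ref = mannwhitneyu(xs, ys, alternative="two-sided",
                           method="asymptotic").pvalue
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_tied_samples_track_scipy(self):
        xs = [1, 1, 2, 2, 3, 3, 3, 5, 5, 6, 6]
        ys = [2, 2, 2, 3, 4, 4, 5, 5, 5, 6, 7]
        ref = mannwhitneyu(xs, ys, alternative="two-sided",
                           method="asymptotic").pvalue
        assert rank_sum_test(xs, ys) == pytest.approx(ref, rel=1e-6)


class TestMedianNormalize:
    def test_self_ratio_is_one(self):
        assert median_normalize(30.0, 30.0) == 1.0

    def test_zero_numerator(self):
        assert median_normalize(0.0, 12.0) == 0.0

    def test_zero_median_guard(self):
        assert median_normalize(5.0, 0.0) == pytest.approx(5.0 / MEDIAN_EPSILON)


class TestBackground:
    @staticmethod
    def _pairs(depths, seed=0):
        rng = np.random.default_rng(seed)
        pairs = []
        for i, d in enumerate(depths):
            obs = [make_obs("A", bqv=int(rng.integers(30, 41)),
                            mqv=int(rng.integers(50, 61)),
                            read_pos=int(rng.integers(1, 101))) for _ in range(d)]
            pairs.append(SitePair(make_record(pos=i + 1, obs=obs),
                                  make_record(pos=i + 1, obs=list(obs))))
        return pairs

    def test_constant_depth_median(self):
        bg = sample_background(iter(self._pairs([30] * 150)), n_positions=100, seed=1)
        assert bg["tumor_depth"] == 30.0

    def test_same_seed_identical(self):
        pairs = self._pairs([10, 20, 30, 40, 50] * 60)
        a = sample_background(iter(pairs), n_positions=100, seed=9)
        b = sample_background(iter(pairs), n_positions=100, seed=9)
        assert a == b

    def test_mixture_median_converges(self):
        pairs = self._pairs(list(np.random.default_rng(3).choice(
            [10, 20, 30, 40, 50], size=4000)))
        bg = sample_background(iter(pairs), n_positions=2000, seed=2)
        assert bg["tumor_depth"] == pytest.approx(30.0, abs=10.0)

    def test_short_input_uses_all_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            bg = sample_background(iter(self._pairs([30] * 50)), n_positions=100, seed=0)
        assert bg.n_positions == 50
        assert "only 50" in caplog.text


class TestExtractFeatures:
    def test_vaf_is_alt_fraction(self, neutral_background):
        site = uniform_site(n_ref=16, n_alt=4, n_ref_normal=30)
        cand = screen_site(site)[0]
        fv = extract_features(cand, neutral_background)
        assert fv["tumor_vaf"] == pytest.approx(0.2)
        assert fv["normal_vaf"] == 0.0

    def test_identical_quality_multisets_give_neutral_p(self, neutral_background):
        obs = ([make_obs("A", bqv=q, read_pos=i + 1) for i, q in enumerate([30, 35, 40] * 4)]
               + [make_obs("C", bqv=q, read_pos=50 + i) for i, q in enumerate([30, 35, 40] * 4)])
        site = SitePair(make_record(obs=obs),
                        make_record(obs=[make_obs("A", read_pos=i + 1) for i in range(24)]))
        fv = extract_features(screen_site(site)[0], neutral_background)
        assert fv["bqv_ranksum_p"] == pytest.approx(1.0)

    def test_strand_bias_matches_fisher_oracle(self, neutral_background):
        obs = ([make_obs("A", "+", read_pos=i + 1) for i in range(10)]
               + [make_obs("A", "-", read_pos=i + 11) for i in range(10)]
               + [make_obs("C", "+", read_pos=i + 21) for i in range(6)])
        site = SitePair(make_record(obs=obs),
                        make_record(obs=[make_obs("A", read_pos=i + 1) for i in range(26)]))
        fv = extract_features(screen_site(site)[0], neutral_background)
        assert fv["strand_fisher_p"] == pytest.approx(
            fisher_exact_oracle(6, 0, 10, 10), abs=1e-9)
        assert fv["alt_majority_strand_frac"] == 1.0

    def test_no_ref_reads_gives_neutral_rank_ps(self, neutral_background):
        obs = [make_obs("C", bqv=30 + i, read_pos=i + 1) for i in range(20)]
        site = SitePair(make_record(obs=obs),
                        make_record(obs=[make_obs("A", read_pos=i + 1) for i in range(20)]))
        fv = extract_features(screen_site(site)[0], neutral_background)
        assert fv["bqv_ranksum_p"] == 1.0
        assert fv["mqv_ranksum_p"] == 1.0
        assert fv["read_pos_ranksum_p"] == 1.0

    def test_near_end_fraction(self, neutral_background):
        # read length proxy = max read_pos = 100; alt at 3, 98, 50 -> 2/3
        obs = ([make_obs("A", read_pos=p) for p in range(1, 101)]
               + [make_obs("C", read_pos=3), make_obs("C", read_pos=98),
                  make_obs("C", read_pos=50)])
        site = SitePair(make_record(obs=obs),
                        make_record(obs=[make_obs("A", read_pos=i + 1) for i in range(30)]))
        fv = extract_features(screen_site(site)[0], neutral_background)
        assert fv["alt_near_end_frac"] == pytest.approx(2 / 3)
        assert fv["alt_read_pos_rel"] == pytest.approx((3 + 98 + 50) / 3 / 100)

    def test_n_alt_alleles_counts_distinct(self, neutral_background):
        obs = ([make_obs("A", read_pos=i + 1) for i in range(20)]
               + [make_obs("C", read_pos=30)] * 2 + [make_obs("G", read_pos=31)])
        site = SitePair(make_record(obs=obs),
                        make_record(obs=[make_obs("A", read_pos=i + 1) for i in range(20)]))
        fv = extract_features(screen_site(site)[0], neutral_background)
        assert fv["n_alt_alleles"] == 2.0

    def test_observation_order_irrelevant(self, neutral_background):
        rng = np.random.default_rng(17)
        site = uniform_site(n_ref=18, n_alt=6, n_ref_normal=25)
        cand = screen_site(site)[0]
        fv1 = extract_features(cand, neutral_background)
        perm_t = list(site.tumor.observations)
        rng.shuffle(perm_t)
        site2 = SitePair(
            make_record(obs=perm_t),
            make_record(obs=list(reversed(site.normal.observations))))
        fv2 = extract_features(screen_site(site2)[0], neutral_background)
        assert fv1 == pytest.approx(fv2)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_all_features_finite_on_fuzzed_sites(self, seed, neutral_background):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 40))
        obs = [make_obs(["A", "C", "G", "T"][int(rng.integers(0, 4))],
                        "+" if rng.random() < 0.5 else "-",
                        bqv=int(rng.integers(0, 60)), mqv=int(rng.integers(0, 60)),
                        read_pos=int(rng.integers(1, 120))) for _ in range(n)]
        nobs = [make_obs(["A", "C", "G", "T"][int(rng.integers(0, 4))],
                         bqv=int(rng.integers(0, 60)), read_pos=int(rng.integers(1, 120)))
                for _ in range(int(rng.integers(8, 40)))]
        site = SitePair(make_record(obs=obs), make_record(obs=nobs))
        from snvforest.candidate_screen import FilterConfig
        for cand in screen_site(site, FilterConfig(min_alt_bqv=0, min_alt_mqv=0)):
            fv = extract_features(cand, neutral_background)
            assert set(fv) == set(FEATURE_NAMES)
            assert all(math.isfinite(v) for v in fv.values())
            for key in ("bqv_ranksum_p", "mqv_ranksum_p", "read_pos_ranksum_p",
                        "strand_fisher_p", "somatic_fisher_p", "tumor_vaf",
                        "normal_vaf", "alt_read_pos_rel", "alt_near_end_frac"):
                assert 0.0 <= fv[key] <= 1.0
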