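"""Rank statistics and nonparametric group inference, checked against
exhaustive enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from semrsa.inference import (
    InferenceError,
    cluster_mass_test,
    kendall_tau_a,
    rdm_compare,
    region_contrast,
    rsa_timecourse,
    tau_a_against,
    wilcoxon_signed_rank,
    window_average_test,
)
from semrsa.neural import RDMSeries
from semrsa.semantic import RDM, cosine_rdm


from oracles import cluster_oracle_exhaustive, tau_a_oracle, wilcoxon_oracle

# ---------------------------------------------------------------------------
# Kendall's Tau-A

class TestKendallTauA:
    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3], [1, 2, 3], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 2, 2, 3], [1, 3, 2, 2], 1 / 3),  # C=3, D=1 over 6 pairs
    ])
    def test_known_values(self, x, y, expected):
        assert kendall_tau_a(x, y) == pytest.approx(expected)

    def test_matches_exhaustive_oracle_on_random_vectors(self, rng):
        for _ in range(300):
            n = rng.integers(2, 13)
            x = rng.integers(0, 6, size=n).astype(float)  # many ties
            y = rng.standard_normal(n)
            assert kendall_tau_a(x, y) == pytest.approx(tau_a_oracle(x, y))

    def test_no_tie_correction_in_denominator(self):
        # with ties, tau-a differs from scipy's tau-b
        x = [1.0, 1.0, 2.0, 3.0]
        y = [1.0, 2.0, 3.0, 4.0]
        tau_b = stats.kendalltau(x, y).statistic
        assert kendall_tau_a(x, y) == pytest.approx(5 / 6)
        assert kendall_tau_a(x, y) != pytest.approx(tau_b)

    def test_vectorized_matches_scalar(self, rng):
        X = rng.standard_normal((7, 10))
        y = rng.standard_normal(10)
        vec = tau_a_against(X, y)
        for k in range(7):
            assert vec[k] == pytest.approx(kendall_tau_a(X[k], y))

    def test_length_mismatch_rejected(self):
        with pytest.raises(InferenceError):
            kendall_tau_a([1, 2], [1, 2, 3])

    @given(st.lists(st.integers(-5, 5), min_size=2, max_size=12),
           st.randoms(use_true_random=False))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_property_equals_enumeration_and_bounds(self, xs, rnd):
        ys = [rnd.gauss(0, 1) for _ in xs]
        tau = kendall_tau_a(xs, ys)
        assert tau == pytest.approx(tau_a_oracle(xs, ys))
        assert -1.0 <= tau <= 1.0


class TestRdmCompare:
    def test_identical_rdms_give_one(self, rng):
        rdm = cosine_rdm(list("abcd"), rng.standard_normal((4, 6)))
        assert rdm_compare(rdm, rdm) == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self, rng):
        rdm = cosine_rdm(list("abcde"), rng.standard_normal((5, 6)))
        squared = RDM(rdm.items, rdm.values**2 * 0.5, "cosine")
        assert rdm_compare(squared, rdm) == pytest.approx(1.0)

    def test_alignment_by_item_name(self, rng):
        mat = rng.standard_normal((4, 6))
        a = cosine_rdm(list("abcd"), mat)
        perm = [2, 0, 3, 1]
        b = cosine_rdm([a.items[i] for i in perm], mat[perm])
        assert rdm_compare(a, b) == pytest.approx(1.0)

    def test_matches_pair_count_oracle(self, rng):
        m1 = cosine_rdm(list("abcde"), rng.standard_normal((5, 7)))
        m2 = cosine_rdm(list("abcde"), rng.standard_normal((5, 7)))
        assert rdm_compare(m1, m2) == pytest.approx(
            tau_a_oracle(m1.vectorize(), m2.vectorize()))

    def test_item_mismatch_error(self, rng):
        a = cosine_rdm(list("abc"), rng.standard_normal((3, 4)))
        b = cosine_rdm(list("abz"), rng.standard_normal((3, 4)))
        with pytest.raises(InferenceError, match="z"):
            rdm_compare(a, b)


class TestRsaTimecourse:
    def _series(self, rdms, items):
        return RDMSeries(items, np.arange(len(rdms), dtype=float), rdms, roi="PRC")

    def test_model_copies_give_tau_one(self, rng):
        model = cosine_rdm(list("abcd"), rng.standard_normal((4, 5)))
        series = self._series([model] * 5, model.items)
        tc = rsa_timecourse(series, model)
        assert np.allclose(tc.tau, 1.0)

    def test_label_permuted_null_has_small_mean_tau(self, rng):
        mat = rng.standard_normal((8, 10))
        model = cosine_rdm([f"i{k}" for k in range(8)], mat)
        rdms = []
        for _ in range(100):
            perm = rng.permutation(8)
            rdms.append(RDM(model.items, model.values[np.ix_(perm, perm)], "cosine"))
        tc = rsa_timecourse(self._series(rdms, model.items), model)
        assert np.abs(tc.tau).mean() < 0.1

    def test_single_time_series(self, rng):
        model = cosine_rdm(list("abc"), rng.standard_normal((3, 4)))
        tc = rsa_timecourse(self._series([model], model.items), model)
        assert tc.tau.shape == (1,)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank

class TestWilcoxonSignedRank:
    def test_all_positive_n8_exact_tail(self):
        res = wilcoxon_signed_rank(np.arange(1.0, 9.0), "greater")
        assert res.p == pytest.approx(1 / 256)
        assert res.statistic == 36.0

    def test_symmetric_pairs_two_sided_p_one(self):
        res = wilcoxon_signed_rank([1.0, -1.0, 2.0, -2.0], "two-sided")
        assert res.p == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(40):
            n = rng.integers(3, 13)
            v = rng.standard_normal(n)
            mask = rng.random(n) < 0.3
            v[mask] = np.round(v[mask] * 2) / 2  # induce ties (and zeros)
            for alt in ("greater", "two-sided"):
                w_o, p_o = wilcoxon_oracle(v, alt)
                res = wilcoxon_signed_rank(v, alt)
                assert res.statistic == pytest.approx(w_o)
                assert res.p == pytest.approx(p_o)

    def test_matches_scipy_exact_without_ties(self, rng):
        v = rng.standard_normal(10)
        ours = wilcoxon_signed_rank(v, "greater")
        ref = stats.wilcoxon(v, alternative="greater", method="exact")
        assert ours.p == pytest.approx(ref.pvalue)

    def test_all_zero_rejected(self):
        with pytest.raises(InferenceError):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_zeros_dropped(self):
        res = wilcoxon_signed_rank([0.0, 1.0, 2.0, 3.0], "greater")
        assert res.n == 3
        assert res.p == pytest.approx(1 / 8)


# ---------------------------------------------------------------------------
# cluster-mass sign-flip permutation

class TestClusterMassTest:
    def test_uniform_strong_effect_single_cluster_floor_p(self):
        """A maximal uniform effect yields one all-times cluster at the floor
        p reachable with 8 participants (only the ~1/256 all-keep flips tie)."""
        X = np.full((8, 30), 0.5)
        res = cluster_mass_test(X, n_perm=10000, seed=0)
        assert len(res.clusters) == 1
        c = res.clusters[0]
        assert (c["t_start"], c["t_end"]) == (0.0, 29.0)
        assert c["p"] <= 0.01
        exact = cluster_mass_test(X, exhaustive=True)
        assert exact.clusters[0]["p"] == pytest.approx(1 / 256)

    def test_matches_exhaustive_256_flip_oracle(self, rng):
        """Monte-Carlo permutation p agrees with full 2^8 enumeration."""
        X = rng.standard_normal((8, 20)) * 0.2
        X[:, 5:12] += 0.45  # moderate effect -> non-floor p
        res = cluster_mass_test(X, n_perm=10000, seed=1)
        oracle = cluster_oracle_exhaustive(X)
        assert len(res.clusters) == len(oracle)
        for c, (a, b, mass, p_ex) in zip(res.clusters, oracle):
            assert (c["t_start"], c["t_end"]) == (float(a), float(b))
            assert c["mass"] == pytest.approx(mass)
            assert abs(c["p"] - p_ex) < 0.02

    def test_invariant_to_participant_relabeling(self, rng):
        X = rng.standard_normal((8, 25)) + 0.3
        r1 = cluster_mass_test(X, exhaustive=True)
        r2 = cluster_mass_test(X[rng.permutation(8)], exhaustive=True)
        assert [c["p"] for c in r1.clusters] == [c["p"] for c in r2.clusters]

    def test_invariant_to_common_positive_rescaling(self, rng):
        X = rng.standard_normal((8, 25)) + 0.3
        r1 = cluster_mass_test(X, n_perm=2000, seed=3)
        r2 = cluster_mass_test(X * 3.7, n_perm=2000, seed=3)
        assert [c["p"] for c in r1.clusters] == [c["p"] for c in r2.clusters]

    def test_monotone_offset_does_not_raise_cluster_p(self, rng):
        X = rng.standard_normal((8, 25)) * 0.3
        X[:, 8:16] += 0.4
        base = cluster_mass_test(X, exhaustive=True)
        shifted = X.copy()
        shifted[:, 8:16] += 0.5
        better = cluster_mass_test(shifted, exhaustive=True)
        win = lambda r: min((c["p"] for c in r.clusters
                             if c["t_end"] >= 8 and c["t_start"] <= 15),
                            default=1.0)
        assert win(better) <= win(base)

    def test_type_one_error_under_symmetric_null(self):
        """Empirical type-I error within binomial error of alpha (500 sims).

        Null timecourses are smooth (temporally autocorrelated), like real
        sliding-window tau series; that keeps the orbit of cluster masses
        effectively continuous."""
        from scipy.ndimage import gaussian_filter1d
        hits = 0
        n_sims = 500
        rng_local = np.random.default_rng(21)
        for _ in range(n_sims):
            X = gaussian_filter1d(rng_local.standard_normal((8, 50)), 4, axis=1)
            res = cluster_mass_test(X, n_perm=500,
                                    seed=int(rng_local.integers(2**31)))
            if res.min_p() <= 0.05:
                hits += 1
        assert 0.03 <= hits / n_sims <= 0.08

    def test_degenerate_all_zero_rejected(self):
        with pytest.raises(InferenceError):
            cluster_mass_test(np.zeros((4, 10)))


# ---------------------------------------------------------------------------
# window, region, band tests

class TestWindowAverageTest:
    def test_all_positive_means_exact_tail(self, rng):
        taus = rng.uniform(0.1, 0.5, size=(8, 50))
        times = np.linspace(0, 490, 50)
        res = window_average_test(taus, times, (100.0, 300.0))
        assert res.p == pytest.approx(1 / 256)

    def test_single_point_window_equals_pointwise_test(self, rng):
        taus = rng.standard_normal((8, 10))
        times = np.arange(10.0)
        res = window_average_test(taus, times, (4.0, 4.0))
        ref = wilcoxon_signed_rank(taus[:, 4], "greater")
        assert res.p == ref.p and res.statistic == ref.statistic

    def test_means_match_direct_averaging(self, rng):
        taus = rng.standard_normal((5, 20))
        times = np.arange(20.0) * 10
        res = window_average_test(taus, times, (50.0, 120.0))
        sel = (times >= 50.0) & (times <= 120.0)
        assert np.allclose(res.values, taus[:, sel].mean(axis=1))

    def test_empty_window_rejected(self, rng):
        with pytest.raises(InferenceError):
            window_average_test(rng.standard_normal((3, 5)), np.arange(5.0),
                                (100.0, 200.0))


class TestRegionContrast:
    def test_identical_groups_p_one(self):
        a = [0.1, 0.2, 0.3, 0.4]
        res = region_contrast(a, a)
        assert res.p == pytest.approx(1.0)
        assert res.extra["greater_count"] == 0

    def test_complete_separation_exact_tail(self):
        a = np.arange(9.0, 17.0)
        b = np.arange(1.0, 9.0) * 0.1
        res = region_contrast(a, b)
        # minimal two-sided rank-sum tail for 8 vs 8: 2 / C(16, 8)
        from math import comb
        assert res.p == pytest.approx(2 / comb(16, 8))
        assert res.extra["greater_count"] == 8

    def test_small_shift_gives_large_p(self, rng):
        b = rng.standard_normal(8)
        res = region_contrast(b + 1e-6, b)
        assert res.p > 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(InferenceError):
            region_contrast([], [1.0])


class TestBandRsaTest:
    def test_model_identical_phases_give_floor_p(self, rng):
        """Phase maps whose circular RDM matches the model at every cell."""
        from semrsa.inference import band_rsa_test
        from semrsa.phase import DEFAULT_BANDS, PhaseTFR, make_freq_grid

        n_items = 8
        angles = np.linspace(0.2, 2.4, n_items)   # monotone phase spread
        model_vals = np.abs(angles[:, None] - angles[None, :])
        items = [f"i{k}" for k in range(n_items)]
        model = RDM(items, model_vals, "circular")
        freqs = make_freq_grid()
        times = np.arange(200.0, 401.0, 20.0)
        phases = np.broadcast_to(
            angles[:, None, None, None],
            (n_items, 1, len(freqs), len(times))).copy()
        tfrs = [PhaseTFR(items, ["e0"], freqs, times, phases,
                         np.full(len(freqs), 5.0)) for _ in range(8)]
        res = band_rsa_test(tfrs, model, DEFAULT_BANDS)
        assert len(res) == 5
        for band_res in res.values():
            assert band_res.p == pytest.approx(1 / 256)
            assert band_res.extra["positive_participants"] == 8
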