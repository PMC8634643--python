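"""Reweighting estimators against closed forms and the quadrature oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proliso import (
    KB_KCAL,
    analytic_state_probability,
    anharmonicity,
    block_bootstrap_se,
    classify_omega,
    exact_weights,
    maclaurin_weights,
    pmf_cumulant2,
    pmf_from_weights,
    reweighted_mean,
    uniform_weights,
)
from proliso.isomers import CIS_RANGE

T = 300.0
KT = KB_KCAL * T


class TestExactWeights:
    def test_zero_boost_gives_uniform(self):
        w = exact_weights(np.zeros(7), T)
        np.testing.assert_allclose(w.weights, np.full(7, 1 / 7), atol=1e-15)

    def test_two_frame_closed_form(self):
        dv = np.array([0.0, KT * np.log(2.0)])
        w = exact_weights(dv, T)
        np.testing.assert_allclose(w.weights, [1 / 3, 2 / 3], atol=1e-12)

    def test_matches_long_double_brute_force(self):
        rng = np.random.default_rng(42)
        dv = rng.exponential(1.0, 200)
        w = exact_weights(dv, T)
        brute = np.exp(np.longdouble(dv) / np.longdouble(KT))
        brute /= brute.sum()
        np.testing.assert_allclose(w.weights, brute.astype(float), rtol=1e-12)

    def test_negative_boost_rejected(self):
        with pytest.raises(ValueError):
            exact_weights(np.array([0.1, -0.2]), T)


class TestMaclaurinWeights:
    def test_order_zero_is_uniform(self):
        w = maclaurin_weights(np.array([0.3, 1.7, 0.9]), T, order=0)
        np.testing.assert_allclose(w.weights, np.full(3, 1 / 3), atol=1e-15)

    def test_single_frame_weight_is_one(self):
        for order in (0, 3, 10):
            w = maclaurin_weights(np.array([2.5]), T, order=order)
            assert w.weights == pytest.approx([1.0])

    def test_order_10_near_exact_for_small_boost(self):
        # Taylor remainder bound: e * (beta dV)^11 / 11! < 1e-7 for beta dV <= 1
        rng = np.random.default_rng(3)
        dv = rng.uniform(0.0, KT, 500)  # beta dV in [0, 1]
        mac = maclaurin_weights(dv, T, order=10).weights
        ex = exact_weights(dv, T).weights
        assert np.max(np.abs(mac - ex) / ex) < 1e-7

    @settings(deadline=None, derandomize=True)
    @given(st.integers(1, 18))
    def test_converges_monotonically_to_exact(self, order):
        rng = np.random.default_rng(8)
        dv = rng.uniform(0.0, 3 * KT, 50)
        ex = exact_weights(dv, T).weights
        err_k = np.max(np.abs(maclaurin_weights(dv, T, order=order).weights - ex))
        err_k1 = np.max(np.abs(maclaurin_weights(dv, T, order=order + 1).weights - ex))
        assert err_k1 <= err_k + 1e-15


class TestReweightedMean:
    def test_uniform_weights_give_arithmetic_mean(self):
        x = np.array([1.0, 2.0, 6.0])
        assert reweighted_mean(x, uniform_weights(3)) == pytest.approx(3.0)

    def test_indicator_gives_state_probability(self):
        dv = np.array([0.0, KT * np.log(3.0)])
        ind = np.array([0.0, 1.0])
        assert reweighted_mean(ind, exact_weights(dv, T)) == pytest.approx(0.75)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reweighted_mean(np.ones(3), uniform_weights(4))

    def test_boosted_run_recovers_quadrature_cis(self, asymmetric_boosted_run):
        spec, traj = asymmetric_boosted_run
        p_oracle = analytic_state_probability(spec, CIS_RANGE)
        ind = (classify_omega(traj.omega[:, 0]) == "cis").astype(float)
        mean, se = block_bootstrap_se(ind, traj.delta_v, T, method="exact", seed=5)
        assert abs(mean - p_oracle) < 3.0 * se


class TestPMF:
    def test_uniform_everything_is_flat(self):
        rng = np.random.default_rng(1)
        omega = rng.uniform(-180.0, 180.0, 200_000)
        pmf = pmf_from_weights(omega, uniform_weights(omega.size), bins=30)
        assert np.nanmax(np.abs(pmf.free_energy)) < 0.05

    def test_min_shift_is_exactly_zero(self, boosted_run):
        spec, traj = boosted_run
        w = maclaurin_weights(traj.delta_v, T)
        for pmf in (
            pmf_from_weights(traj.omega[:, 0], w),
            pmf_cumulant2(traj.omega[:, 0], traj.delta_v, T),
        ):
            assert np.nanmin(pmf.free_energy) == 0.0

    def test_empty_bins_carry_nan_and_skip_min_shift(self):
        omega = np.concatenate([np.full(50, -10.0), np.full(30, 170.0)])
        pmf = pmf_from_weights(omega, uniform_weights(80), bins=12)
        assert np.isnan(pmf.free_energy).sum() == 10
        assert np.nanmin(pmf.free_energy) == 0.0

    def test_zero_boost_cumulant2_is_boltzmann_inversion(self):
        rng = np.random.default_rng(2)
        omega = rng.uniform(-180.0, 180.0, 50_000)
        pmf = pmf_cumulant2(omega, np.zeros(omega.size), T, bins=20)
        counts, _ = np.histogram(omega, bins=np.linspace(-180, 180, 21))
        f = -KT * np.log(counts / counts.sum())
        np.testing.assert_allclose(pmf.free_energy, f - f.min(), atol=1e-10)

    def test_exact_weight_pmf_matches_quadrature(self, boosted_run):
        """-kT ln p from exact reweighting tracks the true potential shape."""
        spec, traj = boosted_run
        w = exact_weights(traj.delta_v, T)
        pmf = pmf_from_weights(traj.omega[:, 0], w, bins=60)
        edges = np.linspace(-180.0, 180.0, 61)
        p_true = np.array(
            [
                analytic_state_probability(spec, (edges[j], edges[j + 1]))
                for j in range(60)
            ]
        )
        f_true = -KT * np.log(p_true)
        f_true -= f_true.min()
        ess = w.effective_sample_size()
        solid = pmf.weight_sum * ess >= 100
        np.testing.assert_allclose(
            pmf.free_energy[solid], f_true[solid], atol=0.3
        )

    def test_cumulant2_recovers_known_barrier(self, boosted_run):
        spec, traj = boosted_run
        pmf = pmf_cumulant2(traj.omega[:, 0], traj.delta_v, T)
        assert pmf.barrier_height() == pytest.approx(4.0, abs=0.5)

    def test_all_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            pmf_from_weights(np.array([0.0]), uniform_weights(1), bins=np.array([100.0, 110.0]))

    def test_maclaurin_does_not_overshoot_cumulant_barrier(self, boosted_run):
        spec, traj = boosted_run
        w = maclaurin_weights(traj.delta_v, T, order=10)
        b_mac = pmf_from_weights(traj.omega[:, 0], w).barrier_height()
        b_c2 = pmf_cumulant2(traj.omega[:, 0], traj.delta_v, T).barrier_height()
        assert b_mac <= b_c2 + 0.1


class TestAnharmonicity:
    def _gaussian_fixture(self, n, seed=0):
        rng = np.random.default_rng(seed)
        omega = rng.uniform(-180.0, 180.0, n)
        dv = np.clip(rng.normal(5.0, 0.8, n), 0.0, None)
        return omega, dv

    def test_gaussian_boost_gives_small_gamma(self):
        omega, dv = self._gaussian_fixture(100_000)
        assert abs(anharmonicity(omega, dv).average) < 1e-2

    def test_gamma_shrinks_with_sample_size(self):
        small = anharmonicity(*self._gaussian_fixture(10_000)).average
        large = anharmonicity(*self._gaussian_fixture(100_000)).average
        assert abs(large) < abs(small)

    def test_bimodal_bin_exceeds_gaussian_gamma(self):
        rng = np.random.default_rng(4)
        n = 40_000
        omega = rng.uniform(-180.0, 180.0, n)
        dv_gauss = np.clip(rng.normal(5.0, 0.5, n), 0.0, None)
        mode = rng.random(n) < 0.5
        dv_bimodal = np.where(mode, rng.normal(2.0, 0.2, n), rng.normal(8.0, 0.2, n))
        dv_bimodal = np.clip(dv_bimodal, 0.0, None)
        g_gauss = anharmonicity(omega, dv_gauss, bins=12)
        g_bi = anharmonicity(omega, dv_bimodal, bins=12)
        assert g_bi.average > g_gauss.average
        assert np.all(g_bi.gamma > np.maximum(g_gauss.gamma, 0.05))

    def test_degenerate_bin_gamma_is_zero(self):
        omega = np.concatenate([np.full(100, -10.0), np.full(100, 170.0)])
        dv = np.concatenate([np.full(100, 2.0), np.full(100, 3.0)])
        rep = anharmonicity(omega, dv, bins=12)
        assert np.all(rep.gamma == 0.0)
        assert rep.average == 0.0

    def test_pass_flag_respects_cutoff(self):
        omega, dv = self._gaussian_fixture(50_000)
        rep = anharmonicity(omega, dv)
        assert rep.cutoff == 1e-3
        assert rep.passed == (abs(rep.average) < 1e-3)
        assert anharmonicity(omega, dv, cutoff=10.0).passed
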