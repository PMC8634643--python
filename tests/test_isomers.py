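"""Cis/trans state classification, percentages, flips and histograms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proliso import (
    IsomerStateSeries,
    cis_percentage,
    classify_omega,
    classify_trajectory,
    exact_weights,
    flip_frequency,
    joint_distribution,
    omega_histogram,
    running_average,
    sample_boosted_trajectory,
    uniform_weights,
)
from conftest import make_boosted_spec


def series(states, sites=("pro1",), dt_ps=0.1):
    arr = np.asarray(states, dtype=object)
    if arr.ndim == 1:
        arr = arr[:, None]
    return IsomerStateSeries(states=arr, sites=sites, dt_ps=dt_ps)


class TestClassifyOmega:
    @pytest.mark.parametrize(
        "omega, expected",
        [
            (0.0, "cis"),
            (180.0, "trans"),
            (-150.0, "trans"),  # 210 in the +100..+240 convention
            (75.0, "unassigned"),  # gap between the ranges
            (-90.0, "cis"),  # closed lower bound
            (50.0, "unassigned"),  # open upper bound of cis
            (100.0, "trans"),
            (-120.0, "unassigned"),  # 240, open upper bound of trans
        ],
    )
    def test_canonical_assignments(self, omega, expected):
        assert classify_omega(omega) == expected

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-180.0, 180.0, exclude_min=True), st.integers(-5, 5))
    def test_wrap_invariance(self, omega, k):
        assert classify_omega(omega + 360.0 * k) == classify_omega(omega)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_omega(np.nan)


class TestCisPercentage:
    def test_all_cis_is_100(self):
        assert cis_percentage(series(["cis"] * 5))["pro1"] == 100.0

    def test_unassigned_excluded_from_denominator(self):
        s = series(["cis", "unassigned", "trans", "trans"])
        assert cis_percentage(s)["pro1"] == pytest.approx(100.0 / 3.0)

    def test_cis_plus_trans_is_100(self):
        rng = np.random.default_rng(0)
        states = rng.choice(["cis", "trans", "unassigned"], size=(500, 2))
        s = series(states, sites=("a", "b"))
        cis = cis_percentage(s)
        trans = cis_percentage(
            series(
                np.where(states == "cis", "trans", np.where(states == "trans", "cis", states)),
                sites=("a", "b"),
            )
        )
        for site in ("a", "b"):
            assert cis[site] + trans[site] == pytest.approx(100.0)

    def test_uniform_equals_exact_weights_when_unboosted(self):
        spec = make_boosted_spec()
        traj = sample_boosted_trajectory(spec, 5000, seed=2)
        states = classify_trajectory(traj)
        w_exact = exact_weights(np.zeros(traj.n_frames), 300.0)
        a = cis_percentage(states, uniform_weights(traj.n_frames))
        b = cis_percentage(states, w_exact)
        assert a["pro1"] == pytest.approx(b["pro1"], abs=1e-12)

    def test_no_assigned_frames_rejected(self):
        with pytest.raises(ValueError, match="no assigned frames"):
            cis_percentage(series(["unassigned"] * 3))


class TestFlipFrequency:
    def test_alternating_states_direct_count(self):
        s = series(["cis", "trans"] * 5, dt_ps=0.1)  # 9 flips over 0.9 ps
        assert flip_frequency(s)["pro1"] == pytest.approx(9 / (0.9e-3))

    def test_constant_state_is_zero(self):
        assert flip_frequency(series(["trans"] * 10))["pro1"] == 0.0

    def test_gap_bridging_counts_once(self):
        s = series(["cis", "unassigned", "trans"], dt_ps=1.0)
        assert flip_frequency(s)["pro1"] == pytest.approx(1 / (2.0e-3))

    def test_relabel_invariance(self):
        rng = np.random.default_rng(1)
        states = rng.choice(["cis", "trans", "unassigned"], size=300)
        swapped = np.where(states == "cis", "trans", np.where(states == "trans", "cis", states))
        assert flip_frequency(series(states))["pro1"] == pytest.approx(
            flip_frequency(series(swapped))["pro1"]
        )

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            flip_frequency(series(["cis"]))


class TestOmegaHistogram:
    def test_uniform_is_flat_and_normalized(self):
        rng = np.random.default_rng(0)
        omega = rng.uniform(-180.0, 180.0, 100_000)
        hist = omega_histogram(omega, bins=24)
        widths = 360.0 / 24
        assert hist["density_per_deg"].sum() * widths == pytest.approx(1.0)
        assert np.ptp(hist["density_per_deg"]) < 0.0005

    def test_two_fold_potential_shows_two_modes(self, boosted_run):
        spec, traj = boosted_run
        hist = omega_histogram(traj.omega[:, 0], bins=72)
        centers = hist["bin_center_deg"].to_numpy()
        dens = hist["density_per_deg"].to_numpy()
        cis_peak = centers[np.argmax(np.where(np.abs(centers) < 90, dens, -1))]
        trans_peak = centers[np.argmax(np.where(np.abs(centers) > 90, dens, -1))]
        assert abs(cis_peak) < 10.0
        assert abs(abs(trans_peak) - 180.0) < 10.0


def poisson_binomial_pmf(ps):
    """DP-convolution oracle for the number of independent successes."""
    pmf = np.array([1.0])
    for p in ps:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


class TestJointDistribution:
    def test_single_always_cis_constant_observable(self):
        s = series(["cis"] * 10)
        jd = joint_distribution(s, np.full(10, 24.0), observable_bins=5)
        assert jd.probability.sum() == pytest.approx(1.0)
        assert np.count_nonzero(jd.probability) == 1
        assert jd.marginal_n_cis()[1] == pytest.approx(1.0)

    def test_observable_marginal_matches_1d_histogram(self):
        rng = np.random.default_rng(5)
        states = rng.choice(["cis", "trans"], size=(2000, 3))
        obs = rng.normal(24.0, 4.0, 2000)
        w = rng.random(2000)
        w /= w.sum()
        edges = np.linspace(obs.min(), obs.max(), 11)
        jd = joint_distribution(
            series(states, sites=("a", "b", "c")), obs, w, observable_bins=edges
        )
        hist, _ = np.histogram(obs, bins=edges, weights=w)
        np.testing.assert_allclose(jd.marginal_observable(), hist / hist.sum(), atol=1e-12)

    def test_n_cis_marginal_matches_poisson_binomial(self):
        rng = np.random.default_rng(9)
        ps = [0.3, 0.24, 0.18, 0.14, 0.1]
        n = 200_000
        cis = rng.random((n, 5)) < np.asarray(ps)
        states = np.where(cis, "cis", "trans").astype(object)
        jd = joint_distribution(
            series(states, sites=tuple("abcde")), rng.normal(size=n), observable_bins=8
        )
        oracle = poisson_binomial_pmf(ps)
        se = np.sqrt(oracle * (1 - oracle) / n)
        assert np.all(np.abs(jd.marginal_n_cis() - oracle) < 3 * se + 1e-4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            joint_distribution(series(["cis"] * 5), np.ones(4))


class TestRunningAverage:
    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(running_average(np.full(10, 3.0), 5), np.full(10, 3.0))

    def test_window_one_is_identity(self):
        x = np.arange(8.0)
        np.testing.assert_array_equal(running_average(x, 1), x)

    def test_linear_ramp_unchanged_in_interior(self):
        x = np.arange(20.0)
        out = running_average(x, 5)
        np.testing.assert_allclose(out[2:-2], x[2:-2], atol=1e-12)

    def test_window_larger_than_series_rejected(self):
        with pytest.raises(ValueError):
            running_average(np.ones(3), 4)
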