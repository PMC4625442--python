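"""Clone statistics: weighted variance, growth fits, front dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pilisort import synthgen
from pilisort.clonedyn import (
    CloneTimeSeries,
    FrontTrace,
    estimate_generation_time,
    exact_ode_model,
    fit_fluorescence_model,
    fit_radius_exponential,
    fluorescence_model,
    front_distance_trace,
    front_probability,
    spatial_variance,
    variance_vs_offspring,
)


def brute_force_weighted_variance(x, y, w):
    """Independent two-pass oracle for the intensity-weighted variance."""
    wtot = sum(w)
    mx = sum(xi * wi for xi, wi in zip(x, w)) / wtot
    my = sum(yi * wi for yi, wi in zip(y, w)) / wtot
    sx2 = sum(wi * (xi - mx) ** 2 for xi, wi in zip(x, w)) / wtot
    sy2 = sum(wi * (yi - my) ** 2 for yi, wi in zip(y, w)) / wtot
    return sx2, sy2, sx2 + sy2


class TestSpatialVariance:
    def test_two_equal_pixels_hand_value(self):
        sx2, sy2, s2 = spatial_variance([0.0, 2.0], [5.0, 5.0], [3.0, 3.0])
        assert (sx2, sy2, s2) == (1.0, 0.0, 1.0)

    def test_single_pixel_zero(self):
        assert spatial_variance([4.0], [7.0], [2.0]) == (0.0, 0.0, 0.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(2, 500)
            x = rng.normal(0, 30, n)
            y = rng.normal(0, 30, n)
            w = rng.uniform(0.1, 10, n)
            got = spatial_variance(x, y, w)
            want = brute_force_weighted_variance(x, y, w)
            np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-10)

    @settings(max_examples=30, deadline=None)
    @given(
        shift=st.floats(-1e3, 1e3),
        scale=st.floats(0.01, 100.0),
        seed=st.integers(0, 2**16),
    )
    def test_invariance_under_translation_and_intensity_scaling(self, shift, scale, seed):
        r = np.random.default_rng(seed)
        n = 40
        x, y, w = r.normal(0, 5, n), r.normal(0, 5, n), r.uniform(0.5, 2, n)
        base = spatial_variance(x, y, w)
        translated = spatial_variance(x + shift, y + shift, w)
        rescaled = spatial_variance(x, y, scale * w)
        np.testing.assert_allclose(translated, base, rtol=1e-6, atol=1e-6)
        np.testing.assert_allclose(rescaled, base, rtol=1e-9, atol=1e-9)

    def test_empty_and_zero_intensity_rejected(self):
        with pytest.raises(ValueError):
            spatial_variance([], [], [])
        with pytest.raises(ValueError):
            spatial_variance([1.0], [1.0], [0.0])


class TestRadiusExponential:
    def test_exact_exponential_full_window(self):
        t = np.arange(12) * 15.0
        r = 10.0 * np.exp(0.008 * t)
        rate, window = fit_radius_exponential(t, r)
        assert rate == pytest.approx(0.008, rel=1e-9)
        assert window.all()

    def test_plateau_truncates_window(self):
        t = np.arange(20) * 15.0
        r = np.where(t <= 150, 10.0 * np.exp(0.01 * t), 10.0 * np.exp(1.5))
        rate, window = fit_radius_exponential(t, r)
        end = int(window.sum())
        assert abs(end - 12) <= 1  # plateau starts at frame 11

    def test_constant_radius_rate_zero_full_window(self):
        t = np.arange(10) * 15.0
        rate, window = fit_radius_exponential(t, np.full(10, 30.0))
        assert rate == pytest.approx(0.0, abs=1e-12)
        assert window.all()

    def test_non_positive_radii_rejected(self):
        with pytest.raises(ValueError):
            fit_radius_exponential(np.arange(8.0), np.array([1, 2, 3, 0, 5, 6, 7, 8.0]))


class TestGenerationTime:
    @pytest.mark.parametrize("tau", [49.0, 41.0, 56.0])
    def test_noiseless_recovery_is_exact(self, tau):
        t = np.arange(40) * 15.0
        y = 100.0 * 2.0 ** (t / tau)
        est, se = estimate_generation_time(t, y)
        assert est == pytest.approx(tau, rel=1e-9)

    @pytest.mark.parametrize("tau", [49.0, 41.0, 56.0])
    def test_noisy_recovery_within_5pct_over_100_seeds(self, tau):
        t = np.arange(40) * 15.0
        errs = []
        for seed in range(100):
            y = synthgen.simulate_intensity_series(
                100.0, 0.0, 0.02, tau, t, noise_sigma=0.05, seed=seed,
                initially_fluorescent=True,
            )
            est, _ = estimate_generation_time(t, y)
            errs.append(est / tau - 1.0)
        errs = np.asarray(errs)
        assert np.all(np.abs(errs) < 0.05)
        assert abs(errs.mean()) < 0.01  # unbiased within Monte-Carlo error

    def test_decreasing_series_rejected(self):
        with pytest.raises(ValueError):
            estimate_generation_time(np.arange(5.0), np.array([5, 4, 3, 2, 1.0]))


class TestFluorescenceModelFit:
    GRID = [(i0, t0, kd) for i0 in (2.0, 5.0, 20.0) for t0 in (60.0, 120.0, 180.0)
            for kd in (0.01, 0.02, 0.05)]

    @pytest.mark.parametrize("i0,t0,kd", GRID)
    def test_noiseless_recovery_below_1pct(self, i0, t0, kd):
        tau = 45.0
        t = np.arange(40) * 15.0
        y = fluorescence_model(t, i0, t0, kd, tau)
        fit = fit_fluorescence_model(t, y, tau)
        assert fit.I0 == pytest.approx(i0, rel=0.01)
        assert fit.t0 == pytest.approx(t0, rel=0.01)
        assert fit.k_deg == pytest.approx(kd, rel=0.01)

    def test_all_zero_series_rejected(self):
        with pytest.raises(ValueError, match="onset"):
            fit_fluorescence_model(np.arange(10.0), np.zeros(10), 45.0)

    def test_per_cell_normalization_saturates_to_one(self):
        tau, i0, t0, kd = 45.0, 5.0, 60.0, 0.2  # fast maturation
        t = np.arange(40) * 15.0
        y = fluorescence_model(t, i0, t0, kd, tau)
        fit = fit_fluorescence_model(t, y, tau)
        norm = fit.per_cell_normalization(t, y)
        late = norm[t > t0 + 3 * tau]
        np.testing.assert_allclose(late, 1.0, rtol=1e-6)

    def test_integer_lineage_mode_recovers_rounded_counts(self):
        tau, i0, t0, kd = 41.0, 50.0, 60.0, 0.02
        t = np.arange(20) * 15.0
        n_round = np.where(t >= t0, np.round(2.0 ** ((t - t0) / tau)), 0.0)
        icell = np.where(t > t0, i0 * (1 - np.exp(-2 * kd * (t - t0))), 0.0)
        fit = fit_fluorescence_model(t, n_round * icell, tau, lineage="integer")
        assert fit.t0 == pytest.approx(t0, abs=1.0)
        assert fit.I0 == pytest.approx(i0, rel=0.02)

    def test_printed_form_differs_from_exact_ode_solution(self):
        # the fitted form is not the ODE solution; both agree at late times in slope
        t = np.arange(40) * 15.0
        printed = fluorescence_model(t, 5.0, 60.0, 0.02, 45.0)
        exact = exact_ode_model(t, 5.0, 60.0, 0.02, 45.0)
        assert not np.allclose(printed, exact)


def _clone(cid, n_est, s2, touching=None, pixel_size=1.0):
    k = len(n_est)
    z = np.zeros(k)
    return CloneTimeSeries(
        clone_id=cid,
        frames=np.arange(k),
        times=np.arange(k) * 15.0,
        itot=np.ones(k),
        sx2=np.asarray(s2) / 2,
        sy2=np.asarray(s2) / 2,
        s2=np.asarray(s2, float),
        s2_norm=z,
        front_touching=np.zeros(k, bool) if touching is None else np.asarray(touching),
        n_est=np.asarray(n_est, float),
        pixel_size=pixel_size,
    )


class TestVarianceVsOffspring:
    def test_linear_relation_recovered(self):
        n = np.array([1, 2, 4, 8, 16, 32], float)
        clones = [_clone(i, n, 3.0 * n) for i in range(4)]
        curve = variance_vs_offspring(clones)
        np.testing.assert_allclose(curve["mean"], 3.0 * curve["n"], rtol=1e-9)
        np.testing.assert_allclose(curve["se"], 0.0, atol=1e-12)  # identical clones

    def test_front_touching_frames_excluded(self):
        n = np.array([1, 2, 4, 8], float)
        touching = np.array([False, False, True, True])
        clones = [_clone(0, n, 5.0 * n, touching)]
        curve = variance_vs_offspring(clones)
        assert curve["n"].max() == 2.0

    def test_all_touching_from_start_empty_curve(self):
        n = np.array([1, 2], float)
        clones = [_clone(0, n, n, np.array([True, True]))]
        with pytest.warns(UserWarning, match="empty"):
            curve = variance_vs_offspring(clones)
        assert curve["mean"].size == 0


class TestFrontDistance:
    def test_pixel_on_circle_touches_front(self):
        tr = front_distance_trace(
            [np.array([[50, 70]])], [(50.0, 50.0, 20.0)], pixel_size=0.32
        )
        assert tr.distances[0] == 0.0
        assert tr.front_touching[0]

    def test_distance_arithmetic(self):
        # outermost pixel at r=47 px, R=50 px, 0.32 µm/px -> 0.96 µm
        tr = front_distance_trace(
            [np.array([[50, 97]])], [(50.0, 50.0, 50.0)], pixel_size=0.32
        )
        assert tr.distances[0] == pytest.approx(0.96)

    def test_missing_frames_are_gaps(self):
        tr = front_distance_trace(
            [np.array([[50, 60]]), None], [(50.0, 50.0, 20.0)] * 2, pixel_size=0.32
        )
        assert np.isnan(tr.distances[1])

    def test_outside_circle_clipped_and_flagged(self):
        tr = front_distance_trace(
            [np.array([[50, 80]])], [(50.0, 50.0, 20.0)], pixel_size=0.32
        )
        assert tr.distances[0] == 0.0 and tr.clipped[0]


def _traces_from_walks(walks, eps=0.5):
    return [
        FrontTrace(clone_id=i, frames=np.arange(w.size), distances=w, front_eps=eps)
        for i, w in enumerate(walks)
    ]


class TestFrontProbability:
    def test_unbiased_walk_interior_bins_near_half(self):
        walks = synthgen.simulate_front_traces(300, lambda d: 0.5, 1.0, 40, seed=2, d0=6.0)
        curve = front_probability([_traces_from_walks(walks)], bin_width=1.0)
        interior = slice(2, 8)
        n = curve.n_transitions[interior]
        p = curve.probability[interior]
        ci = 3 * np.sqrt(0.25 / n)
        assert np.all(np.abs(p - 0.5) < ci)

    def test_piecewise_probability_recovered(self):
        p_fun = synthgen.piecewise_probability([0.0, 3.0], [0.7], default=0.4)
        walks = synthgen.simulate_front_traces(200, p_fun, 1.0, 50, seed=3, d0=5.0)
        curve = front_probability([_traces_from_walks(walks)], bin_width=1.0)
        for bi in (1, 2):  # inside the biased zone, away from the at-front rule
            n = curve.n_transitions[bi]
            assert n >= 100
            assert abs(curve.probability[bi] - 0.7) < 3 * math.sqrt(0.7 * 0.3 / n)
        for bi in (4, 5):
            n = curve.n_transitions[bi]
            if n >= 100:
                assert abs(curve.probability[bi] - 0.4) < 3 * math.sqrt(0.4 * 0.6 / n)

    def test_single_experiment_weighted_sd_zero(self):
        walks = synthgen.simulate_front_traces(20, lambda d: 0.5, 1.0, 10, seed=4, d0=4.0)
        curve = front_probability([_traces_from_walks(walks)])
        finite = np.isfinite(curve.weighted_sd)
        np.testing.assert_allclose(curve.weighted_sd[finite], 0.0, atol=1e-12)

    def test_weighted_sd_formula_two_experiments(self):
        # one experiment always toward, one always away, weights 3:1 traces
        toward = np.array([[5.0, 4.0, 3.0]])
        away = np.array([[5.0, 6.0, 7.0]])
        exp1 = _traces_from_walks(np.repeat(toward, 3, axis=0))
        exp2 = _traces_from_walks(away)
        curve = front_probability([exp1, exp2], bin_width=10.0)
        pbar = (3 * 1.0 + 1 * 0.0) / 4
        assert curve.probability[0] == pytest.approx(pbar)
        expected_sd = math.sqrt((3 * (1 - pbar) ** 2 + 1 * (0 - pbar) ** 2) / 4)
        assert curve.weighted_sd[0] == pytest.approx(expected_sd)
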