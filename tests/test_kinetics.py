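"""Velocities, step detection, MSD, motility calls, bleaching survival."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stereomotion.kinetics import (
    bleaching_survival, classify_motility, detect_steps, msd_curve,
    summarize_velocities, velocity_of_track, VelocityEstimate,
)


class TestVelocity:
    def test_constant_series_zero_velocity(self):
        est = velocity_of_track(np.full(10, 500.0), np.arange(10.0))
        assert est.velocity == 0.0

    def test_noiseless_line_exact(self):
        t = np.arange(10.0)
        est = velocity_of_track(100.0 * t, t)
        assert est.velocity == pytest.approx(100.0, abs=1e-9)
        assert est.r_squared == pytest.approx(1.0)

    def test_mean_recovery_under_noise(self):
        # regression is unbiased: 100 noisy movers average to v_true
        rng = np.random.default_rng(1)
        t = np.arange(20.0)
        vs = [velocity_of_track(100.0 * t + rng.normal(0, 30, 20), t).velocity
              for _ in range(100)]
        assert np.mean(vs) == pytest.approx(100.0, rel=0.05)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            velocity_of_track(np.arange(3.0), np.arange(3.0))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(c=st.floats(-500, 500, allow_nan=False))
    def test_slope_equivariance(self, c):
        # adding c * t to a series adds exactly c to the velocity
        rng = np.random.default_rng(3)
        t = np.arange(15.0)
        s = rng.normal(0, 50, 15)
        v0 = velocity_of_track(s, t).velocity
        v1 = velocity_of_track(s + c * t, t).velocity
        assert v1 - v0 == pytest.approx(c, abs=1e-6 * max(1.0, abs(c)))


class TestSummaries:
    def _est(self, v, dur=10.0, r2=1.0):
        return VelocityEstimate(velocity=v, stderr=0.0, r_squared=r2,
                                duration=dur, n_points=10)

    def test_single_estimate(self):
        s = summarize_velocities([self._est(42.0)])
        assert s.mean == 42.0 and s.n == 1 and np.isnan(s.sd)

    def test_identical_estimates(self):
        s = summarize_velocities([self._est(100.0)] * 3)
        assert (s.mean, s.sd, s.n) == (100.0, 0.0, 3)

    def test_filters_and_empty_result(self):
        ests = [self._est(50.0, r2=0.2), self._est(-30.0)]
        s = summarize_velocities(ests, min_r_squared=0.5,
                                 direction="tipward")
        assert s.empty and s.n == 0

    def test_lognormal_population_recovery(self):
        # Monte-Carlo oracle: CI of the sample mean of 42 drawn speeds
        rng = np.random.default_rng(4)
        true = rng.lognormal(np.log(100), 0.4, 42)
        t = np.arange(20.0)
        ests = [velocity_of_track(v * t + rng.normal(0, 30, 20), t)
                for v in true]
        s = summarize_velocities(ests)
        ci = 1.96 * true.std(ddof=1) / np.sqrt(42)
        assert abs(s.mean - true.mean()) < ci


class TestStepDetection:
    def test_noise_free_single_step_exact(self):
        s = np.concatenate([np.zeros(10), np.full(10, 150.0)])
        fit = detect_steps(s, noise_sd=1.0)
        assert fit.n_steps == 1
        assert fit.changepoints[0] == 10
        assert fit.step_sizes[0] == pytest.approx(150.0, abs=1e-9)

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        s = np.concatenate([np.zeros(12), np.full(12, 120.0),
                            np.full(12, 290.0)]) + rng.normal(0, 15, 36)
        f0 = detect_steps(s, noise_sd=15.0)
        f1 = detect_steps(s + 12345.0, noise_sd=15.0)
        np.testing.assert_array_equal(f0.changepoints, f1.changepoints)
        np.testing.assert_allclose(f0.step_sizes, f1.step_sizes)

    def test_flat_noise_false_positive_rate(self):
        rng = np.random.default_rng(6)
        fp = sum(detect_steps(rng.normal(0, 20, 50), noise_sd=20.0).n_steps > 0
                 for _ in range(100))
        assert fp <= 5

    def test_staircase_recovery(self):
        # 5 steps of 100-200 nm, plateaus >= 5 frames, 30 nm noise
        rng = np.random.default_rng(7)
        n_found, errors = 0, []
        for _ in range(20):
            sizes = rng.uniform(100, 200, 5)
            plateaus = rng.integers(5, 11, 6)
            levels = np.concatenate([[0.0], np.cumsum(sizes)])
            s = np.concatenate([np.full(p, lv)
                                for p, lv in zip(plateaus, levels)])
            noisy = s + rng.normal(0, 30, len(s))
            fit = detect_steps(noisy, noise_sd=30.0, min_plateau=3)
            true_cp = np.cumsum(plateaus[:-1])
            matched = 0
            for j, cp in enumerate(true_cp):
                k = np.where(np.abs(fit.changepoints - cp) <= 2)[0]
                if k.size:
                    matched += 1
                    errors.append(abs(fit.step_sizes[k[0]] - sizes[j]))
            n_found += matched >= 4
        assert n_found >= 18  # >= 4 of 5 steps in >= 90 % of staircases
        assert np.mean(errors) < 30.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least 6"):
            detect_steps(np.arange(5.0))


class TestMsd:
    def test_ballistic_exact(self):
        t = np.arange(40.0)
        res = msd_curve(100.0 * t, 1.0)
        assert res.alpha == pytest.approx(2.0, abs=0.05)
        np.testing.assert_allclose(res.msd, (100.0 * res.lags_s) ** 2,
                                   rtol=1e-9)

    def test_diffusion_coefficient_recovery(self):
        from stereomotion.simcore import (MotilityModel,
                                          StereociliumGeometry,
                                          sample_trajectory)
        geo = StereociliumGeometry((0.0, 0.0), (1.0e6, 0.0))
        d_true = 1.0e5
        s = sample_trajectory(MotilityModel(mode="diffusive",
                                            diffusion_coeff=d_true),
                              geo, 5.0e5, 200, 1.0, seed=11)
        res = msd_curve(s + np.random.default_rng(11).normal(0, 30, 200), 1.0)
        assert res.diffusion_coeff == pytest.approx(d_true, rel=0.3)

    def test_static_noise_plateau(self):
        # closed form: MSD of pure localization noise is 2 sigma^2
        rng = np.random.default_rng(12)
        sigma = 40.0
        s = rng.normal(0, sigma, 4000)
        res = msd_curve(s, 1.0, max_lag=5)
        np.testing.assert_allclose(res.msd, 2 * sigma ** 2, rtol=0.1)

    def test_short_track_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            msd_curve(np.arange(7.0), 1.0)


class TestClassification:
    def test_noiseless_constant_is_static(self):
        assert classify_motility(np.full(20, 1000.0), 1.0).mode == "static"

    def test_noiseless_ramp_is_processive(self):
        s = 1000.0 + 100.0 * np.arange(20.0)
        call = classify_motility(s, 1.0)
        assert call.mode == "processive"
        assert call.velocity == pytest.approx(100.0)

    def test_clean_staircase_is_stepwise(self):
        s = np.concatenate([np.full(8, 0.0), np.full(8, 150.0),
                            np.full(8, 300.0), np.full(8, 480.0)])
        rng = np.random.default_rng(13)
        call = classify_motility(s + rng.normal(0, 20, len(s)), 1.0,
                                 loc_noise_nm=20.0)
        assert call.mode == "stepwise"

    def test_too_short_unclassified(self):
        call = classify_motility(np.arange(3.0), 1.0)
        assert call.mode == "unclassified"

    def test_deterministic(self):
        rng = np.random.default_rng(14)
        s = np.cumsum(rng.normal(0, 300, 50))
        calls = {classify_motility(s, 1.0).mode for _ in range(5)}
        assert len(calls) == 1

    def test_benchmark_per_mode_accuracy(self):
        from stereomotion.benchmarks import classifier_benchmark
        res = classifier_benchmark(99, per_mode=25)
        assert res["accuracy_min"] >= 0.85


class TestBleaching:
    def test_equal_durations_rate_is_reciprocal(self):
        fit = bleaching_survival(np.full(20, 4.0))
        assert fit.rate == pytest.approx(0.25)
        assert fit.mean_lifetime == pytest.approx(4.0)

    def test_rate_recovery_with_censoring(self):
        k = 0.05
        rng = np.random.default_rng(15)
        life = rng.exponential(1 / k, 500)
        censored = life > 60.0
        durations = np.minimum(life, 60.0)
        fit = bleaching_survival(durations, censored)
        assert fit.rate == pytest.approx(k, rel=0.15)

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="censored"):
            bleaching_survival(np.full(20, 10.0), np.ones(20, dtype=bool))

    def test_too_few_tracks_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            bleaching_survival(np.arange(1.0, 6.0))

    def test_agrees_with_lifelines(self):
        # independent survival-analysis implementation as cross-check
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(16)
        life = rng.exponential(20.0, 200)
        censored = life > 50.0
        durations = np.minimum(life, 50.0)
        fit = bleaching_survival(durations, censored)
        ef = lifelines.ExponentialFitter().fit(durations,
                                               event_observed=~censored)
        assert fit.mean_lifetime == pytest.approx(ef.lambda_, rel=1e-6)
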