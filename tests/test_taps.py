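"""Unit tests for tap extraction, ITIs, lag correlations and sync index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadsync import (
    FOUR_OSC,
    TWO_OSC,
    ConditionFailedError,
    ITISeries,
    InsufficientEventsError,
    LagPattern,
    ModelSpec,
    PhaseTrajectory,
    SimulationConfig,
    extract_taps,
    integrate,
    intertap_intervals,
    lagged_crosscorr,
    resultant_length,
    run_condition,
    synchronization_index,
)

TWO_PI = 2 * np.pi


def _manual_trajectory(times, phases, variant=TWO_OSC, config=None):
    times = np.asarray(times, float)
    phases = np.asarray(phases, float)
    spec = (
        ModelSpec(TWO_OSC, e1=0, e2=0)
        if variant == TWO_OSC
        else ModelSpec(FOUR_OSC, e1=0, e2=0, i1=0, i2=0)
    )
    if config is None:
        config = SimulationConfig(
            duration=float(times[-1]) if times[-1] > 0 else 1.0,
            dt=float(times[1] - times[0]),
            sample_interval=float(times[1] - times[0]),
            discard=0.0,
        )
    freqs = np.zeros(phases.shape[1])
    return PhaseTrajectory(times, phases, freqs, spec, config)


class TestTapExtraction:
    def test_noiseless_two_hz_taps_on_half_second_grid(self, two_spec, quiet_config):
        traj = integrate(
            ModelSpec(TWO_OSC, e1=0, e2=0),
            quiet_config,
            initial_phases=np.zeros(2),
        )
        taps = extract_taps(traj, 0, discard=2.0)
        expected = np.arange(2.5, 12.0 + 1e-9, 0.5)
        np.testing.assert_allclose(taps.tap_times, expected, atol=1e-6)
        itis = intertap_intervals(taps)
        np.testing.assert_allclose(itis.intervals, 0.5, atol=1e-6)

    def test_hand_interpolated_crossing(self):
        traj = _manual_trajectory([0.0, 0.5, 1.0], [[0.0, 0], [5.0, 0], [7.5, 0]])
        taps = extract_taps(traj, 0, discard=0.0)
        expected = 0.5 + 0.5 * (TWO_PI - 5.0) / 2.5
        np.testing.assert_allclose(taps.tap_times, [expected], atol=1e-12)

    def test_perception_oscillator_rejected(self, four_spec, default_config):
        traj = integrate(four_spec, default_config)
        with pytest.raises(ValueError, match="action oscillator"):
            extract_taps(traj, 0)

    def test_trajectory_shorter_than_discard(self):
        traj = _manual_trajectory([0.0, 0.5, 1.0], np.zeros((3, 2)))
        with pytest.raises(InsufficientEventsError):
            extract_taps(traj, 0, discard=2.0)

    def test_iti_variability_matches_noise_calibration(self):
        """At the dataset-1 noise level (0.2513 rad per 500 ms tap) the
        intertap intervals of an uncoupled 2 Hz oscillator spread by about
        20 ms, the timing equivalent of the phase noise SD."""
        from dyadsync import integrate_ensemble
        from dyadsync.taps import _crossing_times

        spec = ModelSpec(TWO_OSC, e1=0, e2=0)
        config = SimulationConfig(
            dt=0.01, sample_interval=0.01, noise_sd=0.2513, freq_sd=0.0, seed=21
        )
        ens = integrate_ensemble(spec, config, 300)
        itis = []
        for t in range(ens.n_trials):
            taps = _crossing_times(ens.times, ens.phases[t, :, 0])
            taps = taps[taps > config.discard]
            itis.append(np.diff(taps))
        pooled = np.concatenate(itis)
        assert abs(pooled.std() - 0.020) < 0.003
        np.testing.assert_allclose(pooled.mean(), 0.5, atol=0.005)


class TestIntervals:
    def test_successive_differences(self):
        from dyadsync import TapSeries

        itis = intertap_intervals(TapSeries(1, [2.5, 3.0, 3.6]))
        np.testing.assert_allclose(itis.intervals, [0.5, 0.6])

    def test_too_few_taps(self):
        from dyadsync import TapSeries

        with pytest.raises(InsufficientEventsError):
            intertap_intervals(TapSeries(1, [2.5]))

    def test_non_increasing_taps_rejected(self):
        from dyadsync import TapSeries

        with pytest.raises(ValueError):
            TapSeries(1, [2.5, 2.5, 3.0])


class TestLagCorrelation:
    def test_identical_series_r0_is_one(self, rng):
        x = rng.normal(0.5, 0.02, 30)
        a, b = ITISeries(1, x), ITISeries(2, x.copy())
        pattern = lagged_crosscorr(a, b)
        np.testing.assert_allclose(pattern.r_0, 1.0, atol=1e-12)

    def test_shifted_series_r_plus1_is_one(self, rng):
        x = rng.normal(0.5, 0.02, 31)
        a = ITISeries(1, x[1:])
        b = ITISeries(2, x[:-1])  # unit 2 repeats unit 1's previous interval
        pattern = lagged_crosscorr(a, b)
        np.testing.assert_allclose(pattern.r_plus1, 1.0, atol=1e-12)
        assert pattern.r_0 < 0.9

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_swap_mirrors_pattern(self, seed):
        r = np.random.default_rng(seed)
        a = ITISeries(1, r.uniform(0.4, 0.6, 20))
        b = ITISeries(2, r.uniform(0.4, 0.6, 20))
        fwd = lagged_crosscorr(a, b)
        rev = lagged_crosscorr(b, a)
        np.testing.assert_allclose(rev.as_array(), fwd.mirrored().as_array(), atol=1e-12)
        assert np.all(np.abs(fwd.as_array()) <= 1.0)

    def test_truncation_to_common_length(self, rng):
        x = rng.uniform(0.4, 0.6, 25)
        a = ITISeries(1, x)
        b = ITISeries(2, x[:18])
        pattern = lagged_crosscorr(a, b)
        np.testing.assert_allclose(pattern.r_0, 1.0, atol=1e-12)

    def test_constant_series_flagged_undefined(self):
        a = ITISeries(1, np.full(10, 0.5))
        b = ITISeries(2, np.linspace(0.4, 0.6, 10))
        pattern = lagged_crosscorr(a, b)
        assert not pattern.is_defined

    def test_too_short_series(self):
        with pytest.raises(InsufficientEventsError):
            lagged_crosscorr(ITISeries(1, [0.5, 0.5]), ITISeries(2, [0.5, 0.5]))


class TestSyncIndex:
    def test_constant_offset_gives_one(self, quiet_config):
        traj = integrate(
            ModelSpec(TWO_OSC, e1=0, e2=0),
            quiet_config,
            initial_phases=np.array([0.0, 1.0]),
        )
        np.testing.assert_allclose(synchronization_index(traj, 0, 1), 1.0, atol=1e-12)

    def test_uniform_relative_phase_near_zero(self, rng):
        rel = rng.uniform(0, TWO_PI, 100_000)
        assert resultant_length(rel) < 0.01

    def test_wrapped_normal_closed_form(self, rng):
        s = 0.5
        rel = rng.normal(0.0, s, 200_000)
        np.testing.assert_allclose(resultant_length(rel), np.exp(-(s**2) / 2), atol=0.005)


class TestRunCondition:
    def test_single_trial_mean_equals_trial(self):
        spec = ModelSpec(FOUR_OSC, e1=2.0, e2=2.0, i1=2.0, i2=2.0)
        config = SimulationConfig(noise_sd=0.0, seed=5)
        cond = run_condition(spec, config, 1)
        np.testing.assert_allclose(cond.mean_pattern.as_array(), cond.patterns[0])
        assert cond.n_undefined == 0

    def test_zero_noise_zero_spread_is_degenerate(self, quiet_config):
        spec = ModelSpec(FOUR_OSC, e1=0, e2=0, i1=0, i2=0)
        with pytest.raises(ConditionFailedError):
            run_condition(spec, quiet_config, 3)

    def test_unit_swap_mirrors_patterns_per_trial(self, rng):
        """Swapping the units (weights, states and noise) mirrors every
        trial's lag pattern about lag 0 exactly."""
        spec = ModelSpec(FOUR_OSC, e1=6.0, e2=2.0, i1=1.5, i2=4.0)
        config = SimulationConfig(seed=None)
        n_trials, n = 20, 4
        theta0 = rng.uniform(0, TWO_PI, (n_trials, n))
        omega = rng.normal(4 * np.pi, 1.26, (n_trials, n))
        noise = rng.normal(0, config.sigma_step, (config.n_steps, n_trials, n))
        perm = [3, 2, 1, 0]
        fwd = run_condition(
            spec, config, n_trials, initial_phases=theta0, frequencies=omega, noise=noise
        )
        rev = run_condition(
            spec.swapped_units(),
            config,
            n_trials,
            initial_phases=theta0[:, perm],
            frequencies=omega[:, perm],
            noise=noise[:, :, perm],
        )
        np.testing.assert_allclose(rev.patterns, fwd.patterns[:, ::-1], atol=1e-9)

    def test_patterns_bounded_and_sync_in_unit_interval(self, four_spec, default_config):
        cond = run_condition(four_spec, default_config, 20)
        defined = cond.patterns[np.all(np.isfinite(cond.patterns), axis=1)]
        assert np.all(np.abs(defined) <= 1.0)
        assert 0.0 <= cond.mean_sync <= 1.0
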