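import numpy as np
import pytest

from bowelperf.errors import (
    IndicatorUnreadableError,
    NoInflowDetectedError,
    RangeError,
    ValidationError,
)
from bowelperf.hsi_cube import CircularROI
from bowelperf.inflow import (
    FrameStack,
    InflowCurve,
    InflowMetrics,
    background_noise,
    build_curve,
    classify_thresholds,
    estimate_laser_intensity,
    extract_roi_series,
    inflow_slope,
    laser_levels,
    movmean,
    t0_objective,
    time_to_peak,
)
from bowelperf.synthetic import InflowScenario, render_indicator, simulate_inflow_stack

import oracles

ROI = CircularROI((12.0, 12.0), 4.0)


def _stack(frames, rate=5.0):
    return FrameStack(frames=np.asarray(frames, dtype=float), frame_rate_hz=rate)


def _curve_from_smoothed(t, smoothed):
    s = np.asarray(smoothed, dtype=float)
    return InflowCurve(t_s=np.asarray(t, dtype=float), raw=s, laser=np.ones_like(s), normalized=s, smoothed=s)


class TestRoiSeries:
    def test_constant_frames(self):
        assert np.allclose(extract_roi_series(_stack(np.full((5, 24, 24), 10.0)), ROI), 10.0)

    def test_frame_index_ramp(self):
        frames = np.zeros((6, 24, 24))
        for k in range(6):
            frames[k] = k
        assert np.allclose(extract_roi_series(_stack(frames), ROI), np.arange(6))

    def test_matches_brute_force(self, rng):
        frames = rng.uniform(0, 255, (4, 24, 24))
        series = extract_roi_series(_stack(frames), ROI)
        brute = [oracles.roi_mean_brute(frames[k], 12.0, 12.0, 4.0) for k in range(4)]
        assert np.allclose(series, brute, atol=1e-12)

    def test_roi_out_of_bounds(self):
        with pytest.raises(ValidationError):
            extract_roi_series(_stack(np.zeros((3, 24, 24))), CircularROI((2.0, 2.0), 4.0))


class TestLaserEstimation:
    def test_exact_template_match(self, template_bank):
        frame = np.zeros((40, 60))
        frame[1:13, 20:48] = render_indicator(0.5)
        assert estimate_laser_intensity(frame, (20, 1, 28, 12), template_bank) == 0.5

    def test_noisy_indicator_still_matches(self, template_bank, rng):
        frame = np.zeros((40, 60))
        frame[1:13, 20:48] = render_indicator(1.0, noise_sd=2.0, rng=rng)
        assert estimate_laser_intensity(frame, (20, 1, 28, 12), template_bank) == 1.0

    def test_blank_indicator_unreadable(self, template_bank):
        frame = np.zeros((40, 60))
        with pytest.raises(IndicatorUnreadableError):
            estimate_laser_intensity(frame, (20, 1, 28, 12), template_bank)

    def test_indicator_outside_frame(self, template_bank):
        with pytest.raises(RangeError):
            estimate_laser_intensity(np.zeros((10, 10)), (5, 5, 28, 12), template_bank)

    def test_vectorised_levels_match_per_frame_path(self, template_bank):
        scenario = InflowScenario(seed=11)
        stack, truth = simulate_inflow_stack(scenario)
        fast = laser_levels(stack, scenario.indicator_region, template_bank)
        slow = [
            estimate_laser_intensity(stack.frames[k], scenario.indicator_region, template_bank)
            for k in range(stack.n_frames)
        ]
        assert np.array_equal(fast, np.asarray(slow))
        assert np.array_equal(fast, truth.laser_series)

    def test_unreadable_frames_interpolated(self, template_bank):
        scenario = InflowScenario(seed=12)
        stack, truth = simulate_inflow_stack(scenario)
        k_blank = 40
        stack.frames[k_blank] = 0.0
        levels = laser_levels(stack, scenario.indicator_region, template_bank)
        expected = 0.5 * (truth.laser_series[k_blank - 1] + truth.laser_series[k_blank + 1])
        assert levels[k_blank] == pytest.approx(expected)


class TestMovmeanAndCurve:
    @pytest.mark.parametrize("window", [1, 3, 5, 15])
    def test_movmean_matches_brute_force(self, rng, window):
        x = rng.normal(0, 1, 60)
        assert np.allclose(movmean(x, window), oracles.movmean_brute(x, window), atol=1e-12)

    def test_constant_laser_means_normalized_equals_raw(self):
        frames = np.full((40, 24, 24), 7.0)
        curve = build_curve(_stack(frames), ROI)
        assert np.array_equal(curve.normalized, curve.raw)

    def test_constant_curve_with_laser_half(self, template_bank):
        frames = np.full((40, 24, 24), 100.0)
        curve = build_curve(_stack(frames), ROI)
        halved = InflowCurve(curve.t_s, curve.raw, np.full_like(curve.raw, 0.5),
                             curve.raw / 0.5, movmean(curve.raw / 0.5, 15), 15)
        assert np.allclose(halved.normalized, 200.0)
        assert np.allclose(halved.smoothed, 200.0)

    def test_hand_computed_normalization_and_smoothing(self):
        frames = np.zeros((6, 24, 24))
        raw = np.array([0.0, 10.0, 20.0, 30.0, 40.0, 50.0])
        for k in range(6):
            frames[k] = raw[k]
        stack = _stack(frames, rate=1.0)
        curve = build_curve(stack, ROI, window_s=3.0)
        assert np.allclose(curve.normalized, raw)
        assert np.allclose(curve.smoothed, oracles.movmean_brute(raw, 3), atol=1e-12)


class TestBackgroundAndT0:
    def test_zero_curve_has_zero_noise(self):
        t = np.arange(0, 10.5, 0.5)
        assert background_noise(_curve_from_smoothed(t, np.zeros_like(t))) == 0.0

    def test_spike_inside_window_is_the_max(self):
        t = np.arange(0, 10.5, 0.5)
        s = np.full_like(t, 5.0)
        s[t == 4.0] = 8.0
        assert background_noise(_curve_from_smoothed(t, s)) == 8.0

    def test_random_noise_matches_direct_scan(self, rng):
        t = np.arange(0, 12.1, 0.2)
        s = rng.uniform(0, 3, len(t))
        expected = s[(t >= 3.0) & (t <= 6.0)].max()
        assert background_noise(_curve_from_smoothed(t, s)) == expected

    def test_coverage_gap_rejected(self):
        t = np.arange(4.0, 10.0, 0.5)
        with pytest.raises(RangeError):
            background_noise(_curve_from_smoothed(t, np.zeros_like(t)))

    def test_step_curve_t0_at_step(self):
        t = np.arange(0, 40.5, 0.5)
        s = np.where(t >= 20.0, 100.0, 0.0)
        assert t0_objective(_curve_from_smoothed(t, s), B=0.0) == 20.0

    def test_dip_after_first_crossing_moves_t0(self):
        t = np.arange(0, 40.5, 0.5)
        s = np.where(t >= 15.0, 50.0, 0.0)
        s[t == 18.0] = 0.0  # single dip back below B
        assert t0_objective(_curve_from_smoothed(t, s), B=0.0) == 18.5

    def test_no_inflow_raises(self):
        t = np.arange(0, 20.5, 0.5)
        with pytest.raises(NoInflowDetectedError):
            t0_objective(_curve_from_smoothed(t, np.zeros_like(t)), B=0.0)


class TestSlope:
    def test_perfect_ramp_is_exact(self):
        t = np.arange(0, 30.5, 0.5)
        s = np.clip(2.0 * (t - 10.0), 0.0, None)
        curve = _curve_from_smoothed(t, s)
        assert inflow_slope(curve) == pytest.approx(2.0, abs=1e-9)

    def test_constant_curve_raises(self):
        t = np.arange(0, 20.5, 0.5)
        with pytest.raises(NoInflowDetectedError):
            inflow_slope(_curve_from_smoothed(t, np.full_like(t, 5.0)))

    def test_logistic_matches_definition_oracle_and_analytic_bound(self):
        t = np.arange(0, 60.05, 0.2)
        L, k, c = 200.0, 0.8, 30.0
        s = L / (1.0 + np.exp(-k * (t - c)))
        curve = _curve_from_smoothed(t, s)
        est = inflow_slope(curve)
        # independent brute-force implementation of the same segment rule
        slopes = (s[2:] - s[:-2]) / (t[2:] - t[:-2])
        peak = int(np.argmax(slopes))
        keep = slopes >= 0.5 * slopes[peak]
        lo = peak
        while lo > 0 and keep[lo - 1]:
            lo -= 1
        hi = peak
        while hi < len(slopes) - 1 and keep[hi + 1]:
            hi += 1
        coeffs = np.polyfit(t[lo + 1 : hi + 2], s[lo + 1 : hi + 2], 1)
        assert est == pytest.approx(coeffs[0], rel=1e-12)
        assert abs(est - L * k / 4.0) / (L * k / 4.0) <= 0.15


class TestTimeToPeak:
    def test_decreasing_to_constant(self):
        t = np.arange(0, 30.5, 0.5)
        laser = np.where(t < 12.0, 1.0 - 0.04 * t, 1.0 - 0.04 * 12.0)
        assert time_to_peak(t, laser) == 12.0

    def test_strictly_decreasing_none(self):
        t = np.arange(0, 30.5, 0.5)
        assert time_to_peak(t, 1.0 - 0.01 * t) is None

    def test_noisy_plateau_matches_window_scan(self, rng):
        t = np.arange(0, 30.5, 0.5)
        laser = np.where(t < 10.0, 1.0 - 0.05 * t, 0.5)
        laser = np.round(laser, 2)
        est = time_to_peak(t, laser, hold_s=1.0)
        # direct scan over all candidates
        expected = None
        running_max = np.maximum.accumulate(laser)
        for i in range(len(t)):
            if t[i] + 1.0 > t[-1] + 1e-12:
                break
            if running_max[i] <= laser[i] + 1e-9:
                continue
            window = laser[(t >= t[i]) & (t <= t[i] + 1.0)]
            if np.all(window >= laser[i] - 1e-9):
                expected = t[i]
                break
        assert est == expected == 10.0


class TestThresholds:
    def test_cohort_mean_values_raise_no_flags(self):
        # overall means of a well-perfused cohort: T0 20.3 s, slope 119.5 units/s
        metrics = InflowMetrics(5.0, 20.3, 119.5)
        flags = classify_thresholds(metrics)
        assert not any(flags.values())

    def test_late_t0_trips_both_t0_flags(self):
        flags = classify_thresholds(InflowMetrics(5.0, 65.0, 10.0))
        assert flags["hayami_t0_gt_60"] and flags["kim_t0_gt_40"]

    def test_boundary_slope_is_not_flagged(self):
        flags = classify_thresholds(InflowMetrics(5.0, 20.0, 2.1))
        assert not flags["wada_slope_lt_2.1"]


class TestCurveProperties:
    def test_time_shift_equivariance(self, template_bank):
        scenario = InflowScenario(seed=21)
        stack, _ = simulate_inflow_stack(scenario)
        curve = build_curve(stack, scenario.roi, scenario.indicator_region, template_bank)
        b = background_noise(curve)
        t0 = t0_objective(curve, b)
        ttp = time_to_peak(curve.t_s, curve.laser)
        delta = 2.0  # whole sample shifts only, to stay on the grid
        shifted = InflowCurve(curve.t_s + delta, curve.raw, curve.laser, curve.normalized,
                              curve.smoothed, curve.smooth_window_frames)
        b2 = background_noise(shifted, window_s=(3.0 + delta, 6.0 + delta))
        assert b2 == b
        assert t0_objective(shifted, b2, search_from_s=6.0 + delta) == t0 + delta
        assert time_to_peak(shifted.t_s, shifted.laser) == ttp + delta

    def test_intensity_scaling_scales_slope_not_t0(self, template_bank):
        scenario = InflowScenario(seed=22)
        stack, _ = simulate_inflow_stack(scenario)
        curve = build_curve(stack, scenario.roi, scenario.indicator_region, template_bank)
        c = 3.0
        scaled = InflowCurve(curve.t_s, c * curve.raw, curve.laser, c * curve.normalized,
                             c * curve.smoothed, curve.smooth_window_frames)
        b, b_scaled = background_noise(curve), background_noise(scaled)
        assert b_scaled == pytest.approx(c * b, rel=1e-12)
        assert t0_objective(scaled, b_scaled) == t0_objective(curve, b)
        assert inflow_slope(scaled) == pytest.approx(c * inflow_slope(curve), rel=1e-9)
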