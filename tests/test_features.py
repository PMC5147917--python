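"""Descriptor definitions against brute-force oracles and their invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swayscore.features import (FeatureConfig, SubjectRecord, SwayDensityCurve,
                                acceleration_norm_series, ballistic_intervals,
                                detect_sway_peaks, extract_features,
                                percentile, radius_series, sway_density)
from swayscore.signal import RawTrace, UniformTrace, resample_swarii
from swayscore.synthetic import CohortConfig, PhenotypeParams, simulate_trace

from oracles import (acceleration_oracle, percentile_oracle, radius_oracle,
                     sway_density_oracle, variance_oracle)


def uniform(ml, ap, rate=25.0):
    return UniformTrace(rate=rate, ml=np.asarray(ml, float),
                        ap=np.asarray(ap, float))


class TestPercentile:
    def test_single_element(self):
        assert percentile([5.0], 0.3) == 5.0

    def test_even_length_median(self):
        assert percentile(np.arange(1, 11), 0.5) == pytest.approx(5.5)

    def test_tenth_percentile_interpolates(self):
        # position 0.9 between the order statistics 1 and 2
        assert percentile(np.arange(1, 11), 0.1) == pytest.approx(1.9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile([], 0.5)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30),
           st.floats(0.01, 0.99))
    def test_matches_order_statistic_oracle(self, values, q):
        assert percentile(values, q) == pytest.approx(
            percentile_oracle(values, q), abs=1e-9)


class TestRadius:
    def test_unit_circle(self):
        tr = uniform([1, -1, 0, 0], [0, 0, 1, -1])
        np.testing.assert_allclose(radius_series(tr), 1.0)

    def test_constant_trace_zero(self):
        tr = uniform([2, 2, 2], [3, 3, 3])
        np.testing.assert_allclose(radius_series(tr), 0.0)

    def test_matches_oracle(self, rng):
        ml, ap = rng.normal(size=50), rng.normal(size=50)
        np.testing.assert_allclose(radius_series(uniform(ml, ap)),
                                   radius_oracle(list(ml), list(ap)),
                                   atol=1e-12)


class TestAcceleration:
    def test_linear_motion_zero(self):
        t = np.arange(20) / 25.0
        tr = uniform(3.0 * t, -1.5 * t)
        np.testing.assert_allclose(acceleration_norm_series(tr), 0.0,
                                   atol=1e-10)

    def test_quadratic_recovers_g(self):
        g = 9.81
        t = np.arange(30) / 25.0
        tr = uniform(0.5 * g * t ** 2, np.zeros_like(t))
        np.testing.assert_allclose(acceleration_norm_series(tr), g,
                                   rtol=1e-9)

    def test_matches_oracle(self, rng):
        ml, ap = rng.normal(size=40), rng.normal(size=40)
        np.testing.assert_allclose(
            acceleration_norm_series(uniform(ml, ap)),
            acceleration_oracle(list(ml), list(ap), 25.0), atol=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            acceleration_norm_series(uniform([0, 1], [0, 1]))


class TestSwayDensity:
    def test_constant_trace_dwell_to_end(self):
        n = 10
        tr = uniform(np.ones(n), np.ones(n))
        sdc = sway_density(tr, 0.25)
        np.testing.assert_allclose(sdc.dwell, (n - np.arange(n)) / 25.0)

    def test_straight_line_first_exit(self):
        # speed v = 1 cm/s at 25 Hz: v*dt = 0.04 cm; r = 0.25 -> ceil = 7 steps
        n = 40
        t = np.arange(n) / 25.0
        tr = uniform(t * 1.0, np.zeros(n))
        sdc = sway_density(tr, 0.25)
        expected = int(np.ceil(0.25 / 0.04))
        np.testing.assert_allclose(sdc.dwell[: n - expected - 1],
                                   expected / 25.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ml = np.cumsum(rng.normal(0, 0.1, 60))
        ap = np.cumsum(rng.normal(0, 0.1, 60))
        r = rng.uniform(0.05, 0.5)
        sdc = sway_density(uniform(ml, ap), r)
        np.testing.assert_allclose(
            sdc.dwell, sway_density_oracle(list(ml), list(ap), 1 / 25.0, r),
            atol=1e-12)

    def test_dwell_nonincreasing_in_radius(self, rng):
        ml = np.cumsum(rng.normal(0, 0.1, 80))
        ap = np.cumsum(rng.normal(0, 0.1, 80))
        tr = uniform(ml, ap)
        small = sway_density(tr, 0.1).dwell
        large = sway_density(tr, 0.3).dwell
        assert np.all(small <= large + 1e-12)


class TestPeaksAndIntervals:
    def test_triangular_pulse_single_peak(self):
        dwell = np.concatenate([np.linspace(0, 1, 20),
                                np.linspace(1, 0, 20)[1:]])
        t = np.arange(len(dwell)) / 25.0
        peaks = detect_sway_peaks(SwayDensityCurve(t, dwell),
                                  smooth_window=0.0, min_separation=0.1)
        assert len(peaks) == 1
        assert peaks[0] == pytest.approx(t[19])

    def test_two_pulses_two_seconds_apart(self):
        t = np.arange(125) / 25.0
        dwell = np.exp(-0.5 * ((t - 1.0) / 0.15) ** 2) \
            + np.exp(-0.5 * ((t - 3.0) / 0.15) ** 2)
        peaks = detect_sway_peaks(SwayDensityCurve(t, dwell),
                                  smooth_window=0.2, min_separation=0.5)
        assert len(peaks) == 2
        assert peaks[1] - peaks[0] == pytest.approx(2.0, abs=0.1)

    def test_flat_curve_no_peaks(self):
        t = np.arange(50) / 25.0
        peaks = detect_sway_peaks(SwayDensityCurve(t, np.ones(50)), 0.2, 0.2)
        assert len(peaks) == 0

    def test_close_peaks_merged_keeping_larger(self):
        t = np.arange(50) / 25.0
        dwell = np.zeros(50)
        dwell[10] = 1.0
        dwell[13] = 2.0  # 0.12 s later, larger
        peaks = detect_sway_peaks(SwayDensityCurve(t, dwell),
                                  smooth_window=0.0, min_separation=0.2)
        assert len(peaks) == 1
        assert peaks[0] == pytest.approx(t[13])

    def test_interval_examples(self):
        np.testing.assert_allclose(ballistic_intervals([1.0, 2.0, 3.0]),
                                   [1.0, 1.0])
        np.testing.assert_allclose(ballistic_intervals([0.0, 1.0, 3.0]),
                                   [1.0, 2.0])

    def test_intervals_telescope(self, rng):
        peaks = np.sort(rng.uniform(0, 25, 12))
        assert ballistic_intervals(peaks).sum() == pytest.approx(
            peaks.max() - peaks.min())

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            ballistic_intervals([1.0])


def _make_subject(seed, seconds=12.0):
    cfg = CohortConfig(record_seconds=seconds, seed=seed)
    rng = np.random.default_rng(seed)
    params = PhenotypeParams()
    return SubjectRecord(
        subject_id=f"T{seed}", is_faller=False,
        open_trace=simulate_trace(params, "open", cfg, rng),
        closed_trace=simulate_trace(params, "closed", cfg, rng))


def _oracle_features(subject, cfg=FeatureConfig()):
    """The five descriptors recomputed by single-purpose oracle code."""
    op = resample_swarii(subject.open_trace, cfg.rate)
    cl = resample_swarii(subject.closed_trace, cfg.rate)
    rho = percentile_oracle(radius_oracle(list(cl.ml), list(cl.ap)), 0.5)
    acc = percentile_oracle(
        acceleration_oracle(list(cl.ml), list(cl.ap), cfg.rate), 0.1)
    vy = variance_oracle(list(cl.ap))
    ratio = (percentile_oracle(list(cl.ml), 0.1)
             / percentile_oracle(list(op.ml), 0.1))
    dwell = sway_density_oracle(list(op.ml), list(op.ap), 1 / cfg.rate,
                                cfg.circle_radius)
    sdc = SwayDensityCurve(op.times, np.asarray(dwell))
    peaks = detect_sway_peaks(sdc, cfg.peak_smooth_window,
                              cfg.peak_min_separation)
    vibi = variance_oracle(list(np.diff(np.sort(peaks))))
    return np.array([rho, acc, vy, ratio, vibi])


class TestExtractFeatures:
    def test_circle_radius_one(self):
        # closed-eyes trace on a unit circle around its mean -> rho = 1
        t = np.arange(100) / 25.0
        circle = RawTrace(timestamps=t, ml=2.0 + np.cos(2 * np.pi * t / 4),
                          ap=np.sin(2 * np.pi * t / 4), condition="closed")
        sub = _make_subject(0)
        sub = SubjectRecord(sub.subject_id, False, sub.open_trace, circle)
        fv = extract_features(sub)
        assert fv.rho_cl_50 == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_full_vector_matches_oracles(self, seed):
        sub = _make_subject(seed)
        fv = extract_features(sub)
        np.testing.assert_allclose(fv.to_array(), _oracle_features(sub),
                                   rtol=1e-9)

    def test_translation_invariance(self):
        sub = _make_subject(3)
        shift = lambda tr: RawTrace(tr.timestamps, tr.ml + 4.0, tr.ap - 2.0,
                                    tr.condition)
        moved = SubjectRecord(sub.subject_id, sub.is_faller,
                              shift(sub.open_trace), shift(sub.closed_trace))
        a, b = extract_features(sub), extract_features(moved)
        for name in ("rho_cl_50", "a_cl_10", "var_y_cl", "var_ibi_op"):
            assert getattr(a, name) == pytest.approx(getattr(b, name),
                                                     rel=1e-9)

    def test_scaling_covariance(self):
        # the ML ratio denominator moves with scale, so scale about the
        # stance point: rho and a scale by s, var_y by s^2
        sub = _make_subject(4)
        s = 2.0
        scale = lambda tr: RawTrace(tr.timestamps, s * tr.ml, s * tr.ap,
                                    tr.condition)
        big = SubjectRecord(sub.subject_id, sub.is_faller,
                            scale(sub.open_trace), scale(sub.closed_trace))
        a, b = extract_features(sub), extract_features(big)
        assert b.rho_cl_50 == pytest.approx(s * a.rho_cl_50, rel=1e-9)
        assert b.a_cl_10 == pytest.approx(s * a.a_cl_10, rel=1e-9)
        assert b.var_y_cl == pytest.approx(s ** 2 * a.var_y_cl, rel=1e-9)
        assert b.x_ratio_10 == pytest.approx(a.x_ratio_10, rel=1e-9)

    def test_degenerate_ratio_denominator_rejected(self):
        sub = _make_subject(5)
        # recenter the open-eyes ML so its 10th percentile is ~0
        op = sub.open_trace
        q = np.quantile(resample_swarii(op).ml, 0.1)
        centered = RawTrace(op.timestamps, op.ml - q, op.ap, "open")
        bad = SubjectRecord(sub.subject_id, False, centered, sub.closed_trace)
        with pytest.raises(ValueError, match="degenerate"):
            extract_features(bad, FeatureConfig(ratio_eps=0.5))
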