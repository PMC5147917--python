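"""Statokinesigram descriptors.

Five signal transformations (ML position, AP position, radius, acceleration
norm, sway density / ballistic intervals) and the five scalar descriptors
derived from them, computed from a subject's open- and closed-eyes records:

========== ===========================================================
rho_cl_50  median radius, closed eyes (cm)
a_cl_10    10th percentile of the acceleration norm, closed eyes (cm/s^2)
var_y_cl   variance of the AP coordinate, closed eyes (cm^2)
x_ratio_10 closed/open ratio of the 10th-percentile ML coordinate (unitless)
var_ibi_op variance of the ballistic intervals, open eyes (s^2)
========== ===========================================================

The sway density at a sample is the time the CoP takes to leave a small
circle centred on that sample; ballistic intervals are the times between
successive peaks of the (smoothed) sway-density curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal import RawTrace, UniformTrace, resample_swarii, DEFAULT_RATE

__all__ = [
    "FEATURE_NAMES",
    "FeatureConfig",
    "FeatureVector",
    "SubjectRecord",
    "SwayDensityCurve",
    "percentile",
    "radius_series",
    "acceleration_norm_series",
    "sway_density",
    "detect_sway_peaks",
    "ballistic_intervals",
    "extract_features",
]

FEATURE_NAMES = ("rho_cl_50", "a_cl_10", "var_y_cl", "x_ratio_10", "var_ibi_op")


@dataclass(frozen=True)
class SubjectRecord:
    """Open- and closed-eyes raw traces for one subject, with the fall label."""

    subject_id: str
    is_faller: bool
    open_trace: RawTrace
    closed_trace: RawTrace


@dataclass(frozen=True)
class SwayDensityCurve:
    """Per-sample dwell times (s): time to leave a circle around each sample."""

    times: np.ndarray
    dwell: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.dwell, dtype=float)
        if len(t) != len(d):
            raise ValueError("times and dwell must have equal length")
        if not np.all(np.isfinite(d)):
            raise ValueError("dwell contains non-finite values")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "dwell", d)


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable conventions of the descriptor pipeline.

    The sway-density circle radius defaults to 0.25 cm, the conventional
    value in the sway-density literature; smoothing and peak-separation
    defaults are fixed here since no standard exists.
    """

    rate: float = DEFAULT_RATE
    resample_window: float | None = None  # seconds; None -> 1/rate
    circle_radius: float = 0.25           # cm
    peak_smooth_window: float = 0.48      # seconds
    peak_min_separation: float = 0.2      # seconds
    symmetric_sway: bool = False          # include backward dwell as well
    center_ml_for_ratio: bool = False     # keep raw device ML coordinates
    ratio_eps: float = 1e-6               # cm; degenerate-denominator guard


@dataclass(frozen=True)
class FeatureVector:
    """The five descriptors for one subject."""

    rho_cl_50: float
    a_cl_10: float
    var_y_cl: float
    x_ratio_10: float
    var_ibi_op: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    def __post_init__(self):
        arr = self.to_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("feature vector contains non-finite values")
        for name in ("rho_cl_50", "a_cl_10", "var_y_cl", "var_ibi_op"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def percentile(values, q: float) -> float:
    """q-quantile with linear interpolation at position ``(n - 1) * q``."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot take a percentile of an empty series")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    return float(np.quantile(values, q))


def radius_series(trace: UniformTrace) -> np.ndarray:
    """Distance of each sample from the trajectory center (the mean point)."""
    dml = trace.ml - trace.ml.mean()
    dap = trace.ap - trace.ap.mean()
    return np.hypot(dml, dap)


def acceleration_norm_series(trace: UniformTrace) -> np.ndarray:
    """Norm of the CoP acceleration by central second differences.

    Endpoints are excluded, so the output has ``len(trace) - 2`` samples.
    """
    if len(trace) < 3:
        raise ValueError("acceleration needs at least 3 samples")
    r2 = trace.rate ** 2
    aml = (trace.ml[2:] - 2.0 * trace.ml[1:-1] + trace.ml[:-2]) * r2
    aap = (trace.ap[2:] - 2.0 * trace.ap[1:-1] + trace.ap[:-2]) * r2
    return np.hypot(aml, aap)


def _first_exit_steps(ml: np.ndarray, ap: np.ndarray, radius: float) -> np.ndarray:
    """steps[i] = smallest j - i with sample j outside the circle at i,
    or N - i when the circle is never left."""
    n = len(ml)
    r2 = radius * radius
    steps = np.empty(n, dtype=np.int64)
    for i in range(n):
        d2 = (ml[i + 1:] - ml[i]) ** 2 + (ap[i + 1:] - ap[i]) ** 2
        out = np.nonzero(d2 > r2)[0]
        steps[i] = out[0] + 1 if out.size else n - i
    return steps


def sway_density(trace: UniformTrace, circle_radius: float = 0.25,
                 symmetric: bool = False) -> SwayDensityCurve:
    """Time for the CoP to leave a circle centred on each sample.

    Forward first-exit time by default: ``dwell(i) = dt * (j - i)`` with j the
    first later sample farther than ``circle_radius`` from sample i, truncated
    at the end of the record.  With ``symmetric=True`` the analogous backward
    exit time is added, as in the classical sway-density definition.
    """
    if circle_radius <= 0:
        raise ValueError("circle_radius must be positive")
    dwell = _first_exit_steps(trace.ml, trace.ap, circle_radius).astype(float)
    if symmetric:
        back = _first_exit_steps(trace.ml[::-1], trace.ap[::-1], circle_radius)
        dwell = dwell + back[::-1].astype(float)
    return SwayDensityCurve(times=trace.times, dwell=dwell * trace.dt)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if width <= 1:
        return x.astype(float)
    kernel = np.ones(width)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones(len(x)), kernel, mode="same")
    return num / den


def detect_sway_peaks(sdc: SwayDensityCurve, smooth_window: float = 0.48,
                      min_separation: float = 0.2) -> np.ndarray:
    """Peak times of the smoothed sway-density curve.

    The dwell curve is smoothed by a centered moving average of
    ``smooth_window`` seconds, strict local maxima are collected, and maxima
    closer than ``min_separation`` are merged keeping the larger (ties keep
    the earlier peak).  Returns sorted peak times in seconds.
    """
    t = sdc.times
    if len(t) < 3:
        return np.array([])
    dt = float(t[1] - t[0])
    width = max(1, int(round(smooth_window / dt)))
    s = _moving_average(sdc.dwell, width)
    interior = np.arange(1, len(s) - 1)
    is_max = (s[interior] > s[interior - 1]) & (s[interior] > s[interior + 1])
    candidates = interior[is_max]
    kept: list[int] = []
    for i in candidates:  # time-ordered greedy merge
        if kept and t[i] - t[kept[-1]] < min_separation:
            if s[i] > s[kept[-1]]:
                kept[-1] = i
        else:
            kept.append(i)
    return t[np.array(kept, dtype=int)] if kept else np.array([])


def ballistic_intervals(peaks) -> np.ndarray:
    """Successive differences of sorted sway-density peak times (s)."""
    peaks = np.sort(np.asarray(peaks, dtype=float))
    if len(peaks) < 2:
        raise ValueError("insufficient sway-density peaks")
    return np.diff(peaks)


def _resample(raw: RawTrace, cfg: FeatureConfig) -> UniformTrace:
    return resample_swarii(raw, rate=cfg.rate, window=cfg.resample_window)


def extract_features(subject: SubjectRecord,
                     cfg: FeatureConfig = FeatureConfig()) -> FeatureVector:
    """Compute the five descriptors from a subject's two records.

    The ML coordinate entering the closed/open ratio is the raw (uncentered)
    device coordinate after resampling; see :class:`FeatureConfig`.
    """
    op = _resample(subject.open_trace, cfg)
    cl = _resample(subject.closed_trace, cfg)

    rho_cl_50 = percentile(radius_series(cl), 0.5)
    a_cl_10 = percentile(acceleration_norm_series(cl), 0.1)
    var_y_cl = float(np.var(cl.ap, ddof=1))

    ml_op, ml_cl = op.ml, cl.ml
    if cfg.center_ml_for_ratio:
        ml_op = ml_op - ml_op.mean()
        ml_cl = ml_cl - ml_cl.mean()
    denom = percentile(ml_op, 0.1)
    if abs(denom) < cfg.ratio_eps:
        raise ValueError("degenerate medio-lateral ratio denominator")
    x_ratio_10 = percentile(ml_cl, 0.1) / denom

    sdc = sway_density(op, cfg.circle_radius, symmetric=cfg.symmetric_sway)
    peaks = detect_sway_peaks(sdc, cfg.peak_smooth_window, cfg.peak_min_separation)
    intervals = ballistic_intervals(peaks)
    if len(intervals) < 2:  # unbiased variance needs >= 2 intervals
        raise ValueError("insufficient sway-density peaks")
    var_ibi_op = float(np.var(intervals, ddof=1))

    return FeatureVector(rho_cl_50=rho_cl_50, a_cl_10=a_cl_10,
                         var_y_cl=var_y_cl, x_ratio_10=float(x_ratio_10),
                         var_ibi_op=var_ibi_op)
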