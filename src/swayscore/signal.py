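"""Center-of-pressure signal handling.

Force platforms such as the Wii Balance Board emit samples at an inherently
non-constant rate.  This module turns those irregular recordings into uniform
25 Hz statokinesigrams via a sliding-window average resampler (SWARII-style),
and provides trajectory centering.

Units are centimetres and seconds throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RawTrace",
    "UniformTrace",
    "resample_swarii",
    "center_trajectory",
]

#: Resampling rate used for all statokinesigrams (Hz).
DEFAULT_RATE = 25.0

CONDITIONS = ("open", "closed")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class RawTrace:
    """One irregularly-timestamped 2-D CoP recording.

    Attributes
    ----------
    timestamps : array of float
        Sample times in seconds, strictly increasing.
    ml, ap : array of float
        Medio-lateral and antero-posterior CoP coordinates in cm.
    condition : str
        ``"open"`` or ``"closed"`` eyes.
    """

    timestamps: np.ndarray
    ml: np.ndarray
    ap: np.ndarray
    condition: str = "open"

    def __post_init__(self):
        t = _as_float_array(self.timestamps, "timestamps")
        ml = _as_float_array(self.ml, "ml")
        ap = _as_float_array(self.ap, "ap")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if not (len(t) == len(ml) == len(ap)):
            raise ValueError("timestamps, ml and ap must have equal length")
        if len(t) < 2:
            raise ValueError("a trace needs at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise ValueError(
                f"timestamps must be strictly increasing (violated at sample {i + 1})"
            )
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "ml", ml)
        object.__setattr__(self, "ap", ap)

    @property
    def span(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class UniformTrace:
    """A uniformly resampled statokinesigram.

    ``times`` are implied: ``t0 + k / rate`` for ``k = 0 .. len - 1``.
    """

    rate: float
    ml: np.ndarray
    ap: np.ndarray
    t0: float = 0.0
    condition: str = "open"

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        ml = _as_float_array(self.ml, "ml")
        ap = _as_float_array(self.ap, "ap")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if len(ml) != len(ap):
            raise ValueError("ml and ap must have equal length")
        if len(ml) < 2:
            raise ValueError("a uniform trace needs at least 2 samples")
        object.__setattr__(self, "ml", ml)
        object.__setattr__(self, "ap", ap)

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.ml)) / self.rate

    def __len__(self) -> int:
        return len(self.ml)


def _window_means(t: np.ndarray, x: np.ndarray, grid: np.ndarray,
                  half: float) -> np.ndarray:
    """Mean of raw samples inside the closed window [g - half, g + half].

    Empty windows are filled by linear interpolation between the nearest
    non-empty window means (constant extension at the ends).
    """
    lo = np.searchsorted(t, grid - half, side="left")
    hi = np.searchsorted(t, grid + half, side="right")
    counts = hi - lo
    csum = np.concatenate(([0.0], np.cumsum(x)))
    with np.errstate(invalid="ignore"):
        means = (csum[hi] - csum[lo]) / counts
    nonempty = counts > 0
    if not np.any(nonempty):
        raise ValueError("all resampling windows are empty")
    if not np.all(nonempty):
        idx = np.arange(len(grid))
        means = np.where(
            nonempty, means,
            np.interp(idx, idx[nonempty], means[nonempty]),
        )
    return means


def resample_swarii(raw: RawTrace, rate: float = DEFAULT_RATE,
                    window: float | None = None) -> UniformTrace:
    """Resample an irregular trace onto a uniform grid by window averaging.

    Each output sample at grid time ``t_k`` is the arithmetic mean of all raw
    samples whose timestamp falls in the closed window
    ``[t_k - window/2, t_k + window/2]``; grid points with an empty window are
    filled by linear interpolation between neighbouring window means.  The
    grid starts at the first raw timestamp and is restricted to the raw span.

    Parameters
    ----------
    rate : float
        Output rate in Hz (default 25).
    window : float, optional
        Window width in seconds; defaults to ``1 / rate``, which makes the
        resampler exact on grid-aligned input.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if window is None:
        window = 1.0 / rate
    if window <= 0:
        raise ValueError("window must be positive")
    if raw.span < 2.0 / rate:
        raise ValueError("trace too short")
    # Tolerate float rounding so a grid point exactly at the end survives.
    n_out = int(np.floor(raw.span * rate + 1e-9)) + 1
    t0 = float(raw.timestamps[0])
    grid = t0 + np.arange(n_out) / rate
    half = window / 2.0
    ml = _window_means(raw.timestamps, raw.ml, grid, half)
    ap = _window_means(raw.timestamps, raw.ap, grid, half)
    return UniformTrace(rate=rate, ml=ml, ap=ap, t0=t0, condition=raw.condition)


def center_trajectory(trace: UniformTrace) -> UniformTrace:
    """Subtract the per-record mean from each axis (idempotent)."""
    return replace(trace, ml=trace.ml - trace.ml.mean(),
                   ap=trace.ap - trace.ap.mean())
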