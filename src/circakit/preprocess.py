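"""Preprocessing operators applied before every analysis.

The standard pipeline for a luminescence or temperature trace is a centred
2 h moving average followed by subtraction of a centred 24 h running average
(detrending).  Temperature phase analysis additionally needs the above-mean
mask and the phases of the top-quantile samples of a detrended trace.

Edge policy: windows are never shrunk.  A sample whose centred window extends
beyond the record, or whose window holds fewer than 90% valid samples, is
marked invalid in the output rather than estimated from a truncated window.
"""

from __future__ import annotations

import numpy as np

from .circular import PhaseSet
from .series import UniformSeries

__all__ = [
    "window_samples",
    "moving_average",
    "running_average",
    "detrend_running_average",
    "above_mean_mask",
    "top_quantile_phases",
]

_MIN_VALID_FRACTION = 0.9


def window_samples(window_h: float, step_minutes: float) -> int:
    """Number of samples in a centred window: ``window_h`` rounded to the
    nearest odd sample count so the window centres exactly on a sample."""
    n = int(round(window_h * 60.0 / step_minutes))
    if n < 1:
        n = 1
    if n % 2 == 0:
        n += 1
    return n


def _centered_mean(s: UniformSeries, window_h: float) -> UniformSeries:
    n_win = window_samples(window_h, s.step_minutes)
    if n_win > s.n:
        raise ValueError("window longer than the record")
    half = n_win // 2
    validf = s.valid.astype(float)
    vals = np.where(s.valid, s.values.astype(float), 0.0)
    kernel = np.ones(n_win)
    sums = np.convolve(vals, kernel, mode="same")
    counts = np.convolve(validf, kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    ok = counts >= _MIN_VALID_FRACTION * n_win
    # windows that stick out of the record are invalid regardless of content
    idx = np.arange(s.n)
    ok &= (idx >= half) & (idx < s.n - half)
    ok &= s.valid
    means = np.where(ok, means, np.nan)
    return UniformSeries(s.start_time_h, s.step_minutes, means, ok)


def moving_average(s: UniformSeries, window_h: float) -> UniformSeries:
    """Centred moving average over ``window_h`` (2 h for luminescence traces)."""
    if window_h * 60.0 < s.step_minutes - 1e-9:
        raise ValueError("window must be at least one sampling step")
    return _centered_mean(s, window_h)


def running_average(s: UniformSeries, window_h: float = 24.0) -> UniformSeries:
    """Centred running average (the baseline estimate used for detrending)."""
    return _centered_mean(s, window_h)


def detrend_running_average(s: UniformSeries, window_h: float = 24.0) -> UniformSeries:
    """Subtract a centred ``window_h`` running average (default 24 h).

    Removes slow baseline drift while leaving circadian oscillations intact;
    edge samples whose window leaves the record come back invalid.
    """
    if s.duration_h < window_h:
        raise ValueError("record shorter than the detrending window")
    base = _centered_mean(s, window_h)
    vals = np.where(base.valid, s.values.astype(float) - base.values, np.nan)
    return UniformSeries(s.start_time_h, s.step_minutes, vals, base.valid.copy())


def above_mean_mask(s: UniformSeries) -> np.ndarray:
    """True where a valid sample lies strictly above the mean of all valid
    samples (the display rule for elevated body temperature)."""
    if not s.valid.any():
        raise ValueError("series has no valid samples")
    mean = float(s.values[s.valid].mean())
    return s.valid & (s.values > mean)


def top_quantile_phases(s_detrended: UniformSeries, q: float = 0.2,
                        cycle_h: float = 24.0) -> PhaseSet:
    """Phases (angles on a ``cycle_h`` circle) of the top-``q`` fraction of
    valid samples of a detrended trace.

    With ``q=0.2`` on a detrended temperature record this selects the periods
    of top-20% temperature for a Rayleigh plot.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly between 0 and 1")
    idx = np.flatnonzero(s_detrended.valid)
    k = int(round(q * idx.size))
    if k < 1:
        raise ValueError("quantile selects no samples")
    vals = s_detrended.values[idx]
    order = np.argsort(-vals, kind="stable")[:k]
    chosen = np.sort(idx[order])
    t = s_detrended.times_h[chosen]
    angles = 2.0 * np.pi * np.mod(t, cycle_h) / cycle_h
    return PhaseSet(angles, cycle_h=cycle_h)
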