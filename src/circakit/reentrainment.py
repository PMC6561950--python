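"""Activity-onset detection and re-entrainment metrics.

Two quantities summarise how fast an animal re-adjusts to a shifted light
schedule:

* PS50 — the number of days to reach 50% of an imposed phase shift, read from
  a variable-slope sigmoid fitted to the daily onset shifts,

      Y = Bottom + (Top - Bottom) / (1 + 10**((logPS50 - X) * HillSlope)),

  with X = log10(day), so the curve is a Hill function of the day number and
  Y(day = PS50) = (Top + Bottom)/2 exactly.

* the phase-shift magnitude for a single advance followed by release into
  constant darkness — the gap, at the transition day, between the pre- and
  post-shift onset regression lines, both drawn with the free-running slope
  (period - 24) h/day.

Activity onsets themselves are detected per day by correlating the activity
profile with a step template (quiescence followed by activity), the community
default for wheel-running and PIR records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .series import UniformSeries

__all__ = [
    "OnsetSeries",
    "SigmoidFit",
    "SigmoidFitError",
    "sigmoid_shift",
    "detect_onsets",
    "onset_shifts",
    "fit_ps50",
    "phase_shift_magnitude",
    "unwrap_hours",
]


@dataclass
class OnsetSeries:
    """One value per day: clock time of activity onset, or an onset *shift*
    in hours relative to a reference schedule (context decides)."""

    day: np.ndarray
    hours: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.day = np.asarray(self.day, dtype=int)
        self.hours = np.asarray(self.hours, dtype=float)
        if self.valid is None:
            self.valid = ~np.isnan(self.hours)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.day.shape == self.hours.shape == self.valid.shape):
            raise ValueError("day, hours and valid must have equal length")
        if np.unique(self.day).size != self.day.size:
            raise ValueError("one entry per day required")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class SigmoidFit:
    """Fitted variable-slope sigmoid; ``ps50_days = 10**log_ps50``."""

    top: float
    bottom: float
    hillslope: float
    log_ps50: float
    rss: float
    converged: bool
    n_points: int

    @property
    def ps50_days(self) -> float:
        return float(10.0**self.log_ps50)

    def predict(self, day) -> np.ndarray:
        return sigmoid_shift(day, self.ps50_days, self.top, self.bottom, self.hillslope)


class SigmoidFitError(RuntimeError):
    """Non-convergence; carries the best parameters found so far."""

    def __init__(self, message: str, best: SigmoidFit):
        super().__init__(message)
        self.best = best


def sigmoid_shift(day, ps50_days: float, top: float, bottom: float,
                  hillslope: float) -> np.ndarray:
    """Shift achieved by ``day`` on the variable-slope sigmoid (X=log10 day)."""
    if ps50_days <= 0:
        raise ValueError("ps50_days must be positive")
    d = np.asarray(day, dtype=float)
    if np.any(d <= 0):
        raise ValueError("day numbers must be positive (day 1 = first shifted day)")
    x = np.log10(d)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((np.log10(ps50_days) - x) * hillslope))


# ---------------------------------------------------------------------------
# onset detection
# ---------------------------------------------------------------------------

def detect_onsets(s: UniformSeries, search_window_h: float = 4.0,
                  quiescent_h: float = 6.0, active_h: float = 6.0) -> OnsetSeries:
    """Daily activity onsets by step-template correlation.

    The onset score at a sample is the mean activity of the following
    ``active_h`` hours minus the mean of the preceding ``quiescent_h`` hours;
    the day's onset is the time maximising that score.  From the second
    detected day onward the search is confined to ``search_window_h`` around
    the previous day's onset clock time.  Days with no activity, or where no
    candidate scores positive, come back invalid.
    """
    step_h = s.step_h
    nq = int(round(quiescent_h / step_h))
    na = int(round(active_h / step_h))
    if nq < 1 or na < 1:
        raise ValueError("template windows must span at least one sample")
    v = np.where(s.valid, s.values.astype(float), 0.0)
    c = np.concatenate([[0.0], np.cumsum(v)])
    n = s.n
    i = np.arange(n)
    score = np.full(n, -np.inf)
    ok = (i >= nq) & (i + na <= n)
    fwd = (c[np.minimum(i + na, n)] - c[i]) / na
    bwd = (c[i] - c[np.maximum(i - nq, 0)]) / nq
    score[ok] = fwd[ok] - bwd[ok]

    t = s.times_h
    day_of = np.floor(t / 24.0).astype(int)
    days = np.arange(day_of.min(), day_of.max() + 1)
    onset_h = np.full(days.size, np.nan)
    prev_clock: float | None = None
    for j, d in enumerate(days):
        in_day = day_of == d
        cand = np.flatnonzero(in_day & np.isfinite(score))
        if cand.size == 0 or v[in_day].sum() == 0:
            continue
        if prev_clock is not None:
            dist = np.abs((np.mod(t[cand] - prev_clock, 24.0) + 12.0) % 24.0 - 12.0)
            near = cand[dist <= search_window_h + 1e-9]
            if near.size:
                cand = near
        best = cand[np.argmax(score[cand])]
        if score[best] <= 0:
            continue
        onset_h[j] = np.mod(t[best], 24.0)
        prev_clock = onset_h[j]
    return OnsetSeries(days, onset_h)


def unwrap_hours(hours: np.ndarray, period: float = 24.0) -> np.ndarray:
    """Remove modulo-``period`` jumps so consecutive values differ by < period/2."""
    h = np.asarray(hours, dtype=float).copy()
    last = None
    for i in range(h.size):
        if np.isnan(h[i]):
            continue
        if last is not None:
            h[i] -= period * np.round((h[i] - last) / period)
        last = h[i]
    return h


def onset_shifts(onsets: OnsetSeries, baseline_onset_h: float,
                 advance: bool = True) -> OnsetSeries:
    """Per-day shift (hours achieved) of onsets relative to the pre-shift
    baseline onset clock time; advances counted positive, sequence unwrapped."""
    raw = np.where(onsets.valid, onsets.hours, np.nan)
    delta = baseline_onset_h - raw if advance else raw - baseline_onset_h
    delta = np.mod(delta + 12.0, 24.0) - 12.0  # representative near zero first
    delta = unwrap_hours(delta)
    return OnsetSeries(onsets.day, delta, onsets.valid.copy())


# ---------------------------------------------------------------------------
# PS50 sigmoid fit
# ---------------------------------------------------------------------------

_LOG_PS50_BOUNDS = (np.log10(0.1), np.log10(30.0))


def fit_ps50(onset_shift: OnsetSeries, fix_top: float | None = None,
             fix_bottom: float | None = None, imposed_shift_h: float = 8.0) -> SigmoidFit:
    """Fit the variable-slope sigmoid to daily onset shifts.

    ``onset_shift`` holds the shift achieved on each day (day 1 = first day of
    the new schedule).  All four parameters are fitted by default; ``fix_top``
    / ``fix_bottom`` pin the asymptotes (e.g. to the imposed shift and zero).
    """
    ok = onset_shift.valid & (onset_shift.day >= 1)
    if ok.sum() < 5:
        raise ValueError("need at least five valid post-shift days to fit PS50")
    d = onset_shift.day[ok].astype(float)
    y = onset_shift.hours[ok]

    top0 = imposed_shift_h if fix_top is None else fix_top
    bot0 = 0.0 if fix_bottom is None else fix_bottom
    mid = (top0 + bot0) / 2.0
    above = d[y >= mid]
    ps0 = float(np.clip(above.min() if above.size else np.median(d), 0.2, 25.0))

    free_top = fix_top is None
    free_bot = fix_bottom is None

    def unpack(theta):
        i = 0
        if free_top:
            top = theta[i]; i += 1
        else:
            top = fix_top
        if free_bot:
            bot = theta[i]; i += 1
        else:
            bot = fix_bottom
        hill, logps = theta[i], theta[i + 1]
        return top, bot, hill, logps

    def resid(theta):
        top, bot, hill, logps = unpack(theta)
        x = np.log10(d)
        pred = bot + (top - bot) / (1.0 + 10.0 ** ((logps - x) * hill))
        return pred - y

    theta0, lo, hi = [], [], []
    if free_top:
        theta0 += [top0]; lo += [-30.0]; hi += [30.0]
    if free_bot:
        theta0 += [bot0]; lo += [-30.0]; hi += [30.0]
    theta0 += [2.0, np.log10(ps0)]
    lo += [0.05, _LOG_PS50_BOUNDS[0]]
    hi += [50.0, _LOG_PS50_BOUNDS[1]]

    sol = least_squares(resid, theta0, bounds=(lo, hi),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=5000)
    top, bot, hill, logps = unpack(sol.x)
    fit = SigmoidFit(
        top=float(top), bottom=float(bot), hillslope=float(hill),
        log_ps50=float(logps), rss=float(np.sum(sol.fun**2)),
        converged=bool(sol.success), n_points=int(d.size),
    )
    if not sol.success:
        raise SigmoidFitError(f"sigmoid fit did not converge: {sol.message}", fit)
    return fit


# ---------------------------------------------------------------------------
# single-advance phase-shift magnitude
# ---------------------------------------------------------------------------

def _fixed_slope_intercept(onsets: OnsetSeries, slope: float) -> float:
    ok = onsets.valid
    if ok.sum() < 3:
        raise ValueError("need at least three valid onsets")
    d = onsets.day[ok].astype(float)
    y = unwrap_hours(onsets.hours[ok])
    return float(np.mean(y - slope * d))


def phase_shift_magnitude(pre_onsets: OnsetSeries, post_onsets: OnsetSeries,
                          period_h: float, transition_day: float | None = None) -> float:
    """Phase-shift magnitude (hours, advances positive) at the transition day.

    Both onset series are fitted by least squares with the slope fixed at the
    free-running drift ``period_h - 24`` h/day; the magnitude is the pre-shift
    line minus the post-shift line evaluated at the transition day (a line
    displaced 8 h earlier therefore reads +8 h).
    """
    slope = period_h - 24.0
    b_pre = _fixed_slope_intercept(pre_onsets, slope)
    b_post = _fixed_slope_intercept(post_onsets, slope)
    if transition_day is None:
        transition_day = float(post_onsets.day[post_onsets.valid].min())
    # fixed equal slopes: the gap is day-independent, but evaluate explicitly
    pre_line = b_pre + slope * transition_day
    post_line = b_post + slope * transition_day
    return float(pre_line - post_line)
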