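"""Uniformly sampled time series and light schedules.

:class:`UniformSeries` is the single carrier for every recording type the
toolkit analyses — locomotor activity counts, ex vivo bioluminescence and core
body temperature.  Time is measured in hours from the start of the recording
(ZT0 = lights-on when a light:dark schedule applies); sample ``i`` sits at
``start_time_h + i * step_minutes / 60``.

:class:`LightSchedule` describes the lighting program day by day and supports
the standard chronobiology protocols: LD 12:12, constant darkness (DD),
constant light (LL), an n-hour phase advance of the LD cycle on a given day,
and a single advance followed by release into DD.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UniformSeries",
    "LightSchedule",
    "read_series_csv",
    "write_series_csv",
]


@dataclass
class UniformSeries:
    """A uniformly sampled numeric series with a per-sample validity mask."""

    start_time_h: float
    step_minutes: float
    values: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.step_minutes <= 0:
            raise ValueError("step_minutes must be positive")
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.values.shape:
            raise ValueError("values and valid mask must have the same length")
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.size

    @property
    def step_h(self) -> float:
        return self.step_minutes / 60.0

    @property
    def times_h(self) -> np.ndarray:
        return self.start_time_h + np.arange(self.n) * self.step_h

    @property
    def duration_h(self) -> float:
        return self.n * self.step_h

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    # -- derived series -------------------------------------------------
    def slice_time(self, t0_h: float, t1_h: float) -> "UniformSeries":
        """Samples with ``t0_h <= t < t1_h`` (half-open, in recording hours)."""
        t = self.times_h
        keep = (t >= t0_h - 1e-9) & (t < t1_h - 1e-9)
        if not keep.any():
            raise ValueError("time slice contains no samples")
        i0, i1 = np.flatnonzero(keep)[[0, -1]]
        return UniformSeries(
            start_time_h=float(t[i0]),
            step_minutes=self.step_minutes,
            values=self.values[i0 : i1 + 1].copy(),
            valid=self.valid[i0 : i1 + 1].copy(),
        )

    def rebin_sum(self, bin_minutes: float) -> "UniformSeries":
        """Aggregate into coarser bins by summation (e.g. 1-min counts → 6-min).

        ``bin_minutes`` must be an integer multiple of the current step; a
        trailing partial bin is dropped.  A coarse bin is valid only if all of
        its constituent samples are valid.
        """
        factor = bin_minutes / self.step_minutes
        k = int(round(factor))
        if k < 1 or abs(factor - k) > 1e-9:
            raise ValueError("bin_minutes must be an integer multiple of step_minutes")
        if k == 1:
            return replace(self, values=self.values.copy(), valid=self.valid.copy())
        m = (self.n // k) * k
        vals = self.values[:m].reshape(-1, k).sum(axis=1)
        ok = self.valid[:m].reshape(-1, k).all(axis=1)
        return UniformSeries(self.start_time_h, bin_minutes, vals, ok)

    def with_values(self, values: np.ndarray, valid: np.ndarray | None = None) -> "UniformSeries":
        return UniformSeries(self.start_time_h, self.step_minutes, values,
                             self.valid.copy() if valid is None else valid)


# ---------------------------------------------------------------------------
# light schedules
# ---------------------------------------------------------------------------

_NO_LIGHT = np.nan


@dataclass
class LightSchedule:
    """Per-day lighting program.

    Each day ``d`` (day boundaries at multiples of 24 h from recording start)
    carries a lights-on and lights-off clock hour.  ``nan`` marks a day with no
    light (DD); ``(0, 24)`` marks constant light (LL).  An interval with
    ``off < on`` wraps across midnight.  Recorded phase-advance events are kept
    for provenance and for entrained-phase bookkeeping in the simulator.
    """

    lights_on_h: np.ndarray
    lights_off_h: np.ndarray
    advances: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lights_on_h = np.atleast_1d(np.asarray(self.lights_on_h, dtype=float))
        self.lights_off_h = np.atleast_1d(np.asarray(self.lights_off_h, dtype=float))
        if self.lights_on_h.shape != self.lights_off_h.shape:
            raise ValueError("lights_on_h and lights_off_h must have equal length")
        on = self.lights_on_h[~np.isnan(self.lights_on_h)]
        if ((on < 0) | (on >= 24)).any():
            raise ValueError("lights-on hours must lie in [0, 24)")
        for _, h in self.advances:
            if not 0 < h < 24:
                raise ValueError("advance hours must lie in (0, 24)")

    # -- constructors ----------------------------------------------------
    @classmethod
    def ld(cls, n_days: int, lights_on_h: float = 0.0, photoperiod_h: float = 12.0) -> "LightSchedule":
        off = (lights_on_h + photoperiod_h) % 24.0
        return cls(np.full(n_days, lights_on_h), np.full(n_days, off))

    @classmethod
    def dd(cls, n_days: int) -> "LightSchedule":
        return cls(np.full(n_days, _NO_LIGHT), np.full(n_days, _NO_LIGHT))

    @classmethod
    def ll(cls, n_days: int) -> "LightSchedule":
        return cls(np.zeros(n_days), np.full(n_days, 24.0))

    def __add__(self, other: "LightSchedule") -> "LightSchedule":
        shifted = [(d + self.n_days, h) for d, h in other.advances]
        return LightSchedule(
            np.concatenate([self.lights_on_h, other.lights_on_h]),
            np.concatenate([self.lights_off_h, other.lights_off_h]),
            list(self.advances) + shifted,
        )

    def with_advance(self, day: int, hours: float) -> "LightSchedule":
        """Advance the lighting program by ``hours`` from ``day`` onward."""
        if not 0 < hours < 24:
            raise ValueError("advance hours must lie in (0, 24)")
        on = self.lights_on_h.copy()
        off = self.lights_off_h.copy()
        on[day:] = np.where(np.isnan(on[day:]), on[day:], (on[day:] - hours) % 24.0)
        off[day:] = np.where(np.isnan(off[day:]), off[day:], (off[day:] - hours) % 24.0)
        return LightSchedule(on, off, list(self.advances) + [(day, hours)])

    @classmethod
    def jet_lag(cls, n_pre_days: int = 10, advance_h: float = 8.0,
                n_post_days: int = 14, lights_on_h: float = 0.0) -> "LightSchedule":
        """LD 12:12 with an ``advance_h`` phase advance after ``n_pre_days``."""
        return cls.ld(n_pre_days + n_post_days, lights_on_h).with_advance(n_pre_days, advance_h)

    @classmethod
    def advance_then_dd(cls, n_pre_days: int = 10, advance_h: float = 8.0,
                        n_advanced_ld_days: int = 1, n_dd_days: int = 14,
                        lights_on_h: float = 0.0) -> "LightSchedule":
        """A single phase advance followed by release into constant darkness."""
        sched = cls.ld(n_pre_days + n_advanced_ld_days, lights_on_h)
        sched = sched.with_advance(n_pre_days, advance_h)
        return sched + cls.dd(n_dd_days)

    # -- queries ----------------------------------------------------------
    @property
    def n_days(self) -> int:
        return self.lights_on_h.size

    def is_light(self, t_h) -> np.ndarray:
        """Boolean light state at absolute recording time(s) ``t_h``."""
        t = np.atleast_1d(np.asarray(t_h, dtype=float))
        day = np.clip((t // 24.0).astype(int), 0, self.n_days - 1)
        h = np.mod(t, 24.0)
        on = self.lights_on_h[day]
        off = self.lights_off_h[day]
        ll = (off - on) >= 24.0 - 1e-9
        plain = (h >= on) & (h < off)
        wrapped = (h >= on) | (h < off)
        lit = np.where(off >= on, plain, wrapped) | ll
        lit = np.where(np.isnan(on), False, lit)
        return lit if np.ndim(t_h) else bool(lit[0])

    def is_ld_day(self, day: int) -> bool:
        """True when day ``day`` has both a light and a dark portion."""
        on, off = self.lights_on_h[day], self.lights_off_h[day]
        if np.isnan(on):
            return False
        return (off - on) % 24.0 not in (0.0,) and (off - on) < 24.0 - 1e-9

    def mid_dark_h(self, day: int) -> float:
        """Absolute time (h) of the middle of the dark period of ``day``."""
        on, off = self.lights_on_h[day], self.lights_off_h[day]
        dark_len = (on - off) % 24.0
        return day * 24.0 + (off + dark_len / 2.0) % 24.0


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def write_series_csv(path, s: UniformSeries, header: dict | None = None) -> None:
    """Write ``time_h,value[,valid]`` CSV, with parameters as ``#`` comments."""
    buf = io.StringIO()
    if header:
        for k, v in header.items():
            buf.write(f"# {k}: {v}\n")
    all_valid = bool(s.valid.all())
    buf.write("time_h,value" + ("" if all_valid else ",valid") + "\n")
    t = s.times_h
    for i in range(s.n):
        row = f"{t[i]:.6f},{s.values[i]:.10g}"
        if not all_valid:
            row += f",{int(s.valid[i])}"
        buf.write(row + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_series_csv(path) -> UniformSeries:
    """Read a two- or three-column ``time_h,value[,valid]`` CSV.

    Lines starting with ``#`` are ignored.  The time column must be uniform;
    its spacing defines ``step_minutes``.
    """
    df = pd.read_csv(path, comment="#")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("need at least two samples to infer the sampling step")
    steps = np.diff(t)
    step = float(np.median(steps))
    if step <= 0 or not np.allclose(steps, step, rtol=0, atol=1e-6):
        raise ValueError("time column is not uniformly sampled")
    values = df.iloc[:, 1].to_numpy(dtype=float)
    valid = None
    if df.shape[1] >= 3:
        valid = df.iloc[:, 2].to_numpy().astype(bool)
    return UniformSeries(float(t[0]), step * 60.0, values, valid)
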