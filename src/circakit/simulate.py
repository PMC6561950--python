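"""Synthetic circadian recordings with known ground truth.

Every analysis stage in the toolkit can be validated by parameter recovery on
data from this module:

* locomotor activity — cosine-modulated Poisson counts from a phase-only
  oscillator with intrinsic period tau, multiplicative light masking, and
  exponential re-entrainment toward the schedule-entrained phase;
* ex vivo bioluminescence — damped cosine plus linear baseline drift and
  Gaussian noise;
* core body temperature — sinusoid around a mesor with Gaussian noise;
* onset-shift trajectories — the variable-slope re-entrainment sigmoid plus
  daily Gaussian onset jitter;
* phase sets — von Mises draws calibrated (by Bessel-ratio inversion) to a
  target mean resultant length.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circular import PhaseSet, kappa_for_expected_sample_r, kappa_for_r
from .reentrainment import OnsetSeries, sigmoid_shift
from .series import LightSchedule, UniformSeries

__all__ = [
    "ActivitySimParams",
    "BiolumSimParams",
    "TempSimParams",
    "generate_activity",
    "generate_bioluminescence",
    "generate_temperature",
    "generate_onset_shift",
    "sample_von_mises_by_r",
]


@dataclass
class ActivitySimParams:
    """Parameters of the activity simulator.

    intrinsic_period_h : free-running period tau of the oscillator, hours.
    mesor              : expected counts per bin at zero modulation.
    amplitude          : relative modulation depth in [0, 1].
    bin_minutes        : sampling bin (passive-infrared counts, default 1 min).
    duration_days      : length of the record.
    masking_strength   : fraction of expected counts suppressed while lights
                         are on (negative masking), in [0, 1].
    resetting_rate     : per-day fractional correction of oscillator phase
                         toward the schedule-entrained phase while light is
                         present, in [0, 1]; 0 = free-run, ~1 = near-immediate
                         re-entrainment.
    """

    intrinsic_period_h: float = 23.7
    mesor: float = 5.0
    amplitude: float = 0.8
    bin_minutes: float = 1.0
    duration_days: float = 40.0
    masking_strength: float = 0.5
    resetting_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intrinsic_period_h <= 0:
            raise ValueError("intrinsic_period_h must be positive")
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("amplitude must lie in [0, 1]")
        if self.mesor < 0:
            raise ValueError("mesor must be nonnegative")
        if self.duration_days < 1:
            raise ValueError("duration_days must be at least 1")
        if not 0.0 <= self.masking_strength <= 1.0:
            raise ValueError("masking_strength must lie in [0, 1]")
        if not 0.0 <= self.resetting_rate <= 1.0:
            raise ValueError("resetting_rate must lie in [0, 1]")


@dataclass
class BiolumSimParams:
    """Damped-cosine bioluminescence model
    B(t) = baseline_level + baseline_slope*t
           + amplitude * exp(-damping_rate*t) * cos(2*pi*t/period_h + phase)
           + Gaussian noise."""

    period_h: float = 24.0
    amplitude: float = 100.0
    damping_rate: float = 0.0       # per hour
    baseline_level: float = 500.0
    baseline_slope: float = 0.0     # units per hour
    noise_sd: float = 0.0
    sample_minutes: float = 30.0
    duration_days: float = 9.0
    phase_h: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_h <= 0:
            raise ValueError("period_h must be positive")
        if self.damping_rate < 0:
            raise ValueError("damping_rate must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class TempSimParams:
    """Sinusoidal core body temperature around a mesor (degrees C)."""

    mesor_C: float = 36.8
    amplitude_C: float = 0.8
    period_h: float = 24.0
    noise_sd_C: float = 0.15
    sample_minutes: float = 20.0
    duration_days: float = 14.0
    acrophase_h: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_C < 0:
            raise ValueError("amplitude_C must be nonnegative")
        if self.noise_sd_C < 0:
            raise ValueError("noise_sd_C must be nonnegative")
        if self.period_h <= 0:
            raise ValueError("period_h must be positive")


def generate_activity(params: ActivitySimParams, schedule: LightSchedule) -> UniformSeries:
    """Simulate an activity-count record under a lighting schedule.

    The oscillator phase psi (radians; activity peaks at psi = 0 mod 2*pi)
    advances at 2*pi/tau per hour.  On days with both light and dark, while
    the lights are on, psi relaxes toward the entrained phase (activity peak
    at mid-dark) at ``resetting_rate`` per day.  The expected count in a bin
    is ``mesor * (1 + amplitude*cos(psi)) * (1 - masking_strength*light)``;
    realised counts are Poisson.
    """
    n_bins = int(round(params.duration_days * 1440.0 / params.bin_minutes))
    dt_h = params.bin_minutes / 60.0
    if schedule.n_days * 24.0 < params.duration_days * 24.0 - 1e-9:
        raise ValueError("light schedule shorter than the simulated duration")
    t = np.arange(n_bins) * dt_h
    t_mid = t + dt_h / 2.0
    light = schedule.is_light(t_mid)
    day_idx = np.minimum((t_mid // 24.0).astype(int), schedule.n_days - 1)
    ld_day = np.array([schedule.is_ld_day(d) for d in range(schedule.n_days)])
    omega = 2.0 * np.pi / params.intrinsic_period_h

    def entrained_psi(i: int) -> float:
        # activity peak at the middle of the dark period of the current day
        return 2.0 * np.pi * (t_mid[i] - schedule.mid_dark_h(day_idx[i])) / 24.0

    correcting = light & ld_day[day_idx] & (params.resetting_rate > 0)
    psi = np.empty(n_bins)
    psi0 = entrained_psi(0) if ld_day[day_idx[0]] else 0.0
    if not correcting.any():
        psi = psi0 + omega * t_mid
    else:
        k = params.resetting_rate / 24.0  # per hour
        cur = psi0
        for i in range(n_bins):
            psi[i] = cur
            step = omega * dt_h
            if correcting[i]:
                err = entrained_psi(i) - cur
                err = np.mod(err + np.pi, 2.0 * np.pi) - np.pi
                step += k * err * dt_h
            cur += step
    mu = params.mesor * (1.0 + params.amplitude * np.cos(psi))
    mu *= 1.0 - params.masking_strength * light.astype(float)
    rng = np.random.default_rng(params.seed)
    counts = rng.poisson(np.maximum(mu, 0.0))
    return UniformSeries(0.0, params.bin_minutes, counts)


def generate_bioluminescence(params: BiolumSimParams) -> UniformSeries:
    n = int(round(params.duration_days * 1440.0 / params.sample_minutes))
    t = np.arange(n) * params.sample_minutes / 60.0
    phase = 2.0 * np.pi * params.phase_h / params.period_h
    vals = (
        params.baseline_level
        + params.baseline_slope * t
        + params.amplitude * np.exp(-params.damping_rate * t)
        * np.cos(2.0 * np.pi * t / params.period_h + phase)
    )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        vals = vals + rng.normal(0.0, params.noise_sd, size=n)
    return UniformSeries(0.0, params.sample_minutes, vals)


def generate_temperature(params: TempSimParams) -> UniformSeries:
    n = int(round(params.duration_days * 1440.0 / params.sample_minutes))
    t = np.arange(n) * params.sample_minutes / 60.0
    vals = params.mesor_C + params.amplitude_C * np.cos(
        2.0 * np.pi * (t - params.acrophase_h) / params.period_h
    )
    if params.noise_sd_C > 0:
        rng = np.random.default_rng(params.seed)
        vals = vals + rng.normal(0.0, params.noise_sd_C, size=n)
    return UniformSeries(0.0, params.sample_minutes, vals)


def generate_onset_shift(ps50_days: float, top_h: float = 8.0, bottom_h: float = 0.0,
                         hillslope: float = 2.0, n_days: int = 14,
                         noise_sd_h: float = 0.3, seed: int = 0) -> OnsetSeries:
    """Onset-shift trajectory from the re-entrainment sigmoid plus daily noise.

    Day 1 is the first day on the new schedule; with ``noise_sd_h`` = 0 the
    values are the exact sigmoid, so Y at day = ps50_days is (Top+Bottom)/2.
    """
    if ps50_days <= 0:
        raise ValueError("ps50_days must be positive")
    if n_days < 4:
        raise ValueError("n_days must be at least 4")
    days = np.arange(1, n_days + 1)
    y = sigmoid_shift(days, ps50_days, top_h, bottom_h, hillslope)
    if noise_sd_h > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd_h, size=n_days)
    return OnsetSeries(days, y)


def sample_von_mises_by_r(r_target: float, n: int, seed: int = 0,
                          mean_angle: float = 0.0, cycle_h: float = 24.0,
                          match_sample_size: int | None = None) -> PhaseSet:
    """Draw ``n`` angles from a von Mises distribution calibrated to a target
    mean resultant length.

    By default kappa solves A(kappa) = r_target so the *population* resultant
    length equals the target (r_target = 0 gives the uniform distribution).
    With ``match_sample_size=m`` the calibration instead targets the expected
    *sample* statistic at size m, compensating the small-sample upward bias of
    r-hat — appropriate when the target is itself a small-sample estimate.
    """
    if not 0.0 <= r_target < 1.0:
        raise ValueError("r_target must lie in [0, 1)")
    if match_sample_size is None or r_target == 0.0:
        kappa = kappa_for_r(r_target)
    else:
        kappa = kappa_for_expected_sample_r(r_target, match_sample_size)
    rng = np.random.default_rng(seed)
    angles = rng.vonmises(mean_angle, kappa, size=n) if kappa > 0 else rng.uniform(
        0.0, 2.0 * np.pi, size=n)
    return PhaseSet(angles, cycle_h=cycle_h)
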