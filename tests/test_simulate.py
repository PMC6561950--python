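import numpy as np
import pytest
from scipy.stats import chi2

from circakit import (
    ActivitySimParams,
    BiolumSimParams,
    LightSchedule,
    TempSimParams,
    chi2_periodogram,
    detrend_running_average,
    generate_activity,
    generate_bioluminescence,
    generate_onset_shift,
    generate_temperature,
    rayleigh,
    sample_von_mises_by_r,
    top_quantile_phases,
)
from circakit.periodogram import NoRhythmError
from circakit.spectral import TISSUE, power_spectrum


class TestActivityGenerator:
    def test_flat_parameters_give_stationary_mean(self):
        p = ActivitySimParams(amplitude=0.0, masking_strength=0.0, mesor=5.0,
                              duration_days=2.0, seed=0)
        s = generate_activity(p, LightSchedule.ld(2))
        se = np.sqrt(5.0 / s.n)
        assert abs(s.values.mean() - 5.0) <= 3 * se

    def test_counts_are_nonnegative_integers(self):
        p = ActivitySimParams(duration_days=2.0, seed=1)
        s = generate_activity(p, LightSchedule.ld(2))
        assert np.issubdtype(s.values.dtype, np.integer)
        assert (s.values >= 0).all()

    def test_seed_determinism(self):
        p = ActivitySimParams(duration_days=3.0, seed=7)
        sched = LightSchedule.jet_lag(n_pre_days=2, n_post_days=1)
        a = generate_activity(p, sched)
        b = generate_activity(p, sched)
        assert np.array_equal(a.values, b.values)

    def test_poisson_dispersion_at_zero_amplitude(self):
        """With modulation off, counts obey Poisson mean-variance equality
        (index-of-dispersion test over 1e5 bins, alpha=0.01)."""
        p = ActivitySimParams(amplitude=0.0, masking_strength=0.0, mesor=5.0,
                              duration_days=70.0, seed=3)
        s = generate_activity(p, LightSchedule.dd(70))
        x = s.values[:100_000].astype(float)
        n = x.size
        d = (n - 1) * x.var(ddof=1) / x.mean()
        lo, hi = chi2.ppf([0.005, 0.995], n - 1)
        assert lo < d < hi

    def test_schedule_shorter_than_duration_errors(self):
        p = ActivitySimParams(duration_days=5.0)
        with pytest.raises(ValueError):
            generate_activity(p, LightSchedule.ld(3))

    def test_masking_suppresses_light_phase_counts(self):
        p = ActivitySimParams(amplitude=0.0, masking_strength=0.8, mesor=10.0,
                              duration_days=4.0, seed=5)
        s = generate_activity(p, LightSchedule.ld(4))
        light = LightSchedule.ld(4).is_light(s.times_h + s.step_h / 2)
        assert s.values[light].mean() < 0.5 * s.values[~light].mean()

    def test_ld_entrains_activity_to_dark_phase(self):
        p = ActivitySimParams(intrinsic_period_h=23.7, amplitude=0.9,
                              masking_strength=0.0, resetting_rate=0.9,
                              mesor=10.0, duration_days=10.0, seed=9)
        s = generate_activity(p, LightSchedule.ld(10))
        last3 = s.slice_time(7 * 24.0, 10 * 24.0)
        dark = ~LightSchedule.ld(10).is_light(last3.times_h + last3.step_h / 2)
        assert last3.values[dark].mean() > 1.5 * last3.values[~dark].mean()

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ActivitySimParams(amplitude=1.5)
        with pytest.raises(ValueError):
            ActivitySimParams(intrinsic_period_h=0.0)
        with pytest.raises(ValueError):
            ActivitySimParams(mesor=-1.0)


class TestBioluminescenceGenerator:
    def test_pure_cosine_spectral_peak(self):
        p = BiolumSimParams(period_h=24.0, amplitude=50.0, damping_rate=0.0,
                            baseline_slope=0.0, noise_sd=0.0, duration_days=10.0)
        s = generate_bioluminescence(p)
        spec = power_spectrum(s, TISSUE)
        f_peak = spec.frequencies_cph[np.argmax(spec.density)]
        df = spec.frequencies_cph[1] - spec.frequencies_cph[0]
        assert abs(f_peak - 1 / 24.0) <= df / 2 + 1e-12

    def test_noiseless_formula_exact(self):
        p = BiolumSimParams(period_h=24.0, amplitude=10.0, damping_rate=0.01,
                            baseline_level=100.0, baseline_slope=0.5,
                            noise_sd=0.0, duration_days=2.0, phase_h=3.0)
        s = generate_bioluminescence(p)
        t = s.times_h
        expect = (100.0 + 0.5 * t + 10.0 * np.exp(-0.01 * t)
                  * np.cos(2 * np.pi * t / 24.0 + 2 * np.pi * 3.0 / 24.0))
        assert np.allclose(s.values, expect, atol=1e-12)

    def test_half_life_damping_halves_daily_envelope(self):
        lam = np.log(2) / 24.0
        p = BiolumSimParams(amplitude=100.0, damping_rate=lam, noise_sd=0.0,
                            duration_days=7.0)
        s = generate_bioluminescence(p)
        amps = [s.values[d * 48:(d + 1) * 48].max() - s.values[d * 48:(d + 1) * 48].min()
                for d in range(7)]
        ratios = np.array(amps[1:]) / np.array(amps[:-1])
        assert np.allclose(ratios, 0.5, rtol=0.05)

    def test_seed_determinism(self):
        p = BiolumSimParams(noise_sd=5.0, seed=11)
        a, b = generate_bioluminescence(p), generate_bioluminescence(p)
        assert np.array_equal(a.values, b.values)


class TestTemperatureGenerator:
    def test_arrhythmic_noise_has_no_significant_period(self):
        """amplitude 0: the periodogram of the detrended record should stay
        below the detection threshold in at least 95% of seeds."""
        quiet = 0
        n_seeds = 20
        for seed in range(n_seeds):
            p = TempSimParams(amplitude_C=0.0, noise_sd_C=0.3, duration_days=14.0,
                              seed=seed)
            det = detrend_running_average(generate_temperature(p), 24.0)
            res = chi2_periodogram(det, 20.0, 28.0)
            corrected = chi2.ppf(1 - 0.05 / res.qp.size, res.df)
            if not (res.qp > corrected).any():
                quiet += 1
        assert quiet / n_seeds >= 0.95

    def test_top_quantile_window_width_matches_cosine_quantile(self):
        """amplitude 1, no noise: the top-20% mask is a contiguous ~4.8 h
        window around the acrophase each cycle (arccos arithmetic)."""
        p = TempSimParams(amplitude_C=1.0, noise_sd_C=0.0, duration_days=14.0,
                          acrophase_h=6.0)
        det = detrend_running_average(generate_temperature(p), 24.0)
        ph = top_quantile_phases(det, q=0.2)
        hours = ph.to_hours()
        dev = np.abs((hours - 6.0 + 12.0) % 24.0 - 12.0)
        assert dev.max() <= 2.4 + p.sample_minutes / 60.0
        assert rayleigh(ph).mean_hour(24.0) == pytest.approx(6.0, abs=p.sample_minutes / 60.0)

    def test_seed_determinism(self):
        p = TempSimParams(seed=2)
        a, b = generate_temperature(p), generate_temperature(p)
        assert np.array_equal(a.values, b.values)


class TestOnsetShiftGenerator:
    def test_noiseless_midpoint_exact(self):
        traj = generate_onset_shift(4.0, top_h=8.0, bottom_h=0.0, hillslope=2.0,
                                    n_days=14, noise_sd_h=0.0)
        assert traj.hours[3] == pytest.approx(4.0, abs=1e-12)  # day 4 = PS50

    def test_wt_like_refit_recovers_ps50(self):
        from circakit import fit_ps50

        traj = generate_onset_shift(5.33, noise_sd_h=0.3, seed=21)
        fit = fit_ps50(traj, fix_top=8.0, fix_bottom=0.0)
        assert fit.ps50_days == pytest.approx(5.33, rel=0.05)

    def test_step_limit_matches_brute_formula(self):
        days = np.arange(1, 15)
        traj = generate_onset_shift(5.0, hillslope=300.0, n_days=14, noise_sd_h=0.0)
        brute = np.where(days < 5, 0.0, np.where(days > 5, 8.0, 4.0))
        assert np.allclose(traj.hours, brute, atol=1e-6)

    def test_validation(self):
        with pytest.raises(ValueError):
            generate_onset_shift(-1.0)
        with pytest.raises(ValueError):
            generate_onset_shift(5.0, n_days=3)


class TestVonMisesSampler:
    def test_seed_determinism(self):
        a = sample_von_mises_by_r(0.6, 50, seed=4)
        b = sample_von_mises_by_r(0.6, 50, seed=4)
        assert np.array_equal(a.angles, b.angles)

    def test_uniform_null(self):
        ph = sample_von_mises_by_r(0.0, 10_000, seed=8)
        assert rayleigh(ph).r < 0.05

    def test_small_sample_calibration_unbiased(self):
        """match_sample_size compensates the small-n upward bias of r-hat."""
        rs = [rayleigh(sample_von_mises_by_r(0.42, 14, seed=s, match_sample_size=14)).r
              for s in range(400)]
        assert np.mean(rs) == pytest.approx(0.42, abs=0.02)
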