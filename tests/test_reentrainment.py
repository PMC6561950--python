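import numpy as np
import pytest

from circakit import (
    OnsetSeries,
    detect_onsets,
    fit_ps50,
    generate_onset_shift,
    onset_shifts,
    phase_shift_magnitude,
    sigmoid_shift,
)
from circakit.reentrainment import unwrap_hours


class TestSigmoidModel:
    def test_midpoint_identity(self):
        for ps50 in (0.5, 2.0, 5.33, 8.0):
            y = sigmoid_shift(ps50, ps50, top=8.0, bottom=0.0, hillslope=2.0)
            assert y == pytest.approx(4.0, abs=1e-12)

    def test_large_hillslope_approaches_step_function(self):
        days = np.arange(1, 15, dtype=float)
        y = sigmoid_shift(days, 5.0, 8.0, 0.0, hillslope=200.0)
        brute = np.where(days < 5.0, 0.0, np.where(days > 5.0, 8.0, 4.0))
        assert np.allclose(y, brute, atol=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sigmoid_shift(1.0, -2.0, 8.0, 0.0, 2.0)
        with pytest.raises(ValueError):
            sigmoid_shift(0.0, 5.0, 8.0, 0.0, 2.0)


class TestFitPs50:
    @pytest.mark.parametrize("ps50", [0.5, 1.0, 2.0, 5.0, 8.0])
    @pytest.mark.parametrize("hill", [1.0, 2.0, 5.0])
    def test_noiseless_exact_recovery(self, ps50, hill):
        traj = generate_onset_shift(ps50, top_h=8.0, bottom_h=0.0, hillslope=hill,
                                    n_days=14, noise_sd_h=0.0)
        fit = fit_ps50(traj)
        assert fit.ps50_days == pytest.approx(ps50, rel=1e-6)
        assert fit.top == pytest.approx(8.0, rel=1e-6)
        assert fit.bottom == pytest.approx(0.0, abs=1e-5)
        assert fit.hillslope == pytest.approx(hill, rel=1e-6)
        assert fit.rss < 1e-12

    def test_fitted_curve_midpoint(self):
        traj = generate_onset_shift(5.33, noise_sd_h=0.3, seed=12)
        fit = fit_ps50(traj, fix_top=8.0, fix_bottom=0.0)
        mid = fit.predict(fit.ps50_days)
        assert mid == pytest.approx((fit.top + fit.bottom) / 2, abs=1e-9)

    def test_too_few_days_rejected(self):
        traj = OnsetSeries(np.arange(1, 5), np.array([0.1, 0.5, 2.0, 4.0]))
        with pytest.raises(ValueError):
            fit_ps50(traj)


class TestDetectOnsets:
    def test_noiseless_square_wave_exact(self, square_wave):
        s = square_wave(6.0, onset_h=18.0, step_minutes=6.0)
        onsets = detect_onsets(s)
        got = onsets.hours[onsets.valid]
        assert got.size >= 5
        assert np.allclose(got, 18.0, atol=1e-9)

    def test_constant_activity_all_invalid(self):
        from circakit import UniformSeries

        s = UniformSeries(0.0, 6.0, np.full(6 * 240, 5.0))
        onsets = detect_onsets(s)
        assert onsets.n_valid == 0

    def test_all_zero_day_invalid(self, square_wave):
        s = square_wave(6.0, onset_h=18.0, step_minutes=6.0)
        day2 = slice(2 * 240, 3 * 240)
        s.values[day2] = 0.0
        onsets = detect_onsets(s)
        assert not onsets.valid[2]

    def test_noisy_square_wave_within_15_minutes(self):
        """Poisson square wave: detected onsets within 15 min of truth on at
        least 95% of days across seeds."""
        hits = total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 7 * 1440
            t = np.arange(n) / 60.0
            mu = np.where(np.mod(t - 18.0, 24.0) < 12.0, 5.0, 0.5)
            from circakit import UniformSeries

            s = UniformSeries(0.0, 1.0, rng.poisson(mu).astype(float))
            onsets = detect_onsets(s)
            ok = onsets.valid
            err = np.abs(onsets.hours[ok] - 18.0)
            hits += int((np.minimum(err, 24.0 - err) <= 0.25).sum())
            total += int(ok.sum())
        assert total >= 20 * 6
        assert hits / total >= 0.95

    def test_shift_equivariance_on_interior_days(self, square_wave):
        # the final day is excluded: a shifted onset near the record end loses
        # its full forward template window
        base = detect_onsets(square_wave(6.0, onset_h=18.0, step_minutes=6.0))
        shifted = detect_onsets(square_wave(6.0, onset_h=21.0, step_minutes=6.0))
        both = (base.valid & shifted.valid)[:-1]
        b = base.hours[:-1][both]
        sh = shifted.hours[:-1][both]
        assert b.size >= 4
        assert np.allclose(np.mod(sh - b, 24.0), 3.0, atol=1e-9)

    def test_template_scan_matches_naive_oracle(self):
        """Implementation equals a literal per-sample template scan."""
        rng = np.random.default_rng(5)
        n = 3 * 240
        t = np.arange(n) * 0.1
        mu = np.where(np.mod(t - 18.0, 24.0) < 12.0, 6.0, 0.3)
        vals = rng.poisson(mu).astype(float)
        from circakit import UniformSeries

        s = UniformSeries(0.0, 6.0, vals)
        onsets = detect_onsets(s, search_window_h=12.0)
        nq = na = 60  # 6 h at 6-min sampling
        # naive scan for day 1 (first day with full windows on both sides)
        best_score, best_i = -np.inf, None
        for i in range(240, 480):
            if i < nq or i + na > n:
                continue
            fwd = sum(vals[i:i + na]) / na
            bwd = sum(vals[i - nq:i]) / nq
            if fwd - bwd > best_score:
                best_score, best_i = fwd - bwd, i
        assert onsets.valid[1]
        assert onsets.hours[1] == pytest.approx((best_i * 0.1) % 24.0, abs=1e-9)


class TestOnsetShifts:
    def test_unwrap_removes_midnight_jumps(self):
        h = np.array([23.5, 0.5, 1.5, 23.0])
        u = unwrap_hours(h)
        assert np.allclose(u, [23.5, 24.5, 25.5, 23.0])

    def test_advance_counts_positive(self):
        onsets = OnsetSeries(np.arange(1, 6), np.array([18.0, 16.0, 14.0, 12.0, 10.0]))
        shifts = onset_shifts(onsets, baseline_onset_h=18.0, advance=True)
        assert np.allclose(shifts.hours, [0.0, 2.0, 4.0, 6.0, 8.0])


class TestPhaseShiftMagnitude:
    def _onsets(self, days, intercept, slope):
        return OnsetSeries(days, intercept + slope * days)

    def test_identical_lines_give_zero(self):
        pre = self._onsets(np.arange(1, 6), 18.0, -0.3)
        post = self._onsets(np.arange(6, 12), 18.0, -0.3)
        assert phase_shift_magnitude(pre, post, period_h=23.7) == pytest.approx(0.0, abs=1e-9)

    def test_eight_hour_displacement(self):
        pre = self._onsets(np.arange(1, 6), 18.0, -0.3)
        post = self._onsets(np.arange(6, 12), 10.0, -0.3)
        assert phase_shift_magnitude(pre, post, period_h=23.7) == pytest.approx(8.0, abs=1e-9)

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        pre = OnsetSeries(np.arange(1, 7), 18.0 - 0.3 * np.arange(1, 7) + rng.normal(0, 0.1, 6))
        post = OnsetSeries(np.arange(7, 13), 11.0 - 0.3 * np.arange(7, 13) + rng.normal(0, 0.1, 6))
        fwd = phase_shift_magnitude(pre, post, period_h=23.7)
        rev = phase_shift_magnitude(post, pre, period_h=23.7)
        assert fwd == pytest.approx(-rev, abs=1e-9)

    def test_insufficient_onsets_error(self):
        pre = self._onsets(np.arange(1, 3), 18.0, 0.0)
        post = self._onsets(np.arange(3, 9), 10.0, 0.0)
        with pytest.raises(ValueError):
            phase_shift_magnitude(pre, post, period_h=24.0)
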