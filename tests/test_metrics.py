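"""Cosinor fitting and non-parametric window metrics."""

from datetime import datetime

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circalipid import (DegenerateInputError, EpochSeries,
                        InsufficientDataError, ValidationError,
                        circular_mean_clock, composite_day, fit_cosinor,
                        fit_cosinor_times, nonparametric_metrics,
                        normalized_amplitude)
from conftest import MIDNIGHT, brute_force_window


class TestCosinor:
    def test_recovers_pure_cosine_exactly(self, make_cosine_series):
        est = fit_cosinor(make_cosine_series(10.0, 5.0, 14.0))
        assert abs(est.mesor - 10.0) < 1e-9
        assert abs(est.amplitude - 5.0) < 1e-9
        assert abs(est.acrophase_h - 14.0) * 3600 < 1.0   # < 1 s
        assert est.rss < 1e-12
        assert est.p_zero_amp < 1e-10

    def test_constant_series_has_undefined_acrophase(self):
        s = EpochSeries(MIDNIGHT, np.full(7 * 1440, 3.0))
        est = fit_cosinor(s)
        assert est.mesor == pytest.approx(3.0)
        assert est.amplitude == pytest.approx(0.0, abs=1e-9)
        assert not est.acrophase_defined
        assert est.p_zero_amp == pytest.approx(1.0)
        assert est.f_zero_amp == 0.0

    def test_matches_grid_search_oracle_on_noisy_series(self, make_cosine_series):
        """Exhaustive 1-second acrophase grid with closed-form (M, A) per
        grid point must agree with the linear least-squares fit."""
        series = make_cosine_series(8.0, 3.0, 5.25, noise_sd=1.0, seed=7)
        t = series.clock_hours()
        y = series.values
        omega = 2 * np.pi / 24.0
        # coarse-to-fine grid search, 1 s final resolution
        best = (np.inf, None)
        centers, span = np.arange(0, 24, 0.1), 0.05
        for _ in range(3):
            for phi in centers:
                c = np.cos(omega * (t - phi))
                X = np.column_stack([np.ones_like(t), c])
                coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
                sse = float(res[0]) if res.size else float(
                    np.sum((y - X @ coef) ** 2))
                if coef[1] >= 0 and sse < best[0]:
                    best = (sse, phi, coef[0], coef[1])
            centers = np.arange(best[1] - span, best[1] + span, span / 40)
            span /= 40
        est = fit_cosinor(series)
        assert abs(est.acrophase_h - best[1]) < 1.0 / 3600
        assert est.mesor == pytest.approx(best[2], abs=1e-6)
        assert est.amplitude == pytest.approx(best[3], abs=1e-6)

    @settings(deadline=None, max_examples=20)
    @given(shift=st.floats(-30, 30), scale=st.floats(0.1, 50))
    def test_shift_and_scale_equivariance(self, shift, scale):
        rng = np.random.default_rng(11)
        t = np.sort(rng.uniform(0, 72, 300))
        y = 6 + 2.5 * np.cos(2 * np.pi * (t - 15) / 24) + rng.normal(0, 0.5, 300)
        base = fit_cosinor_times(t, y)
        moved = fit_cosinor_times(t + shift, y * scale)
        assert moved.mesor == pytest.approx(scale * base.mesor, rel=1e-8)
        assert moved.amplitude == pytest.approx(scale * base.amplitude, rel=1e-8)
        d = (moved.acrophase_h - base.acrophase_h - shift) % 24.0
        assert min(d, 24 - d) < 1e-6

    def test_unbiased_on_its_own_model(self):
        """At n = 10,080 the parameter estimates carry no systematic bias."""
        rng = np.random.default_rng(3)
        t = np.arange(10080) / 60.0
        est_m, est_a, est_p = [], [], []
        for _ in range(40):
            y = 10 + 5 * np.cos(2 * np.pi * (t - 14) / 24) + rng.normal(0, 3, t.size)
            e = fit_cosinor_times(t, y)
            est_m.append(e.mesor)
            est_a.append(e.amplitude)
            est_p.append(e.acrophase_h)
        # MC SE: mesor/amp ~ 3*sqrt(2/10080)/sqrt(40) ~ 0.007
        assert np.mean(est_m) == pytest.approx(10.0, abs=0.03)
        assert np.mean(est_a) == pytest.approx(5.0, abs=0.03)
        assert np.mean(est_p) == pytest.approx(14.0, abs=0.03)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateInputError):
            fit_cosinor_times(np.arange(5.0), np.full(5, np.nan))
        with pytest.raises(InsufficientDataError):
            fit_cosinor_times(np.array([1.0, 1.0, 2.0]), np.array([1, 2, 3.0]))
        with pytest.raises(DegenerateInputError):  # span <= half period
            fit_cosinor_times(np.linspace(0, 11, 30), np.random.rand(30))


class TestNonparametric:
    def test_constant_series(self):
        s = EpochSeries(MIDNIGHT, np.full(7 * 1440, 4.0))
        m = nonparametric_metrics(s, fit_cosinor(s))
        assert m.m10 == m.l5 == pytest.approx(4.0)
        assert m.ra == 0.0
        assert m.m10_onset_h == 0.0 and m.l5_onset_h == 0.0  # earliest tie

    def test_square_wave_hand_enumeration(self, square_wave_series):
        m = nonparametric_metrics(square_wave_series,
                                  fit_cosinor(square_wave_series))
        assert m.m10 == pytest.approx(100.0)
        assert m.m10_onset_h == pytest.approx(8.0)
        assert m.l5 == pytest.approx(0.0)
        assert m.l5_onset_h == pytest.approx(0.0)
        assert m.ra == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_windows_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        day = rng.lognormal(1.0, 1.5, 1440)
        series = EpochSeries(MIDNIGHT, np.tile(day, 7)
                             * rng.lognormal(0, 0.3, 7 * 1440))
        comp = composite_day(series)
        m = nonparametric_metrics(series, fit_cosinor(series))
        m10_o, s10 = brute_force_window(comp, 600, "max")
        l5_o, s5 = brute_force_window(comp, 300, "min")
        assert m.m10 == pytest.approx(m10_o, rel=1e-12)
        assert m.m10_onset_h == pytest.approx(s10 / 60.0)
        assert m.l5 == pytest.approx(l5_o, rel=1e-12)
        assert m.l5_onset_h == pytest.approx(s5 / 60.0)
        assert 0.0 <= m.ra <= 1.0

    def test_missing_day_policy(self):
        vals = np.tile(np.sin(np.linspace(0, 2 * np.pi, 1440)) + 2, 5)
        vals[1440:1440 + 400] = np.nan      # day 1: 28% missing -> dropped
        series = EpochSeries(MIDNIGHT, vals)
        comp = composite_day(series)        # 4 valid days remain
        assert np.isfinite(comp).all()
        with pytest.raises(InsufficientDataError):
            composite_day(EpochSeries(MIDNIGHT, np.where(
                np.arange(3 * 1440) % 1440 < 400, np.nan,
                np.tile(vals[:1440], 3))), min_days=3)

    def test_na_definition_and_scale_invariance(self, make_cosine_series):
        s = make_cosine_series(10.0, 5.0, 14.0)
        est = fit_cosinor(s)
        assert normalized_amplitude(est) == pytest.approx(0.5, abs=1e-12)
        scaled = EpochSeries(s.start_time, s.values * 7.3)
        assert normalized_amplitude(fit_cosinor(scaled)) == pytest.approx(
            0.5, abs=1e-9)
        est0 = fit_cosinor(make_cosine_series(3.0, 0.0, 0.0))
        assert normalized_amplitude(est0) == pytest.approx(0.0, abs=1e-9)
        est.mesor = 0.0
        with pytest.raises(DegenerateInputError):
            normalized_amplitude(est)


class TestCircularMean:
    @pytest.mark.parametrize("times,expected", [
        ([23.5, 0.5], 0.0),
        ([6, 6, 6], 6.0),
        ([11.0, 13.0], 12.0),
    ])
    def test_known_means(self, times, expected):
        res = circular_mean_clock(times)
        assert res.mean_h == pytest.approx(expected, abs=1e-9)

    def test_symmetric_input_is_undefined(self):
        res = circular_mean_clock([0.0, 8.0, 16.0])
        assert np.isnan(res.mean_h)
        assert res.resultant < 1e-9

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            circular_mean_clock([])
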