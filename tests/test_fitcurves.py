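"""Sinusoid pre-fit, sawtooth model, per-sarcomere fitting and selection."""

import numpy as np
import pytest

import sarctrack.fitcurves as fc
from sarctrack.fitcurves import (
    SinusoidFit,
    fit_sawtooth,
    fit_sinusoid,
    filter_by_rmse,
    sawtooth_model,
    summarize_sarcomere,
)
from sarctrack.trace import SarcomereTrace

FPS = 30.0
SINE_45 = SinusoidFit(frequency=FPS / 45.0, amplitude=1.0, phase=0.0, fps=FPS)


def _trace(values, gid=0):
    values = np.asarray(values, dtype=float)
    return SarcomereTrace(gid, values, np.ones_like(values), FPS)


class TestSinusoid:
    def test_pure_one_hertz_recovered(self):
        t = np.arange(150)
        y = 19.0 + 0.8 * np.sin(2 * np.pi * 1.0 * t / FPS)
        fit = fit_sinusoid(y, fps=FPS)
        assert fit.frequency == pytest.approx(1.0, abs=0.005)
        assert fit.bpm == pytest.approx(60.0, abs=0.3)
        assert fit.amplitude == pytest.approx(0.8, rel=0.02)

    def test_sawtooth_period_45_recovered(self):
        # 45-frame beat at 30 fps -> 0.667 Hz, within 5%
        t = np.arange(150)
        y = 18 + 2 * sawtooth_model(t, FPS / 45.0, 10, 10, 3.0, FPS)
        fit = fit_sinusoid(y, fps=FPS)
        assert fit.frequency == pytest.approx(2.0 / 3.0, rel=0.05)

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_sinusoid(np.full(150, 19.0), fps=FPS)


class TestSawtoothModel:
    def test_plateau_is_exactly_one(self):
        # u in [0, L): relaxed plateau
        v = sawtooth_model(np.array([0.0, 5.0, 24.9]), FPS / 45.0, 10, 10, 0, FPS)
        np.testing.assert_array_equal(v, 1.0)

    def test_valley_floor_is_exactly_zero(self):
        # plateau L = 45 - 20 = 25; floor at u = L + c = 35
        v = sawtooth_model(35.0, FPS / 45.0, 10, 10, 0, FPS)
        assert float(v) == pytest.approx(0.0, abs=1e-12)

    def test_periodic_continuous_bounded(self):
        t = np.linspace(0, 135, 2000)
        v = sawtooth_model(t, FPS / 45.0, 10, 20, 7.3, FPS)
        v_shift = sawtooth_model(t + 45.0, FPS / 45.0, 10, 20, 7.3, FPS)
        np.testing.assert_allclose(v, v_shift, atol=1e-9)
        assert np.all((v >= 0) & (v <= 1))
        # continuity: no jump larger than the local slope allows
        assert np.max(np.abs(np.diff(v))) < 0.02

    def test_relaxation_twice_contraction_timing(self):
        # time from valley floor back to plateau is twice plateau-to-floor
        c, r = 8.0, 16.0
        T, L = 45.0, 45.0 - c - r
        v_floor = sawtooth_model(L + c, FPS / T, c, r, 0, FPS)
        assert float(v_floor) == pytest.approx(0.0, abs=1e-12)
        assert (L + c) - L == c
        v_end = sawtooth_model(L + c + r - 1e-9, FPS / T, c, r, 0, FPS)
        assert float(v_end) == pytest.approx(1.0, abs=1e-6)

    def test_infeasible_durations_rejected(self):
        with pytest.raises(ValueError):
            sawtooth_model(0.0, FPS / 45.0, 30, 30, 0, FPS)
        with pytest.raises(ValueError):
            sawtooth_model(0.0, FPS / 45.0, -1, 10, 0, FPS)


class TestFitSawtooth:
    def test_exact_recovery_and_affine_invariance(self):
        t = np.arange(150)
        m = sawtooth_model(t, SINE_45.frequency, 10, 20, 7, FPS)
        for scale, off in [(2.0, 3.0), (0.5, 100.0), (7.7, -4.0)]:
            fit = fit_sawtooth(off + scale * m, SINE_45)
            assert fit.t_contract == pytest.approx(10.0, abs=0.1)
            assert fit.t_relax == pytest.approx(20.0, abs=0.1)
            assert fit.phase_offset == pytest.approx(7.0, abs=0.1)
            assert fit.correlation == pytest.approx(1.0, abs=1e-6)

    def test_relaxation_twice_contraction_ratio(self):
        t = np.arange(150)
        y = 18 + 2 * sawtooth_model(t, SINE_45.frequency, 9, 18, 21.0, FPS)
        fit = fit_sawtooth(y, SINE_45)
        assert fit.t_relax / fit.t_contract == pytest.approx(2.0, rel=0.15)

    def test_white_noise_has_low_correlation(self):
        rng = np.random.default_rng(123)
        corrs = []
        for _ in range(100):
            fit = fit_sawtooth(rng.normal(size=150), SINE_45)
            corrs.append(fit.correlation)
        # an optimized fit to noise still reaches moderate correlation,
        # but nowhere near a genuine periodic trace
        assert np.median(corrs) < 0.6

    def test_init_guides_search(self):
        t = np.arange(150)
        y = 18 + 2 * sawtooth_model(t, SINE_45.frequency, 12, 14, 3.0, FPS)
        init = fit_sawtooth(y, SINE_45)
        again = fit_sawtooth(y, SINE_45, init=init)
        assert again.t_contract == pytest.approx(12.0, abs=0.2)
        assert again.t_relax == pytest.approx(14.0, abs=0.2)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        y = 18 + 2 * sawtooth_model(
            np.arange(150), SINE_45.frequency, 10, 15, 9.0, FPS
        ) + rng.normal(0, 0.2, 150)
        a = fit_sawtooth(y, SINE_45)
        b = fit_sawtooth(y, SINE_45)
        assert (a.t_contract, a.t_relax, a.phase_offset) == (
            b.t_contract,
            b.t_relax,
            b.phase_offset,
        )


def _make_fit(rmse, corr, at_bounds=False):
    return fc.SawtoothFit(
        t_contract=10,
        t_relax=10,
        phase_offset=0,
        frequency=SINE_45.frequency,
        fps=FPS,
        correlation=corr,
        rmse=rmse,
        at_bounds=at_bounds,
    )


class TestRmseFilter:
    def test_permissive_settings_retain_all(self):
        fits = [_make_fit(r, 0.0) for r in [0.1, 5.0, 2.0]]
        assert filter_by_rmse(fits, rmse_quantile=1.0, min_correlation=-1.0) == [
            0,
            1,
            2,
        ]

    def test_clean_vs_noise_mixture(self):
        t = np.arange(150)
        clean = 18 + 2 * sawtooth_model(t, SINE_45.frequency, 10, 15, 2, FPS)
        rng = np.random.default_rng(9)
        fits, order = [], []
        for i in range(10):
            fits.append(fit_sawtooth(clean, SINE_45))
            order.append("clean")
        for i in range(10):
            fits.append(fit_sawtooth(19 + rng.normal(0, 1, 150), SINE_45))
            order.append("noise")
        kept = filter_by_rmse(fits, rmse_quantile=0.75, min_correlation=0.5)
        assert set(kept) == set(range(10))

    def test_duplicates_share_fate(self):
        fits = [_make_fit(1.0, 0.9), _make_fit(1.0, 0.9), _make_fit(9.0, 0.9)]
        kept = filter_by_rmse(fits, rmse_quantile=0.5, min_correlation=0.5)
        assert (0 in kept) == (1 in kept)

    def test_bound_pinned_fits_excluded(self):
        fits = [_make_fit(0.1, 0.99), _make_fit(0.1, 0.99, at_bounds=True)]
        assert filter_by_rmse(fits, 1.0, -1.0) == [0]

    def test_empty_input_allowed(self):
        assert filter_by_rmse([], 0.75, 0.5) == []


class TestSummarize:
    def test_shortening_and_calibration(self):
        # square wave between 18 and 20 px, period 45 frames
        t = np.arange(150)
        y = np.where((t % 45) < 30, 20.0, 18.0)
        fit = _make_fit(0.1, 0.99)
        st = summarize_sarcomere(_trace(y), fit, microns_per_pixel=0.1, fps=FPS)
        assert st.d_max == pytest.approx(20.0)
        assert st.d_min == pytest.approx(18.0)
        assert st.shortening_pct == pytest.approx(10.0)
        assert st.sl_max_um == pytest.approx(2.0)
        assert st.sl_min_um == pytest.approx(1.8)
        assert st.t_contract_s == pytest.approx(10 / 30)
        assert st.t_relax_s == pytest.approx(10 / 30)


class TestNoiseRecovery:
    def test_duration_recovery_under_noise(self):
        # additive noise at 10% of the 2 px oscillation amplitude
        rng = np.random.default_rng(2024)
        t = np.arange(150)
        errs_c, errs_r = [], []
        for _ in range(30):
            delta = rng.uniform(0, 45)
            y = (
                18.0
                + 2.0 * sawtooth_model(t, SINE_45.frequency, 10, 20, delta, FPS)
                + rng.normal(0, 0.2, 150)
            )
            fit = fit_sawtooth(y, SINE_45)
            errs_c.append(abs(fit.t_contract - 10))
            errs_r.append(abs(fit.t_relax - 20))
        assert np.median(errs_c) <= 2.0
        assert np.median(errs_r) <= 2.0
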