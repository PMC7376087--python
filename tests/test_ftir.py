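"""FTIR analysis: peak picking, melting curves, Tm, beta, band fits."""

import numpy as np
import pytest

from flickerspec import (
    MeltGenParams,
    MeltingCurve,
    Spectrum1D,
    build_melting_curve,
    compute_beta,
    estimate_tm,
    fit_two_gaussians,
    generate_co_band,
    generate_melting_curve,
    generate_melting_spectra,
    integrate_band,
    pick_peak,
)
from flickerspec.ftir import EdgePeakError, NoTransitionError


def gaussian_spectrum(center, sigma=4.0, amp=1.0, grid=(2800, 2900, 1.0), t=None):
    wn = np.arange(grid[0], grid[1] + grid[2] / 2, grid[2])
    return Spectrum1D(wavenumber=wn,
                      absorbance=amp * np.exp(-0.5 * ((wn - center) / sigma) ** 2),
                      temperature=t)


class TestPickPeak:
    def test_grid_quantization(self):
        # standard-mode picking returns the grid point, not an interpolation
        assert pick_peak(gaussian_spectrum(2850.4), (2840, 2860)) == 2850.0

    def test_highest_of_two_maxima(self):
        wn = np.arange(2840.0, 2861.0)
        y = (1.0 * np.exp(-0.5 * ((wn - 2852) / 2) ** 2)
             + 0.6 * np.exp(-0.5 * ((wn - 2846) / 2) ** 2))
        assert pick_peak(Spectrum1D(wavenumber=wn, absorbance=y), (2840, 2860)) == 2852.0

    def test_edge_peak_rejected(self):
        wn = np.arange(2840.0, 2861.0)
        y = wn - 2840.0  # monotone: maximum on the window edge
        with pytest.raises(EdgePeakError):
            pick_peak(Spectrum1D(wavenumber=wn, absorbance=y), (2840, 2860))

    def test_descending_grid_normalized(self):
        sp = gaussian_spectrum(2850.0)
        rev = Spectrum1D(wavenumber=sp.wavenumber[::-1],
                         absorbance=sp.absorbance[::-1])
        assert pick_peak(rev, (2840, 2860)) == 2850.0

    def test_noisy_position_within_one_grid_step(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            sp = gaussian_spectrum(2851.0)
            noisy = Spectrum1D(wavenumber=sp.wavenumber,
                               absorbance=sp.absorbance
                               + rng.normal(0, 0.005, sp.absorbance.shape))
            if abs(pick_peak(noisy, (2840, 2860)) - 2851.0) <= 1.0:
                hits += 1
        assert hits >= 95


class TestMeltingCurve:
    def test_build_from_synthetic_spectra(self):
        p = MeltGenParams(tm=27.0, width=3.0, noise_sd=0.0)
        series = generate_melting_spectra(p)
        curve = build_melting_curve(series, (2840, 2860))
        ref = generate_melting_curve(p)
        assert curve.temperature.size == ref.temperature.size
        # positions quantized to the 0.1 cm^-1 grid of the synthetic band
        assert np.max(np.abs(curve.peak_position - ref.peak_position)) <= 0.05 + 1e-9

    def test_monotone_through_transition(self):
        p = MeltGenParams(tm=27.0, width=3.0, noise_sd=0.0)
        curve = build_melting_curve(generate_melting_spectra(p), (2840, 2860))
        assert np.all(np.diff(curve.peak_position) >= 0)

    def test_failed_pick_dropped(self):
        p = MeltGenParams(tm=27.0, width=3.0, noise_sd=0.0)
        series = generate_melting_spectra(p)
        bad = series[10]
        series[10] = Spectrum1D(wavenumber=bad.wavenumber,
                                absorbance=np.linspace(0, 1, bad.wavenumber.size),
                                temperature=bad.temperature)
        curve = build_melting_curve(series, (2840, 2860))
        assert bad.temperature not in curve.temperature

    def test_too_few_temperatures_rejected(self):
        p = MeltGenParams(tm=27.0, t_range=(20.0, 23.0, 1.0), noise_sd=0.0)
        with pytest.raises(ValueError):
            build_melting_curve(generate_melting_spectra(p), (2840, 2860))


class TestEstimateTm:
    @pytest.mark.parametrize("tm,width,tol", [(27.0, 3.0, 0.2), (33.0, 5.0, 0.3)])
    def test_noiseless_logistic_midpoint(self, tm, width, tol):
        curve = generate_melting_curve(MeltGenParams(tm=tm, width=width, noise_sd=0.0))
        assert estimate_tm(curve) == pytest.approx(tm, abs=tol)

    def test_midpoint_recovery_anywhere_interior(self):
        for tm in (20.0, 30.0, 40.0, 50.0):
            curve = generate_melting_curve(MeltGenParams(tm=tm, width=3.0, noise_sd=0.0))
            assert estimate_tm(curve) == pytest.approx(tm, abs=0.2)

    def test_noisy_recovery_within_one_degree(self):
        errs = []
        for seed in range(100):
            curve = generate_melting_curve(
                MeltGenParams(tm=27.0, width=3.0, noise_sd=0.05, seed=seed))
            errs.append(abs(estimate_tm(curve) - 27.0))
        assert np.mean(np.array(errs) <= 1.0) >= 0.95

    def test_linear_curve_has_no_transition(self):
        t = np.arange(5.0, 70.0)
        curve = MeltingCurve(temperature=t, peak_position=2850 + 0.01 * t)
        with pytest.raises(NoTransitionError):
            estimate_tm(curve)

    def test_flat_generator_raises(self):
        curve = generate_melting_curve(MeltGenParams(delta_nu=0.0, noise_sd=0.0))
        with pytest.raises(NoTransitionError):
            estimate_tm(curve)


class TestComputeBeta:
    def test_constant_curve_zero_beta(self):
        t = np.arange(5.0, 46.0)
        curve = MeltingCurve(temperature=t, peak_position=np.full(t.size, 2850.0))
        assert all(b == pytest.approx(0.0, abs=1e-15) for _, b in compute_beta(curve))

    def test_linear_trend_analytic_value(self):
        t = np.arange(5.0, 46.0)
        curve = MeltingCurve(temperature=t, peak_position=2850.0 + 0.1 * t)
        beta = dict(compute_beta(curve))
        assert beta[25.0] == pytest.approx(0.1 / 2852.5, rel=1e-6)

    def test_exponential_trend_constant_rate(self):
        c = 1e-4
        t = np.arange(5.0, 46.0)
        curve = MeltingCurve(temperature=t, peak_position=2850.0 * np.exp(c * t))
        vals = [b for _, b in compute_beta(curve)]
        np.testing.assert_allclose(vals, c, rtol=0.01)

    def test_logistic_peaks_at_midpoint(self):
        curve = generate_melting_curve(MeltGenParams(tm=30.0, width=3.0, noise_sd=0.0))
        pts = compute_beta(curve)
        t_at_max = max(pts, key=lambda p: p[1])[0]
        assert t_at_max == pytest.approx(30.0, abs=1.0)


class TestIntegrateBand:
    def test_gaussian_analytic_area(self):
        sp = generate_co_band((0.0, 0.0), grid=(1950, 2000, 0.5))
        wn = sp.wavenumber
        y = np.exp(-0.5 * ((wn - 1975) / 3.0) ** 2)
        area = integrate_band(Spectrum1D(wavenumber=wn, absorbance=y), (1960, 1990))
        assert area == pytest.approx(3.0 * np.sqrt(2 * np.pi), rel=1e-3)

    def test_constant_offset_removed(self):
        wn = np.arange(1950.0, 2000.5, 0.5)
        y = np.exp(-0.5 * ((wn - 1975) / 3.0) ** 2)
        a0 = integrate_band(Spectrum1D(wavenumber=wn, absorbance=y), (1960, 1990))
        a1 = integrate_band(Spectrum1D(wavenumber=wn, absorbance=y + 0.2), (1960, 1990))
        assert a1 == pytest.approx(a0, rel=1e-9)

    def test_normalization(self):
        sp = generate_co_band((2.0, 1.0))
        assert integrate_band(sp, norm_ref=4.0) == pytest.approx(0.75, rel=1e-2)

    def test_additive_over_subranges(self):
        sp = generate_co_band((2.0, 1.0))
        # split at an interior grid point; baseline anchored per sub-range
        whole = np.trapezoid(
            sp.absorbance[(sp.wavenumber >= 1960) & (sp.wavenumber <= 1990)],
            sp.wavenumber[(sp.wavenumber >= 1960) & (sp.wavenumber <= 1990)])
        left = np.trapezoid(
            sp.absorbance[(sp.wavenumber >= 1960) & (sp.wavenumber <= 1975)],
            sp.wavenumber[(sp.wavenumber >= 1960) & (sp.wavenumber <= 1975)])
        right = np.trapezoid(
            sp.absorbance[(sp.wavenumber >= 1975) & (sp.wavenumber <= 1990)],
            sp.wavenumber[(sp.wavenumber >= 1975) & (sp.wavenumber <= 1990)])
        assert left + right == pytest.approx(whole, rel=1e-12)


class TestTwoGaussianFit:
    def test_known_mixture(self):
        sp = generate_co_band((3.0, 1.0))
        dec = fit_two_gaussians(sp)
        assert dec.f1 == pytest.approx(0.75, abs=0.01)
        assert dec.widths[0] <= dec.widths[1]

    def test_single_component_limit(self):
        dec = fit_two_gaussians(generate_co_band((3.0, 0.0)))
        assert dec.f1 == pytest.approx(1.0, abs=0.02)

    def test_zero_core_component(self):
        dec = fit_two_gaussians(generate_co_band((0.0, 1.0)))
        assert dec.f1 == pytest.approx(0.0, abs=0.02)

    def test_scale_invariance_of_f1(self):
        sp = generate_co_band((3.0, 1.0))
        scaled = Spectrum1D(wavenumber=sp.wavenumber, absorbance=7.3 * sp.absorbance)
        assert fit_two_gaussians(scaled).f1 == pytest.approx(
            fit_two_gaussians(sp).f1, abs=1e-6)

    def test_noisy_f1_recovery(self):
        amp_core = (3.0 / (1.5 * np.sqrt(2 * np.pi)))
        hits = 0
        for seed in range(100):
            sp = generate_co_band((3.0, 1.0), noise_sd=0.01 * amp_core, seed=seed)
            if abs(fit_two_gaussians(sp).f1 - 0.75) <= 0.02:
                hits += 1
        assert hits >= 95
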