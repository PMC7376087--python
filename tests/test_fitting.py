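"""Membrane parameter fits: identifiability, nestedness, weighting."""

import numpy as np
import pytest

from flickerspec import (
    FluctuationSpectrum,
    SpectrumModelParams,
    estimate_spectrum,
    eval_confined_spectrum,
    eval_free_spectrum,
    eval_tension_spectrum,
    fit_bending_free,
    fit_confined_model,
    fit_tension_model,
    normalize_series,
    sample_contour_modes,
)
from flickerspec.fitting import InsufficientDataError


def analytic_spectrum(params, model_fn, n_lo=2, n_hi=18, rel_se=0.02, frames=2000):
    n = np.arange(n_lo, n_hi + 1)
    d2 = np.asarray(model_fn(params, n), dtype=float)
    return FluctuationSpectrum(n=n, delta2=d2, se=rel_se * d2, frames=frames,
                               mean_radius=params.mean_radius)


class TestBendingFreeFit:
    def test_noiseless_exact_recovery(self):
        p = SpectrumModelParams(kappa_tilde=44)
        spec = analytic_spectrum(p, lambda q, n: eval_free_spectrum(q.kappa_tilde, n))
        res = fit_bending_free(spec)
        assert res.params.kappa_tilde == pytest.approx(44.0, rel=1e-10)
        assert res.n_range == (5, 18)

    @pytest.mark.parametrize("kappa", [44.0, 170.0])
    def test_sampled_vesicles_recover_kappa(self, kappa):
        """Mean over 4 synthetic vesicles of 2000 frames each, ~5%."""
        p = SpectrumModelParams(kappa_tilde=kappa, sigma_tilde=0.01, mean_radius=50)
        fits = []
        for v in range(4):
            modes = sample_contour_modes(p, "tension", 18, 2000, seed=1000 + v)
            fits.append(fit_bending_free(estimate_spectrum(modes)).params.kappa_tilde)
        assert np.mean(fits) == pytest.approx(kappa, rel=0.05)

    def test_weight_rescaling_leaves_estimate_unchanged(self):
        p = SpectrumModelParams(kappa_tilde=60, sigma_tilde=0.01, mean_radius=50)
        modes = sample_contour_modes(p, "tension", 18, 500, seed=4)
        spec = estimate_spectrum(modes)
        doubled = FluctuationSpectrum(n=spec.n, delta2=spec.delta2,
                                      se=2 * spec.se, frames=spec.frames,
                                      mean_radius=spec.mean_radius)
        r1, r2 = fit_bending_free(spec), fit_bending_free(doubled)
        assert r1.params.kappa_tilde == pytest.approx(r2.params.kappa_tilde, rel=1e-12)
        assert r2.se["kappa_tilde"] == pytest.approx(2 * r1.se["kappa_tilde"], rel=1e-10)

    def test_se_shrinks_with_frames(self):
        p = SpectrumModelParams(kappa_tilde=44, sigma_tilde=0.01, mean_radius=50)
        s1 = estimate_spectrum(sample_contour_modes(p, "tension", 18, 1000, seed=5))
        s2 = estimate_spectrum(sample_contour_modes(p, "tension", 18, 4000, seed=6))
        se1 = fit_bending_free(s1).se["kappa_tilde"]
        se2 = fit_bending_free(s2).se["kappa_tilde"]
        assert se2 == pytest.approx(se1 / 2, rel=0.35)

    def test_too_few_modes_rejected(self):
        p = SpectrumModelParams(kappa_tilde=44)
        spec = analytic_spectrum(p, lambda q, n: eval_free_spectrum(q.kappa_tilde, n),
                                 n_lo=5, n_hi=7)
        with pytest.raises(InsufficientDataError):
            fit_bending_free(spec)


class TestTensionFit:
    def test_noiseless_recovery(self):
        p = SpectrumModelParams(kappa_tilde=30, sigma_tilde=50)
        spec = analytic_spectrum(p, eval_tension_spectrum)
        res = fit_tension_model(spec)
        assert res.params.kappa_tilde == pytest.approx(30.0, rel=1e-6)
        assert res.params.sigma_tilde == pytest.approx(50.0, rel=1e-6)

    def test_sampled_recovery_over_seeds(self):
        """Identifiable-tension regime: both parameters within 15%."""
        p = SpectrumModelParams(kappa_tilde=30, sigma_tilde=50, mean_radius=50)
        ks, ss = [], []
        for seed in range(20):
            spec = estimate_spectrum(sample_contour_modes(p, "tension", 18, 2000,
                                                          seed=3000 + seed))
            res = fit_tension_model(spec)
            ks.append(res.params.kappa_tilde)
            ss.append(res.params.sigma_tilde)
        assert np.mean(ks) == pytest.approx(30.0, rel=0.15)
        assert np.mean(ss) == pytest.approx(50.0, rel=0.15)

    def test_tension_unidentifiable_at_high_modes_only(self):
        """Fitting only n >= 5 of a low-tension spectrum: kappa fine,
        sigma returned with se exceeding the estimate."""
        p = SpectrumModelParams(kappa_tilde=44, sigma_tilde=0.01, mean_radius=50)
        spec = estimate_spectrum(sample_contour_modes(p, "tension", 18, 2000, seed=9))
        res = fit_tension_model(spec, n_min=5, n_max=18)
        assert res.params.kappa_tilde == pytest.approx(44.0, rel=0.05)
        assert not np.isfinite(res.se["sigma_tilde"]) or \
            res.se["sigma_tilde"] > res.params.sigma_tilde


class TestConfinedFit:
    def test_noiseless_recovery(self):
        p = SpectrumModelParams(kappa_tilde=50, sigma_tilde=40, gamma_tilde=900)
        spec = analytic_spectrum(p, eval_confined_spectrum, n_lo=3)
        res = fit_confined_model(spec)
        assert res.params.kappa_tilde == pytest.approx(50.0, rel=1e-4)
        assert res.params.sigma_tilde == pytest.approx(40.0, rel=1e-4)
        assert res.params.gamma_tilde == pytest.approx(900.0, rel=1e-4)

    def test_nested_in_tension_model_at_zero_gamma(self):
        p = SpectrumModelParams(kappa_tilde=30, sigma_tilde=50, mean_radius=50)
        spec = estimate_spectrum(sample_contour_modes(p, "tension", 18, 2000, seed=13))
        r_conf = fit_confined_model(spec, n_min=3)
        r_tens = fit_tension_model(spec, n_min=3)
        assert r_conf.params.kappa_tilde == pytest.approx(
            r_tens.params.kappa_tilde, rel=0.02)
        # gamma statistically consistent with zero
        g, g_se = r_conf.params.gamma_tilde, r_conf.se["gamma_tilde"]
        assert g <= 2 * g_se or not np.isfinite(g_se) or g < 1e-3

    def test_rbc_like_sampled_recovery(self):
        """Confined-spectrum sampling at RBC-like parameters, 20 seeds."""
        p = SpectrumModelParams(kappa_tilde=50, sigma_tilde=40, gamma_tilde=900,
                                mean_radius=30)
        ks = []
        for seed in range(20):
            spec = estimate_spectrum(sample_contour_modes(p, "confined", 18, 2000,
                                                          seed=5000 + seed))
            ks.append(fit_confined_model(spec).params.kappa_tilde)
        assert np.mean(ks) == pytest.approx(50.0, rel=0.20)

    def test_fixed_gamma_matches_tension_model(self):
        p = SpectrumModelParams(kappa_tilde=30, sigma_tilde=50)
        spec = analytic_spectrum(p, eval_tension_spectrum, n_lo=3)
        r_fix = fit_confined_model(spec, fix_gamma=0.0)
        r_tens = fit_tension_model(spec, n_min=3)
        assert r_fix.params.kappa_tilde == pytest.approx(
            r_tens.params.kappa_tilde, rel=1e-5)


class TestNormalizeSeries:
    def test_baseline_maps_to_one(self):
        series = [(0.0, 40.0), (10.0, 40.0), (20.0, 40.0)]
        assert all(v == pytest.approx(1.0) for _, v in normalize_series(series, 40.0))

    def test_ratio_definition(self):
        out = normalize_series([(10.0, 1.37 * 40.0)], 40.0)
        assert out[0][1] == pytest.approx(1.37, rel=1e-12)

    def test_mean_ratio_across_cells(self):
        """Cells sharing a true ratio: the mean normalized value is
        within one standard error of that ratio."""
        rng = np.random.default_rng(17)
        true_ratio, n_cells = 1.37, 7
        ratios = []
        for _ in range(n_cells):
            k0 = rng.uniform(30, 60)
            k_obs = true_ratio * k0 * (1 + rng.normal(0, 0.03))
            ratios.append(normalize_series([(10.0, k_obs)], k0)[0][1])
        se = np.std(ratios, ddof=1) / np.sqrt(n_cells)
        assert abs(np.mean(ratios) - true_ratio) < max(se, 1e-6) * 2.5

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            normalize_series([(0.0, 1.0)], 0.0)
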