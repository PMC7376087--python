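"""Membrane parameter estimation from fluctuation spectra.

Three nested fits of the planar-membrane spectra to a measured
``⟨δ_n²⟩`` vs ``n`` curve:

``fit_bending_free``
    bending-only n⁻³ law over modes 5–18; linear in 1/κ̃, solved in
    closed form by weighted least squares.

``fit_tension_model``
    two-parameter (κ̃, σ̃) nonlinear fit of the tension spectrum.

``fit_confined_model``
    three-parameter (κ̃, σ̃, γ̃) fit of the confined spectrum used for
    red blood cells, where the spectrin skeleton suppresses long
    wavelengths; the confinement branch is evaluated with complex
    square roots when the optimiser wanders into σ̃² < γ̃.

Weights are 1/se² with ``se_n = ⟨δ_n²⟩·sqrt(2/N)`` (independent-frame
Gaussian amplitudes), the standard flicker-spectroscopy choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import lmfit
import numpy as np

from .fourier import FluctuationSpectrum
from .models import (
    SpectrumModelParams,
    eval_confined_spectrum,
    eval_tension_spectrum,
)

__all__ = ["FitResult", "InsufficientDataError", "fit_bending_free",
           "fit_tension_model", "fit_confined_model", "normalize_series"]

_TWO_PI = 2.0 * math.pi


class InsufficientDataError(ValueError):
    """Too few usable modes for the requested fit."""


@dataclass
class FitResult:
    """Fitted membrane parameters with uncertainties.

    ``params`` holds the point estimates; ``se`` maps parameter name
    ('kappa_tilde', 'sigma_tilde', 'gamma_tilde') to its standard
    error (NaN when not estimable).  ``model`` is one of 'free',
    'tension', 'confined'.
    """

    params: SpectrumModelParams
    se: dict[str, float]
    n_range: tuple[int, int]
    chi2_reduced: float
    model: str
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "n_range": list(self.n_range),
            "estimates": {
                "kappa_tilde": self.params.kappa_tilde,
                "sigma_tilde": self.params.sigma_tilde,
                "gamma_tilde": self.params.gamma_tilde,
                "mean_radius": self.params.mean_radius,
            },
            "se": self.se,
            "chi2_reduced": self.chi2_reduced,
            "converged": self.converged,
        }


def _usable(spectrum: FluctuationSpectrum, n_min: int, n_max: int, min_modes: int):
    sub = spectrum.restrict(n_min, n_max)
    ok = sub.delta2 > 0
    if ok.sum() < min_modes:
        raise InsufficientDataError(
            f"only {int(ok.sum())} usable modes in n = {n_min}..{n_max}; "
            f"need >= {min_modes}"
        )
    return sub.n[ok], sub.delta2[ok], sub.se[ok]


def _weights(delta2: np.ndarray, se: np.ndarray) -> np.ndarray:
    se = np.where(se > 0, se, np.max(se[se > 0]) if np.any(se > 0) else 1.0)
    return 1.0 / se


def fit_bending_free(
    spectrum: FluctuationSpectrum, n_min: int = 5, n_max: int = 18
) -> FitResult:
    """Fit the bending-only spectrum ``⟨δ_n²⟩ = (1/2πκ̃) n⁻³``.

    The model is linear in C = 1/(2πκ̃), so the weighted least-squares
    solution is closed form: C = Σw y x / Σw x² with x = n⁻³ and
    w = 1/se².  Returns κ̃ with its propagated standard error.
    """
    n, y, se = _usable(spectrum, n_min, n_max, min_modes=4)
    x = n.astype(float) ** -3.0
    w = _weights(y, se) ** 2
    sxx = float(np.sum(w * x * x))
    c_hat = float(np.sum(w * y * x)) / sxx
    if c_hat <= 0:
        raise RuntimeError("non-positive amplitude estimate; spectrum unusable")
    c_se = sxx**-0.5
    kappa = 1.0 / (_TWO_PI * c_hat)
    kappa_se = c_se / (_TWO_PI * c_hat**2)
    resid = (y - c_hat * x) * np.sqrt(w)
    dof = max(n.size - 1, 1)
    params = SpectrumModelParams(
        kappa_tilde=kappa, sigma_tilde=0.0, gamma_tilde=0.0,
        mean_radius=spectrum.mean_radius,
    )
    return FitResult(
        params=params,
        se={"kappa_tilde": kappa_se, "sigma_tilde": float("nan"),
            "gamma_tilde": float("nan")},
        n_range=(int(n.min()), int(n.max())),
        chi2_reduced=float(np.sum(resid**2)) / dof,
        model="free",
    )


def _run_lmfit(pars, model_fn, n, y, se, n_range, mean_radius, model_name, n_free):
    def residual(p):
        return (model_fn(p, n) - y) / se

    result = lmfit.minimize(residual, pars, method="leastsq", nan_policy="raise")
    if not result.success:
        raise RuntimeError(f"{model_name} fit did not converge: {result.message}")
    v = result.params.valuesdict()
    params = SpectrumModelParams(
        kappa_tilde=v["kappa_tilde"],
        sigma_tilde=v["sigma_tilde"],
        gamma_tilde=v.get("gamma_tilde", 0.0),
        mean_radius=mean_radius,
    )
    se_out = {}
    for name in ("kappa_tilde", "sigma_tilde", "gamma_tilde"):
        if name in result.params and result.params[name].stderr is not None:
            se_out[name] = float(result.params[name].stderr)
        else:
            se_out[name] = float("nan")
    return FitResult(
        params=params, se=se_out, n_range=n_range,
        chi2_reduced=float(result.redchi), model=model_name,
        converged=bool(result.success),
    )


def fit_tension_model(
    spectrum: FluctuationSpectrum, n_min: int = 2, n_max: int = 18
) -> FitResult:
    """Weighted nonlinear fit of the tension spectrum over (κ̃, σ̃).

    κ̃ is initialised from the bending-only fit of the upper half of
    the mode range; σ̃ starts at 1.  Bounds: κ̃ ∈ (0, 1e4],
    σ̃ ∈ [1e-6, 1e6].  On a low-tension spectrum fitted only at high
    modes σ̃ is unidentifiable: the estimate is then returned with a
    standard error exceeding it, which callers should treat as "no
    tension information".
    """
    n, y, se = _usable(spectrum, n_min, n_max, min_modes=4)
    try:
        k0 = fit_bending_free(spectrum, max(n_min, 5), n_max).params.kappa_tilde
    except (InsufficientDataError, RuntimeError):
        k0 = 1.0 / (_TWO_PI * float(np.mean(y * n.astype(float) ** 3)))
    pars = lmfit.Parameters()
    pars.add("kappa_tilde", value=k0, min=1e-12, max=1e4)
    pars.add("sigma_tilde", value=1.0, min=1e-6, max=1e6)

    def model_fn(p, nn):
        sp = SpectrumModelParams(kappa_tilde=p["kappa_tilde"].value,
                                 sigma_tilde=p["sigma_tilde"].value)
        return eval_tension_spectrum(sp, nn)

    return _run_lmfit(pars, model_fn, n.astype(float), y, se,
                      (int(n.min()), int(n.max())), spectrum.mean_radius,
                      "tension", 2)


def fit_confined_model(
    spectrum: FluctuationSpectrum,
    n_min: int = 3,
    n_max: int = 18,
    fix_gamma: float | None = None,
) -> FitResult:
    """Weighted nonlinear fit of the confined spectrum over (κ̃, σ̃, γ̃).

    Used for erythrocytes: γ̃ measures the harmonic coupling of the
    bilayer to the spectrin skeleton.  γ̃ is initialised at 0 and may
    pass through the σ̃² < γ̃ regime during the search (complex-branch
    evaluation keeps the model real there).  ``fix_gamma`` freezes γ̃
    for nested-model comparisons.
    """
    n, y, se = _usable(spectrum, n_min, n_max, min_modes=5)
    try:
        k0 = fit_bending_free(spectrum, max(n_min, 5), n_max).params.kappa_tilde
    except (InsufficientDataError, RuntimeError):
        k0 = 1.0 / (_TWO_PI * float(np.mean(y * n.astype(float) ** 3)))
    pars = lmfit.Parameters()
    pars.add("kappa_tilde", value=k0, min=1e-12, max=1e4)
    pars.add("sigma_tilde", value=1.0, min=1e-6, max=1e6)
    if fix_gamma is None:
        pars.add("gamma_tilde", value=0.0, min=0.0, max=1e9)
    else:
        pars.add("gamma_tilde", value=fix_gamma, vary=False)

    def model_fn(p, nn):
        sp = SpectrumModelParams(
            kappa_tilde=p["kappa_tilde"].value,
            sigma_tilde=p["sigma_tilde"].value,
            gamma_tilde=p["gamma_tilde"].value,
        )
        return eval_confined_spectrum(sp, nn)

    return _run_lmfit(pars, model_fn, n.astype(float), y, se,
                      (int(n.min()), int(n.max())), spectrum.mean_radius,
                      "confined", 2 if fix_gamma is not None else 3)


def normalize_series(
    kappas: list[tuple[float, float]], baseline: float
) -> list[tuple[float, float]]:
    """Normalise a (time, κ̃) series to its pre-treatment baseline κ̃₀.

    Returns (time, κ/κ₀) pairs; the entry measured at the baseline
    maps to exactly 1.
    """
    if not baseline > 0:
        raise ValueError("baseline kappa must be positive")
    return [(t, k / baseline) for t, k in kappas]
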