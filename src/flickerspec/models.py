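"""Planar-membrane fluctuation spectrum models.

Thermal shape undulations of a quasispherical vesicle (or a red blood
cell imaged at its equator) are analysed mode by mode: the equatorial
contour is written as a Fourier series and the mean-squared amplitude
of mode ``n``, ``⟨δ_n²⟩``, is compared with the prediction of the
Helfrich membrane model in the planar approximation.

Three nested spectra are provided, all dimensionless:

free (bending-only) spectrum
    ``⟨δ_n²⟩ = (1/2π) κ̃⁻¹ n⁻³`` — valid for short-wavelength modes
    where tension is negligible.

tension spectrum
    ``⟨δ_n²⟩ = (1/2π) (κ̃ σ̃)⁻¹ [1/n − (2σ̃ + n²)^{−1/2}]`` — a free
    bilayer under lateral tension.

confined spectrum
    adds a harmonic confinement of strength ``γ̃`` coupling the bilayer
    to the spectrin skeleton of an erythrocyte; see
    :func:`eval_confined_spectrum`.

The reduced parameters are ``κ̃ = κ/k_BT``, ``σ̃ = σ⟨R⟩²/2κ`` and
``γ̃ = γ⟨R⟩⁴/κ``, with ``⟨R⟩`` the mean contour radius.  Conversion to
dimensional values is an explicit, optional step
(:func:`to_dimensional`); the bending modulus is otherwise reported in
units of the thermal energy ``k_BT`` throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BOLTZMANN",
    "SpectrumModelParams",
    "DimensionalParams",
    "eval_free_spectrum",
    "eval_tension_spectrum",
    "eval_confined_spectrum",
    "to_dimensional",
    "to_dimensionless",
]

#: Boltzmann constant, J/K.
BOLTZMANN = 1.380649e-23

_TWO_PI = 2.0 * math.pi

# Below this value of 2*sigma/n^2 the direct bracket of the tension
# spectrum loses all significant digits to cancellation; switch to its
# series expansion.
_SERIES_SWITCH = 1e-8


@dataclass(frozen=True)
class SpectrumModelParams:
    """Reduced (dimensionless) membrane parameters.

    Parameters
    ----------
    kappa_tilde : float
        Bending modulus in units of ``k_BT``; must be positive.
    sigma_tilde : float
        Reduced lateral tension ``σ⟨R⟩²/2κ``; non-negative.
    gamma_tilde : float
        Reduced confinement strength ``γ⟨R⟩⁴/κ``; non-negative.
        Zero for free vesicles.
    mean_radius : float
        Mean contour radius ``⟨R⟩``; any length unit (m or px), used
        only for dimensional conversion.
    temperature : float
        Absolute temperature in K.
    """

    kappa_tilde: float
    sigma_tilde: float = 0.0
    gamma_tilde: float = 0.0
    mean_radius: float = 1.0
    temperature: float = 299.15

    def __post_init__(self) -> None:
        if not self.kappa_tilde > 0:
            raise ValueError(f"kappa_tilde must be > 0, got {self.kappa_tilde}")
        if self.sigma_tilde < 0:
            raise ValueError(f"sigma_tilde must be >= 0, got {self.sigma_tilde}")
        if self.gamma_tilde < 0:
            raise ValueError(f"gamma_tilde must be >= 0, got {self.gamma_tilde}")
        if not self.mean_radius > 0:
            raise ValueError(f"mean_radius must be > 0, got {self.mean_radius}")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")

    @property
    def kBT(self) -> float:
        """Thermal energy k_B * T in joules."""
        return BOLTZMANN * self.temperature


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional membrane parameters.

    ``kappa`` in J, ``sigma`` in N/m, ``gamma`` in J/m^4, ``kBT`` in J.
    """

    kappa: float
    sigma: float
    gamma: float
    kBT: float

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if not self.kBT > 0:
            raise ValueError(f"kBT must be > 0, got {self.kBT}")


def _check_modes(n) -> np.ndarray:
    n = np.asarray(n)
    if not np.all(n >= 2):
        raise ValueError("mode number n must be >= 2")
    return n.astype(float)


def eval_free_spectrum(kappa_tilde: float, n) -> np.ndarray | float:
    """Mean-squared mode amplitude of a tensionless free membrane.

    ``⟨δ_n²⟩ = (1/2π) κ̃⁻¹ n⁻³`` — the short-wavelength (bending
    dominated) limit used to fit modes n = 5–18.

    Parameters
    ----------
    kappa_tilde : float
        Reduced bending modulus, > 0.
    n : int or array of int
        Mode number(s), each >= 2.
    """
    if not kappa_tilde > 0:
        raise ValueError(f"kappa_tilde must be > 0, got {kappa_tilde}")
    nf = _check_modes(n)
    out = nf**-3.0 / (_TWO_PI * kappa_tilde)
    return out if isinstance(n, np.ndarray) else float(out)

def _tension_bracket(sigma_tilde: float, nf: np.ndarray) -> np.ndarray:
    """Bracket ``1/n − (2σ̃ + n²)^{−1/2}`` with a series fallback.

    For ``2σ̃/n² < 1e-8`` direct evaluation is pure cancellation; the
    expansion ``σ̃/n³ − (3/2)σ̃²/n⁵`` is then exact to double precision.
    """
    x = 2.0 * sigma_tilde / nf**2
    direct = 1.0 / nf - (2.0 * sigma_tilde + nf**2) ** -0.5
    series = sigma_tilde / nf**3 - 1.5 * sigma_tilde**2 / nf**5
    return np.where(x < _SERIES_SWITCH, series, direct)


def eval_tension_spectrum(params: SpectrumModelParams, n) -> np.ndarray | float:
    """Mean-squared mode amplitude of a free membrane under tension.

    ``⟨δ_n²⟩ = (1/2π) (κ̃ σ̃)⁻¹ [1/n − (2σ̃ + n²)^{−1/2}]``

    Requires ``σ̃ > 0``; the ``σ̃ → 0`` limit is
    :func:`eval_free_spectrum`.
    """
    if params.sigma_tilde <= 0:
        raise ValueError(
            "sigma_tilde must be > 0 for the tension spectrum; "
            "use eval_free_spectrum for the tensionless limit"
        )
    nf = _check_modes(n)
    out = _tension_bracket(params.sigma_tilde, nf) / (
        _TWO_PI * params.kappa_tilde * params.sigma_tilde
    )
    return out if isinstance(n, np.ndarray) else float(out)


#: imaginary residue above this fraction of the real part means the
#: complex-branch evaluation went wrong rather than merely rounded
_IMAG_TOL = 1e-9


def eval_confined_spectrum(params: SpectrumModelParams, n) -> np.ndarray | float:
    """Mean-squared mode amplitude of a harmonically confined membrane.

    ``⟨δ_n²⟩ = (1/2π) (κ̃ s)⁻¹ [(σ̃ + n² − s)^{−1/2} − (σ̃ + n² + s)^{−1/2}]``
    with ``s = (σ̃² − γ̃)^{1/2}``.

    When ``σ̃² < γ̃``, ``s`` is imaginary but the two bracket terms are
    complex conjugates, so the whole expression is analytically real:
    it is evaluated with principal complex square roots and the real
    part is returned after asserting the imaginary residue is
    negligible.  At ``σ̃² = γ̃`` the removable 0/0 is replaced by its
    limit ``(1/2π) κ̃⁻¹ (σ̃ + n²)^{−3/2}``.
    """
    if params.sigma_tilde <= 0:
        raise ValueError("sigma_tilde must be > 0 for the confined spectrum")
    nf = _check_modes(n)
    kt, st, gt = params.kappa_tilde, params.sigma_tilde, params.gamma_tilde
    disc = st**2 - gt
    A = st + nf**2

    if abs(disc) < 1e-14 * max(st**2, gt, 1e-300):
        out = A**-1.5 / (_TWO_PI * kt)
        return out if isinstance(n, np.ndarray) else float(out)

    s = np.sqrt(complex(disc))
    lo = A - s
    if disc > 0 and np.any(np.real(lo) <= 0):
        raise ValueError(
            "sigma_tilde + n^2 - sqrt(sigma_tilde^2 - gamma_tilde) <= 0: "
            "spectrum undefined for these parameters"
        )
    # small real sigma with moderate gamma: use the cancellation-safe
    # tension bracket when gamma == 0 (identical by algebra)
    if gt == 0.0:
        out = _tension_bracket(st, nf) / (_TWO_PI * kt * st)
        return out if isinstance(n, np.ndarray) else float(out)

    val = (lo**-0.5 - (A + s) ** -0.5) / (_TWO_PI * kt * s)
    re, im = np.real(val), np.imag(val)
    if np.any(np.abs(im) > _IMAG_TOL * np.maximum(np.abs(re), 1e-300)):
        raise FloatingPointError(
            "confined spectrum: imaginary residue exceeds tolerance"
        )
    if np.any(re <= 0):
        raise ValueError("confined spectrum evaluated non-positive")
    return re if isinstance(n, np.ndarray) else float(re)


def to_dimensional(params: SpectrumModelParams, kBT: float | None = None) -> DimensionalParams:
    """Convert reduced parameters to dimensional κ, σ, γ.

    ``κ = κ̃·k_BT``; ``σ = 2κσ̃/⟨R⟩²``; ``γ = γ̃κ/⟨R⟩⁴``.
    ``mean_radius`` must be in metres for SI output.  If *kBT* is not
    given it is taken from ``params.temperature``.
    """
    if kBT is None:
        kBT = params.kBT
    if not kBT > 0:
        raise ValueError("kBT must be > 0")
    if not params.mean_radius > 0:
        raise ValueError("mean_radius must be > 0")
    kappa = params.kappa_tilde * kBT
    sigma = 2.0 * kappa * params.sigma_tilde / params.mean_radius**2
    gamma = params.gamma_tilde * kappa / params.mean_radius**4
    return DimensionalParams(kappa=kappa, sigma=sigma, gamma=gamma, kBT=kBT)


def to_dimensionless(
    dim: DimensionalParams, mean_radius: float, temperature: float | None = None
) -> SpectrumModelParams:
    """Inverse of :func:`to_dimensional` (exact round trip)."""
    if not mean_radius > 0:
        raise ValueError("mean_radius must be > 0")
    if temperature is None:
        temperature = dim.kBT / BOLTZMANN
    return SpectrumModelParams(
        kappa_tilde=dim.kappa / dim.kBT,
        sigma_tilde=dim.sigma * mean_radius**2 / (2.0 * dim.kappa),
        gamma_tilde=dim.gamma * mean_radius**4 / dim.kappa,
        mean_radius=mean_radius,
        temperature=temperature,
    )
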