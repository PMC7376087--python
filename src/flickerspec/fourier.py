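"""Fourier decomposition of polar contours and fluctuation spectra.

Each closed equatorial contour is represented in polar coordinates
about its centre as

    r(θ) = R { 1 + Σ_n [ a_n cos(nθ) + b_n sin(nθ) ] }

and the fluctuation spectrum across a sequence of frames is the
per-mode variance

    ⟨δ_n²⟩ = [⟨a_n²⟩ − ⟨a_n⟩²] + [⟨b_n²⟩ − ⟨b_n⟩²]

using population moments over frames.  Integrals over θ use the
periodic trapezoidal rule, which is spectrally accurate for smooth
periodic contours; non-uniform angle grids (e.g. from ray-based
segmentation) are sorted and closed periodically before quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["Contour", "ContourModes", "FluctuationSpectrum",
           "decompose", "estimate_spectrum", "reconstruct"]

_TWO_PI = 2.0 * math.pi


@dataclass
class Contour:
    """A closed polar contour: radius samples at increasing angles.

    ``theta`` is in radians within one period, ``radius`` in the same
    length unit as ``center`` (px or m).  At least 64 samples covering
    at least 95% of the full circle are required.
    """

    theta: np.ndarray
    radius: np.ndarray
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        if self.theta.shape != self.radius.shape or self.theta.ndim != 1:
            raise ValueError("theta and radius must be 1-D arrays of equal length")
        if self.theta.size < 64:
            raise ValueError(f"need >= 64 contour samples, got {self.theta.size}")
        if np.any(self.radius <= 0):
            raise ValueError("all radii must be positive")
        order = np.argsort(self.theta)
        self.theta = self.theta[order]
        self.radius = self.radius[order]
        if np.any(np.diff(self.theta) <= 0):
            raise ValueError("theta samples must be distinct")
        span = self.theta[-1] - self.theta[0]
        # account for the implicit wrap-around gap
        gap = _TWO_PI - span
        if span + min(gap, np.max(np.diff(self.theta))) < 0.95 * _TWO_PI:
            raise ValueError("theta must span at least 95% of the full circle")


@dataclass
class ContourModes:
    """Fourier representation of one contour frame.

    ``a[k]`` and ``b[k]`` hold the coefficients of mode ``k + 1``
    (mode numbers run 1..n_max); ``mean_radius`` is the per-frame R.
    """

    mean_radius: float
    a: np.ndarray
    b: np.ndarray
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("a and b must be 1-D arrays of equal length")
        if self.n_max < 2:
            raise ValueError("need n_max >= 2")
        if not self.mean_radius > 0:
            raise ValueError("mean_radius must be positive")

    @property
    def n_max(self) -> int:
        return self.a.size

    def coeff(self, n: int) -> tuple[float, float]:
        """(a_n, b_n) for mode number n (1-based)."""
        return float(self.a[n - 1]), float(self.b[n - 1])


@dataclass
class FluctuationSpectrum:
    """Mean-squared fluctuation amplitudes ⟨δ_n²⟩ versus mode number.

    ``se`` is the per-mode standard error ``⟨δ_n²⟩·sqrt(2/N)`` from
    Gaussian-amplitude theory with N independent frames.
    """

    n: np.ndarray
    delta2: np.ndarray
    se: np.ndarray
    frames: int
    mean_radius: float

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=int)
        self.delta2 = np.asarray(self.delta2, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if not (self.n.shape == self.delta2.shape == self.se.shape):
            raise ValueError("n, delta2, se must have matching shapes")
        if self.frames < 2:
            raise ValueError("need at least 2 frames")
        if np.any(self.delta2 < 0) or np.any(self.se < 0):
            raise ValueError("delta2 and se must be non-negative")

    def restrict(self, n_min: int, n_max: int) -> "FluctuationSpectrum":
        """Sub-spectrum with n_min <= n <= n_max."""
        m = (self.n >= n_min) & (self.n <= n_max)
        return FluctuationSpectrum(
            n=self.n[m], delta2=self.delta2[m], se=self.se[m],
            frames=self.frames, mean_radius=self.mean_radius,
        )


def _periodic_close(theta: np.ndarray, values: np.ndarray):
    """Append the wrapped first sample so the trapezoid covers 2π."""
    th = np.append(theta, theta[0] + _TWO_PI)
    vv = np.append(values, values[..., :1], axis=-1)
    return th, vv


def decompose(contour: Contour, n_max: int = 18) -> ContourModes:
    """Fourier-decompose a contour into modes 1..n_max.

    R is the angular mean radius ``(1/2π)∮ r dθ``; the coefficients are
    ``a_n = (1/πR)∮ r cos(nθ) dθ`` and ``b_n = (1/πR)∮ r sin(nθ) dθ``.

    ``n_max`` may not exceed a quarter of the number of samples
    (≥ 4 samples per period of the highest mode).
    """
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    if n_max > contour.theta.size // 4:
        raise ValueError(
            f"n_max={n_max} too high for {contour.theta.size} samples "
            "(need >= 4 samples per period of the highest mode)"
        )
    th, r = _periodic_close(contour.theta, contour.radius)
    R = np.trapezoid(r, th) / _TWO_PI
    modes = np.arange(1, n_max + 1)[:, None]
    a = np.trapezoid(r[None, :] * np.cos(modes * th[None, :]), th, axis=1) / (math.pi * R)
    b = np.trapezoid(r[None, :] * np.sin(modes * th[None, :]), th, axis=1) / (math.pi * R)
    return ContourModes(mean_radius=float(R), a=a, b=b, center=contour.center)


def reconstruct(modes: ContourModes, theta_grid: np.ndarray) -> Contour:
    """Evaluate r(θ) = R{1 + Σ[a_n cos nθ + b_n sin nθ]} on a grid."""
    th = np.asarray(theta_grid, dtype=float)
    ns = np.arange(1, modes.n_max + 1)[:, None]
    r = modes.mean_radius * (
        1.0
        + modes.a @ np.cos(ns * th[None, :])
        + modes.b @ np.sin(ns * th[None, :])
    )
    return Contour(theta=th, radius=r, center=modes.center)


def estimate_spectrum(
    mode_series: list[ContourModes], n_min: int = 2
) -> FluctuationSpectrum:
    """Fluctuation spectrum ⟨δ_n²⟩ across a sequence of frames.

    Population (divide-by-N) moments are used, matching the ensemble
    averages of the definition; at the typical N ≈ 2000 frames the
    difference from the N−1 convention is negligible.  Mode 1 is the
    translation mode absorbed by per-frame centring and is excluded
    from reported spectra (``n_min`` defaults to 2).
    """
    if len(mode_series) < 2:
        raise ValueError("need at least 2 frames to estimate a spectrum")
    n_max = mode_series[0].n_max
    if any(m.n_max != n_max for m in mode_series):
        raise ValueError("all frames must share the same n_max")
    A = np.stack([m.a for m in mode_series])  # (N, n_max)
    B = np.stack([m.b for m in mode_series])
    N = A.shape[0]
    delta2 = A.var(axis=0) + B.var(axis=0)  # population variance
    se = delta2 * math.sqrt(2.0 / N)
    ns = np.arange(1, n_max + 1)
    keep = ns >= n_min
    return FluctuationSpectrum(
        n=ns[keep],
        delta2=delta2[keep],
        se=se[keep],
        frames=N,
        mean_radius=float(np.mean([m.mean_radius for m in mode_series])),
    )
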