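"""Synthetic data generators for every pipeline stage.

The generators emulate the statistical structure the analysis assumes,
so each stage can be validated against known ground truth:

* contour mode sequences whose Fourier amplitudes are zero-mean
  Gaussians with the variances of the tension or confined spectrum
  (equipartition of independent harmonic modes);
* rendered ring images — a Gaussian-profile bright or dark ring with
  additive Gaussian or Poisson noise, mimicking a fluorescence or
  phase-contrast equatorial section;
* sigmoidal ν_s(CH2) melting curves, optionally expanded into full
  synthetic band spectra so the peak-picking stage is exercised;
* two-component C≡O bands with prescribed areas.

Frames are temporally independent: the generators reproduce amplitude
statistics only, not mode relaxation dynamics.  Every generator is a
pure function of its parameters and an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fourier import Contour, ContourModes
from .models import (
    SpectrumModelParams,
    eval_confined_spectrum,
    eval_tension_spectrum,
)
from .segmentation import FrameImage
from .ftir import MeltingCurve, Spectrum1D

__all__ = [
    "RenderParams", "MeltGenParams",
    "sample_contour_modes", "render_frame", "render_sequence",
    "generate_melting_curve", "generate_melting_spectra", "generate_co_band",
]

_TWO_PI = 2.0 * math.pi
_SQRT_2PI = math.sqrt(_TWO_PI)


@dataclass(frozen=True)
class RenderParams:
    """Rendering parameters for synthetic ring images.

    ``ring_sigma`` is the Gaussian cross-section width of the membrane
    image (px); ``noise_sd`` is the additive Gaussian noise SD as a
    fraction of ``peak_intensity`` (so SNR = 1/noise_sd);
    ``poisson`` switches to Poisson shot noise with the intensity
    interpreted as expected counts; ``invert`` renders a dark ring on a
    bright background (phase-contrast-like).
    """

    image_size: int = 128
    ring_sigma: float = 2.0
    peak_intensity: float = 200.0
    background: float = 20.0
    noise_sd: float = 0.1
    poisson: bool = False
    invert: bool = False


@dataclass(frozen=True)
class MeltGenParams:
    """Parameters of the logistic melting-curve generator.

    ``nu(T) = nu_gel + delta_nu / (1 + exp(-(T - tm)/width)) + noise``

    with ``nu_gel`` the low-temperature (gel) band position (cm⁻¹),
    ``delta_nu`` the gel→fluid upshift (cm⁻¹), ``tm`` the midpoint
    (°C), ``width`` the transition width (°C) and ``noise_sd`` the
    per-point position noise (cm⁻¹), matching the ±0.1 cm⁻¹ read-out
    uncertainty of band positions.
    """

    nu_gel: float = 2850.5
    delta_nu: float = 2.5
    tm: float = 27.0
    width: float = 3.0
    t_range: tuple[float, float, float] = (5.0, 70.0, 1.0)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("width must be positive")
        if not self.t_range[2] > 0:
            raise ValueError("temperature step must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def sample_contour_modes(
    params: SpectrumModelParams,
    model: str,
    n_max: int,
    n_frames: int,
    seed: int,
) -> list[ContourModes]:
    """Draw i.i.d. frames of Fourier modes from a model spectrum.

    Per frame and mode, ``a_n`` and ``b_n`` are independent zero-mean
    normals with variance ``⟨δ_n²⟩/2`` each, so their variances sum to
    the model value.  ``model`` selects the tension spectrum
    (``"tension"``, free vesicle) or the confined spectrum
    (``"confined"``, erythrocyte); modes below 2 get zero amplitude
    (mode 1 is removed by centring in real data).
    """
    if model in ("tension", "eq1"):
        spec_fn = eval_tension_spectrum
    elif model in ("confined", "eq3"):
        spec_fn = eval_confined_spectrum
    else:
        raise ValueError(f"unknown model {model!r}: use 'tension' or 'confined'")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    ns = np.arange(2, n_max + 1)
    var = np.asarray(spec_fn(params, ns), dtype=float)
    sd = np.sqrt(var / 2.0)
    rng = np.random.default_rng(seed)
    A = np.zeros((n_frames, n_max))
    B = np.zeros((n_frames, n_max))
    A[:, 1:] = rng.normal(0.0, sd, size=(n_frames, ns.size))
    B[:, 1:] = rng.normal(0.0, sd, size=(n_frames, ns.size))
    return [
        ContourModes(mean_radius=params.mean_radius, a=A[i], b=B[i])
        for i in range(n_frames)
    ]


def render_frame(contour: Contour, rp: RenderParams, seed: int = 0) -> FrameImage:
    """Render a contour as a noisy ring image.

    Pixel intensity is ``background + peak·exp(−d²/2σ²)`` where d is
    the radial distance from the pixel to the contour at the pixel's
    angle (the contour radius is interpolated periodically in angle).
    With ``invert`` the ring is subtracted instead, giving a dark ring
    on a bright background.
    """
    size = rp.image_size
    cx, cy = contour.center
    if np.max(contour.radius) + 3 * rp.ring_sigma >= size / 2:
        raise ValueError("contour plus 3 ring widths exceeds the image half-size")
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dx, dy = xx - cx, yy - cy
    ang = np.mod(np.arctan2(dy, dx), _TWO_PI)
    pix_r = np.hypot(dx, dy)
    th = np.concatenate([contour.theta, [contour.theta[0] + _TWO_PI]])
    rr = np.concatenate([contour.radius, [contour.radius[0]]])
    ring_r = np.interp(ang, th, rr, period=_TWO_PI)
    d = pix_r - ring_r
    ring = np.exp(-0.5 * (d / rp.ring_sigma) ** 2)
    if rp.invert:
        img = rp.background + rp.peak_intensity * (1.0 - ring)
    else:
        img = rp.background + rp.peak_intensity * ring
    rng = np.random.default_rng(seed)
    if rp.poisson:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    elif rp.noise_sd > 0:
        img = img + rng.normal(0.0, rp.noise_sd * rp.peak_intensity, img.shape)
    return FrameImage(intensity=img)


def render_sequence(
    contours: list[Contour], rp: RenderParams, seed: int = 0
) -> list[FrameImage]:
    """Render a list of contours with per-frame independent noise."""
    seeds = np.random.SeedSequence(seed).spawn(len(contours))
    return [
        render_frame(c, rp, seed=int(s.generate_state(1)[0] % 2**31))
        for c, s in zip(contours, seeds)
    ]


def generate_melting_curve(p: MeltGenParams) -> MeltingCurve:
    """Sigmoidal ν_s(CH2)-vs-T melting curve with Gaussian noise."""
    lo, hi, step = p.t_range
    t = np.arange(lo, hi + step / 2, step)
    nu = p.nu_gel + p.delta_nu / (1.0 + np.exp(-(t - p.tm) / p.width))
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        nu = nu + rng.normal(0.0, p.noise_sd, nu.shape)
    return MeltingCurve(temperature=t, peak_position=nu)


def generate_melting_spectra(
    p: MeltGenParams,
    band_sigma: float = 5.0,
    amplitude: float = 1.0,
    grid: tuple[float, float, float] = (2820.0, 2880.0, 0.1),
) -> list[Spectrum1D]:
    """Expand a melting curve into full synthetic band spectra.

    Each temperature yields a Gaussian ν_s(CH2) band centred at the
    (noisy) generated position, so the full peak-picking →
    melting-curve → T_m chain can be exercised.  The default grid
    step of 0.1 cm⁻¹ makes the grid quantisation of "standard mode"
    peak picking match the ±0.1 cm⁻¹ read-out precision of band
    positions; instruments achieve this sub-resolution sampling by
    zero-filling before the Fourier transform.
    """
    curve = generate_melting_curve(p)
    lo, hi, step = grid
    wn = np.arange(lo, hi + step / 2, step)
    out = []
    for t, center in zip(curve.temperature, curve.peak_position):
        absorb = amplitude * np.exp(-0.5 * ((wn - center) / band_sigma) ** 2)
        out.append(Spectrum1D(wavenumber=wn, absorbance=absorb, temperature=float(t)))
    return out


def generate_co_band(
    areas: tuple[float, float],
    centers: tuple[float, float] = (1981.0, 1975.0),
    sigmas: tuple[float, float] = (1.5, 3.0),
    baseline: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    grid: tuple[float, float, float] = (1950.0, 2000.0, 0.5),
) -> Spectrum1D:
    """Two-Gaussian C≡O band with prescribed integrated areas.

    ``areas`` are (core, interfacial) integrated intensities; the
    Gaussian amplitudes are area/(σ√2π).  ``baseline`` is (offset,
    slope per cm⁻¹ from the grid start); ``noise_sd`` is absolute
    absorbance noise.
    """
    if any(a < 0 for a in areas):
        raise ValueError("areas must be non-negative")
    lo, hi, step = grid
    wn = np.arange(lo, hi + step / 2, step)
    y = baseline[0] + baseline[1] * (wn - lo)
    for area, c, s in zip(areas, centers, sigmas):
        y = y + (area / (s * _SQRT_2PI)) * np.exp(-0.5 * ((wn - c) / s) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, y.shape)
    return Spectrum1D(wavenumber=wn, absorbance=y)
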