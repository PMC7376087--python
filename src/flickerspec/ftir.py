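"""FTIR membrane-structure analysis.

Covers the infrared side of the workflow:

* peak picking of the CH2 symmetric stretch ``ν_s(CH2)`` (~2850 cm⁻¹),
  whose position tracks acyl-chain conformational order;
* melting curves (peak position vs temperature) and the main
  phase-transition temperature ``T_m`` from the maximum of the
  smoothed first derivative;
* the expansivity proxy ``β = (∂ν_s/∂T)/ν_s``;
* integration of the C≡O antisymmetric stretch of membrane-solubilised
  tungsten hexacarbonyl (W(CO)₆) over 1960–1990 cm⁻¹ after linear
  baseline removal, optionally normalised to the ν_s(CH2) intensity at
  25 °C;
* two-Gaussian decomposition of that band into a narrow core component
  near 1981 cm⁻¹ and a broader interfacial component near 1975 cm⁻¹,
  with the core area fraction ``f₁ = I₁/(I₁+I₂)``.

Derivatives are taken after Savitzky–Golay smoothing (window 7,
polynomial order 2), which keeps the derivative-maximum estimate of
T_m robust to the ±0.1 cm⁻¹ noise typical of band-position readings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import lmfit
import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "Spectrum1D", "MeltingCurve", "BandDecomposition",
    "EdgePeakError", "NoTransitionError",
    "pick_peak", "build_melting_curve", "estimate_tm", "compute_beta",
    "integrate_band", "fit_two_gaussians",
]

log = logging.getLogger(__name__)

#: integration window of the W(CO)6 C≡O antisymmetric stretch, cm^-1
CO_BAND_RANGE = (1960.0, 1990.0)
#: decomposition window: wider than the integration range so the flat
#: wings on both sides anchor the linear baseline of the two-Gaussian fit
CO_FIT_RANGE = (1950.0, 2000.0)
#: component centres of the C≡O band: hydrophobic core / interfacial
CO_CENTERS = (1981.0, 1975.0)

_SAVGOL_WINDOW = 7
_SAVGOL_ORDER = 2


class EdgePeakError(ValueError):
    """The band maximum sits on the edge of the search window."""


class NoTransitionError(ValueError):
    """No interior derivative maximum: the curve shows no transition."""


@dataclass
class Spectrum1D:
    """A single IR absorbance spectrum.

    ``wavenumber`` (cm⁻¹) must be strictly monotonic on input and is
    stored ascending; ``temperature`` (°C) is metadata.
    """

    wavenumber: np.ndarray
    absorbance: np.ndarray
    temperature: float | None = None

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumber.shape != self.absorbance.shape or self.wavenumber.ndim != 1:
            raise ValueError("wavenumber and absorbance must be 1-D and equal length")
        if self.wavenumber.size < 16:
            raise ValueError("need at least 16 spectral points")
        if not (np.all(np.isfinite(self.wavenumber)) and np.all(np.isfinite(self.absorbance))):
            raise ValueError("spectrum contains non-finite values")
        d = np.diff(self.wavenumber)
        if np.all(d < 0):  # descending grids are common in FTIR exports
            self.wavenumber = self.wavenumber[::-1]
            self.absorbance = self.absorbance[::-1]
        elif not np.all(d > 0):
            raise ValueError("wavenumber grid must be strictly monotonic")


@dataclass
class MeltingCurve:
    """ν_s(CH2) band position versus temperature (both ascending in T)."""

    temperature: np.ndarray
    peak_position: np.ndarray

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.peak_position = np.asarray(self.peak_position, dtype=float)
        if self.temperature.shape != self.peak_position.shape or self.temperature.ndim != 1:
            raise ValueError("temperature and peak_position must be 1-D, equal length")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class BandDecomposition:
    """Two-Gaussian decomposition of the C≡O band.

    Component 0 is the narrow hydrophobic-core band (~1981 cm⁻¹),
    component 1 the broader interfacial band (~1975 cm⁻¹).  ``f1`` is
    the core area fraction I₁/(I₁+I₂).
    """

    centers: tuple[float, float]
    widths: tuple[float, float]
    areas: tuple[float, float]
    f1: float
    rss: float

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.areas):
            raise ValueError("component areas must be non-negative")
        if not 0.0 <= self.f1 <= 1.0:
            raise ValueError("f1 must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "centers_cm1": list(self.centers),
            "widths_sigma_cm1": list(self.widths),
            "areas": list(self.areas),
            "f1": self.f1,
            "rss": self.rss,
        }


def _window_slice(wn: np.ndarray, window: tuple[float, float]) -> slice:
    lo, hi = min(window), max(window)
    if lo < wn[0] or hi > wn[-1]:
        raise ValueError(f"window {window} outside spectral grid "
                         f"[{wn[0]}, {wn[-1]}]")
    i0 = int(np.searchsorted(wn, lo, side="left"))
    i1 = int(np.searchsorted(wn, hi, side="right"))
    if i1 - i0 < 3:
        raise ValueError("window covers fewer than 3 grid points")
    return slice(i0, i1)


def pick_peak(
    spectrum: Spectrum1D,
    window: tuple[float, float],
    refine: bool = False,
) -> float:
    """Position of the highest relative maximum inside *window*.

    Matches the "standard mode" of interactive peak picking: the
    returned position is the grid x-coordinate of the tallest local
    maximum (no interpolation).  Set ``refine=True`` for an optional
    three-point parabolic sub-grid refinement.
    """
    sl = _window_slice(spectrum.wavenumber, window)
    y = spectrum.absorbance[sl]
    x = spectrum.wavenumber[sl]
    interior = np.arange(1, y.size - 1)
    is_max = (y[interior] >= y[interior - 1]) & (y[interior] >= y[interior + 1]) & (
        (y[interior] > y[interior - 1]) | (y[interior] > y[interior + 1])
    )
    cand = interior[is_max]
    if cand.size == 0:
        raise EdgePeakError("no relative maximum inside the window "
                            "(band maximum on window edge?)")
    i = int(cand[np.argmax(y[cand])])
    if not refine:
        return float(x[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(x[i])
    off = 0.5 * (y[i - 1] - y[i + 1]) / denom
    step = x[i + 1] - x[i] if off > 0 else x[i] - x[i - 1]
    return float(x[i] + np.clip(off, -0.5, 0.5) * step)


def build_melting_curve(
    series: list[Spectrum1D], window: tuple[float, float]
) -> MeltingCurve:
    """Apply :func:`pick_peak` per temperature and sort ascending in T.

    Spectra whose peak pick fails are dropped with a log entry; at
    least 5 temperatures must survive.
    """
    if len(series) < 5:
        raise ValueError("need spectra at >= 5 temperatures")
    temps, pos = [], []
    for sp in series:
        if sp.temperature is None:
            raise ValueError("every spectrum needs a temperature")
        try:
            p = pick_peak(sp, window)
        except (EdgePeakError, ValueError) as exc:
            log.info("T = %s dropped: %s", sp.temperature, exc)
            continue
        temps.append(sp.temperature)
        pos.append(p)
    if len(temps) < 5:
        raise ValueError("fewer than 5 temperatures survived peak picking")
    order = np.argsort(temps)
    return MeltingCurve(
        temperature=np.asarray(temps)[order],
        peak_position=np.asarray(pos)[order],
    )


_DERIV_WINDOW = 11


def _smoothed_derivative(curve: MeltingCurve, smooth_deriv: bool = False) -> np.ndarray:
    """Savitzky–Golay smoothed dν/dT on the curve's temperature grid.

    The filter assumes near-uniform temperature steps (the acquisition
    protocol ramps at a constant rate).  With ``smooth_deriv`` the
    derivative itself gets a second Savitzky–Golay pass (window 11,
    order 2), which suppresses the argmax jitter of broad derivative
    peaks without shifting a symmetric peak.
    """
    t, v = curve.temperature, curve.peak_position
    window = min(_SAVGOL_WINDOW, v.size if v.size % 2 == 1 else v.size - 1)
    sm = savgol_filter(v, window_length=window, polyorder=min(_SAVGOL_ORDER, window - 1))
    dv = np.gradient(sm, t)
    if smooth_deriv and v.size >= _DERIV_WINDOW:
        dv = savgol_filter(dv, window_length=_DERIV_WINDOW, polyorder=_SAVGOL_ORDER)
    return dv


def estimate_tm(curve: MeltingCurve, min_points: int = 7) -> float:
    """Main-transition temperature from the derivative maximum.

    The melting curve is smoothed (Savitzky–Golay, window 7, order 2)
    and differentiated by centred finite differences; the derivative
    receives a second smoothing pass, and T_m is located as the
    intensity-weighted centroid of the contiguous half-maximum region
    around the derivative maximum.  For the (symmetric) derivative
    peak of a sigmoidal transition the centroid is an unbiased and
    far less noise-sensitive localiser than the raw argmax.  A
    derivative maximum on the first or last point, or an essentially
    flat derivative — as for a strictly linear curve — raises
    :class:`NoTransitionError`.
    """
    if curve.temperature.size < min_points:
        raise ValueError(f"need >= {min_points} points spanning the transition")
    t = curve.temperature
    dv = _smoothed_derivative(curve, smooth_deriv=True)
    span = float(np.ptp(dv))
    if span <= 1e-9 * max(float(np.max(np.abs(dv))), 1e-30):
        raise NoTransitionError("flat derivative: no transition")
    i = int(np.argmax(dv))
    if i == 0 or i == dv.size - 1:
        raise NoTransitionError("derivative maximum on range edge: "
                                "no interior melting transition")
    # half-maximum centroid above the low-derivative baseline
    base = float(np.percentile(dv, 10))
    dvb = np.clip(dv - base, 0.0, None)
    thr = 0.5 * dvb[i]
    lo = i
    while lo > 0 and dvb[lo - 1] >= thr:
        lo -= 1
    hi = i
    while hi < dv.size - 1 and dvb[hi + 1] >= thr:
        hi += 1
    w = dvb[lo:hi + 1] - thr
    return float(np.sum(w * t[lo:hi + 1]) / np.sum(w))


def compute_beta(curve: MeltingCurve) -> list[tuple[float, float]]:
    """Thermal-expansivity proxy β(T) = (∂ν_s/∂T)/ν_s per interior point.

    Uses the same smoothing as :func:`estimate_tm`.  β peaks in the
    melting range, mirroring the volumetric expansion coefficient.
    """
    if curve.temperature.size < 5:
        raise ValueError("need >= 5 points")
    if np.any(curve.peak_position == 0):
        raise ValueError("zero band position is unphysical")
    dv = _smoothed_derivative(curve)
    beta = dv / curve.peak_position
    return [(float(t), float(b))
            for t, b in zip(curve.temperature[1:-1], beta[1:-1])]


def integrate_band(
    spectrum: Spectrum1D,
    band_range: tuple[float, float] = CO_BAND_RANGE,
    norm_ref: float | None = None,
) -> float:
    """Baseline-corrected trapezoidal band area over *band_range*.

    A straight baseline through the absorbance at the two range
    endpoints is subtracted before integration; the area is divided by
    ``norm_ref`` (e.g. the ν_s(CH2) peak height at 25 °C) when given.
    A net area below −1% of the gross area triggers a warning — the
    linear baseline has likely failed.
    """
    sl = _window_slice(spectrum.wavenumber, band_range)
    x = spectrum.wavenumber[sl]
    y = spectrum.absorbance[sl]
    base = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    net = float(np.trapezoid(y - base, x))
    gross = float(np.trapezoid(np.abs(y), x))
    if net < -0.01 * max(gross, 1e-300):
        log.warning("integrate_band: net area %.3g is significantly negative; "
                    "linear baseline may be inadequate", net)
    if norm_ref is not None:
        if not norm_ref > 0:
            raise ValueError("norm_ref must be positive")
        net /= norm_ref
    return net


_SQRT_2PI = math.sqrt(2.0 * math.pi)


def fit_two_gaussians(
    spectrum: Spectrum1D,
    band_range: tuple[float, float] = CO_FIT_RANGE,
    centers: tuple[float, float] = CO_CENTERS,
    center_bound: float = 3.0,
) -> BandDecomposition:
    """Decompose the C≡O band into two Gaussians plus a linear baseline.

    Component centres are initialised at 1981 and 1975 cm⁻¹ and bounded
    to ±3 cm⁻¹ of those values; the core (1981) component is
    constrained narrower than the interfacial (1975) one, reflecting
    the more homogeneous environment deep in the hydrophobic core.
    Areas are amplitude·σ·√(2π) and ``f1`` is the core fraction.

    The default fit window is wider than the 1960–1990 cm⁻¹
    integration range: the near-flat wings on either side of the band
    are what determine the linear baseline, and including them
    noticeably tightens the uncertainty of the area fraction.
    """
    sl = _window_slice(spectrum.wavenumber, band_range)
    x = spectrum.wavenumber[sl]
    y = spectrum.absorbance[sl]
    dx = float(np.median(np.diff(x)))
    amp0 = max(float(y.max() - y.min()), 1e-12)

    pars = lmfit.Parameters()
    pars.add("amp1", value=0.6 * amp0, min=0.0)
    pars.add("cen1", value=centers[0], min=centers[0] - center_bound,
             max=centers[0] + center_bound)
    pars.add("sig1", value=1.5, min=0.2, max=15.0)
    pars.add("amp2", value=0.6 * amp0, min=0.0)
    pars.add("cen2", value=centers[1], min=centers[1] - center_bound,
             max=centers[1] + center_bound)
    # widths: sig2 = sig1 + dsig with dsig >= 0 keeps the core band narrower
    pars.add("dsig", value=1.5, min=0.0, max=15.0)
    pars.add("sig2", expr="sig1 + dsig")
    pars.add("b0", value=float(y.min()))
    pars.add("b1", value=0.0)

    def model(p):
        g1 = p["amp1"] * np.exp(-0.5 * ((x - p["cen1"]) / p["sig1"]) ** 2)
        g2 = p["amp2"] * np.exp(-0.5 * ((x - p["cen2"]) / p["sig2"]) ** 2)
        return g1 + g2 + p["b0"] + p["b1"] * (x - x[0])

    result = lmfit.minimize(lambda p: model(p) - y, pars, method="leastsq")
    if not result.success:
        raise RuntimeError(f"two-Gaussian fit failed: {result.message}")
    v = result.params.valuesdict()
    if v["sig1"] < dx or v["sig2"] < dx:
        raise RuntimeError("degenerate fit: component width below grid step")
    a1 = v["amp1"] * v["sig1"] * _SQRT_2PI
    a2 = v["amp2"] * v["sig2"] * _SQRT_2PI
    total = a1 + a2
    f1 = a1 / total if total > 0 else 0.0
    return BandDecomposition(
        centers=(v["cen1"], v["cen2"]),
        widths=(v["sig1"], v["sig2"]),
        areas=(a1, a2),
        f1=float(np.clip(f1, 0.0, 1.0)),
        rss=float(np.sum(result.residual**2)),
    )
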