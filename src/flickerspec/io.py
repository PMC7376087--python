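"""Readers, writers, configuration and pipeline composition.

File conventions (all diffable text except TIFF stacks):

* contour CSV — long format, columns ``frame, theta_rad, r_px``;
* spectrum CSV — columns ``n, delta2, se, frames, mean_radius_px``;
* melting-curve CSV — columns ``temperature_C, peak_cm1``;
* FTIR spectra — two-column CSV ``wavenumber_cm-1, absorbance`` with
  the temperature in a manifest CSV (columns ``file, temperature_C``);
* fit results — JSON embedding the resolved configuration and seed.

Angles are stored in radians; image coordinates are (row, col) with
the origin top-left, while contour centres are (x, y) = (col, row).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .fourier import Contour, FluctuationSpectrum, decompose, estimate_spectrum
from .fitting import FitResult, fit_bending_free, fit_confined_model, fit_tension_model
from .ftir import MeltingCurve, Spectrum1D, build_melting_curve, compute_beta, estimate_tm, fit_two_gaussians
from .segmentation import FrameImage, track_sequence

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_contours_csv", "write_contours_csv",
    "read_spectrum_csv", "write_spectrum_csv",
    "read_tiff_stack", "write_tiff_stack",
    "read_spectrum1d_csv", "read_ftir_manifest",
    "write_melting_curve_csv", "write_fit_json",
    "run_flicker", "run_ftir",
]


@dataclass
class PipelineConfig:
    """Resolved parameters of a full pipeline run.

    Defaults follow the analysis protocol: 360 rays, modes up to 18,
    bending-only fits over n = 5–18 for free vesicles and the confined
    model over n = 3–18 for red blood cells.
    """

    seed: int = 0
    output_dir: str = "."
    # segmentation
    n_rays: int = 360
    invert: bool = False
    annulus_frac: float = 0.30
    seed_radius: float | None = None
    center_guess: tuple[float, float] | None = None
    # fourier
    n_max: int = 18
    # fitting
    fit_model: str = "free"  # free | tension | confined
    n_min_fit: int = 5
    n_max_fit: int = 18
    # ftir
    ch2_window: tuple[float, float] = (2840.0, 2860.0)
    co_range: tuple[float, float] = (1960.0, 1990.0)
    co_fit_range: tuple[float, float] = (1950.0, 2000.0)
    fit_bands: bool = False

    def __post_init__(self) -> None:
        if self.n_max < 2 or self.n_min_fit < 2 or self.n_max_fit < self.n_min_fit:
            raise ValueError("invalid mode-range configuration")
        if self.n_rays < 4 * self.n_max:
            raise ValueError("n_rays must be >= 4 * n_max")
        if self.fit_model not in ("free", "tension", "confined"):
            raise ValueError(f"unknown fit model {self.fit_model!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("center_guess", "ch2_window", "co_range", "co_fit_range"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d


# ---------------------------------------------------------------- contours

def write_contours_csv(contours: list[Contour], path: str | Path) -> None:
    rows = []
    for i, c in enumerate(contours):
        rows.append(pd.DataFrame({
            "frame": i, "theta_rad": c.theta, "r_px": c.radius,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_contours_csv(path: str | Path) -> list[Contour]:
    df = pd.read_csv(path)
    need = {"frame", "theta_rad", "r_px"}
    if not need.issubset(df.columns):
        raise ValueError(f"contour CSV must have columns {sorted(need)}")
    out = []
    for _, grp in df.groupby("frame", sort=True):
        out.append(Contour(theta=grp["theta_rad"].to_numpy(),
                           radius=grp["r_px"].to_numpy()))
    return out


# ---------------------------------------------------------------- spectra

def write_spectrum_csv(spec: FluctuationSpectrum, path: str | Path) -> None:
    pd.DataFrame({
        "n": spec.n, "delta2": spec.delta2, "se": spec.se,
        "frames": spec.frames, "mean_radius_px": spec.mean_radius,
    }).to_csv(path, index=False)


def read_spectrum_csv(path: str | Path) -> FluctuationSpectrum:
    df = pd.read_csv(path)
    return FluctuationSpectrum(
        n=df["n"].to_numpy(), delta2=df["delta2"].to_numpy(),
        se=df["se"].to_numpy(), frames=int(df["frames"].iloc[0]),
        mean_radius=float(df["mean_radius_px"].iloc[0]),
    )


# ---------------------------------------------------------------- images

def read_tiff_stack(path: str | Path) -> list[FrameImage]:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return [FrameImage(intensity=frame.astype(float)) for frame in arr]


def write_tiff_stack(frames: list[FrameImage], path: str | Path) -> None:
    arr = np.stack([f.intensity for f in frames]).astype(np.float32)
    tifffile.imwrite(path, arr)


# ---------------------------------------------------------------- ftir

def read_spectrum1d_csv(path: str | Path, temperature: float | None = None) -> Spectrum1D:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("FTIR CSV needs two columns: wavenumber, absorbance")
    return Spectrum1D(
        wavenumber=df.iloc[:, 0].to_numpy(),
        absorbance=df.iloc[:, 1].to_numpy(),
        temperature=temperature,
    )


def read_ftir_manifest(path: str | Path) -> list[Spectrum1D]:
    """Read a manifest CSV (columns ``file, temperature_C``).

    File paths are resolved relative to the manifest location.
    Unreadable entries are logged and skipped; more than 20% failures
    aborts the run.
    """
    mpath = Path(path)
    df = pd.read_csv(mpath)
    need = {"file", "temperature_C"}
    if not need.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(need)}")
    out, failed = [], 0
    for _, row in df.iterrows():
        try:
            out.append(read_spectrum1d_csv(mpath.parent / str(row["file"]),
                                           temperature=float(row["temperature_C"])))
        except (OSError, ValueError) as exc:
            log.warning("manifest entry %s failed: %s", row["file"], exc)
            failed += 1
    if failed > 0.2 * len(df):
        raise RuntimeError(f"{failed}/{len(df)} manifest entries unreadable")
    return out


def write_melting_curve_csv(curve: MeltingCurve, path: str | Path) -> None:
    pd.DataFrame({
        "temperature_C": curve.temperature, "peak_cm1": curve.peak_position,
    }).to_csv(path, index=False)


def write_fit_json(result: FitResult, config: PipelineConfig, path: str | Path,
                   provenance: dict | None = None) -> None:
    payload = result.to_dict()
    payload["config"] = config.to_dict()
    payload["seed"] = config.seed
    payload["code_version"] = __version__
    if provenance:
        payload["provenance"] = provenance
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------- pipelines

_FITTERS = {
    "free": lambda s, c: fit_bending_free(s, c.n_min_fit, c.n_max_fit),
    "tension": lambda s, c: fit_tension_model(s, c.n_min_fit, c.n_max_fit),
    "confined": lambda s, c: fit_confined_model(s, c.n_min_fit, c.n_max_fit),
}


def run_flicker(
    input_path: str | Path, config: PipelineConfig
) -> tuple[FitResult, FluctuationSpectrum]:
    """Full flicker pipeline: images or contours → spectrum → fit.

    TIFF input runs segmentation first; contour CSV input skips it.
    Writes ``spectrum.csv`` and ``fit.json`` into the configured
    output directory and returns the in-memory results.
    """
    input_path = Path(input_path)
    if not input_path.exists():
        raise FileNotFoundError(input_path)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if input_path.suffix.lower() in (".tif", ".tiff"):
        stack = read_tiff_stack(input_path)
        h, w = stack[0].intensity.shape
        guess = config.center_guess or (w / 2.0, h / 2.0)
        contours, dropped = track_sequence(
            stack, guess, n_rays=config.n_rays,
            annulus_frac=config.annulus_frac,
            seed_radius=config.seed_radius, invert=config.invert,
        )
        if dropped:
            log.info("dropped frames: %s", dropped)
    else:
        contours = read_contours_csv(input_path)
        dropped = []

    modes = [decompose(c, config.n_max) for c in contours]
    spectrum = estimate_spectrum(modes)
    result = _FITTERS[config.fit_model](spectrum, config)

    write_spectrum_csv(spectrum, outdir / "spectrum.csv")
    write_fit_json(result, config, outdir / "fit.json",
                   provenance={"input": str(input_path),
                               "dropped_frames": dropped})
    return result, spectrum


def run_ftir(manifest: str | Path, config: PipelineConfig) -> dict:
    """FTIR pipeline: manifest → melting curve, T_m, β, optional bands.

    Writes ``melting_curve.csv`` and ``ftir.json``; returns the
    summary dict.  Band decomposition per temperature is enabled with
    ``config.fit_bands``.
    """
    series = read_ftir_manifest(manifest)
    if len(series) < 5:
        raise ValueError("manifest must list >= 5 readable temperatures")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    curve = build_melting_curve(series, config.ch2_window)
    tm = estimate_tm(curve)
    beta = compute_beta(curve)
    summary: dict = {
        "tm_C": tm,
        "beta": [[t, b] for t, b in beta],
        "config": config.to_dict(),
        "seed": config.seed,
        "code_version": __version__,
    }
    if config.fit_bands:
        bands = []
        for sp in series:
            try:
                dec = fit_two_gaussians(sp, config.co_fit_range)
            except (RuntimeError, ValueError) as exc:
                log.warning("band fit at T = %s failed: %s", sp.temperature, exc)
                continue
            bands.append({"temperature_C": sp.temperature, **dec.to_dict()})
        summary["bands"] = bands

    write_melting_curve_csv(curve, outdir / "melting_curve.csv")
    (outdir / "ftir.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
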