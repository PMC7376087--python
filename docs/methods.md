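# Methods

This note documents the models, estimators and numerical choices behind
`flickerspec`, and what the synthetic-data generators do and do not
emulate.

## Flicker (thermal fluctuation) spectroscopy

A quasispherical vesicle — or an erythrocyte imaged at its equatorial
plane — undergoes thermally driven shape undulations. The equatorial
contour in polar coordinates about its centre is expanded as

    r(θ) = R { 1 + Σ_n [ a_n cos(nθ) + b_n sin(nθ) ] },

and the fluctuation spectrum is the per-mode variance across frames,

    ⟨δ_n²⟩ = [⟨a_n²⟩ − ⟨a_n⟩²] + [⟨b_n²⟩ − ⟨b_n⟩²].

In the planar-membrane approximation the Helfrich model predicts, with
the reduced parameters κ̃ = κ/k_BT (bending modulus), σ̃ = σ⟨R⟩²/2κ
(tension) and γ̃ = γ⟨R⟩⁴/κ (harmonic confinement of the bilayer by the
spectrin skeleton):

* tension spectrum (free vesicle):
  ⟨δ_n²⟩ = (1/2π)(κ̃σ̃)⁻¹ [1/n − (2σ̃ + n²)^(−1/2)];
* bending-only limit (n ≥ 5): ⟨δ_n²⟩ ≈ (1/2πκ̃) n⁻³;
* confined spectrum (red blood cell):
  ⟨δ_n²⟩ = (1/2π)(κ̃s)⁻¹ [(σ̃ + n² − s)^(−1/2) − (σ̃ + n² + s)^(−1/2)],
  s = (σ̃² − γ̃)^(1/2).

Numerical choices:

* **Cancellation guard.** The tension bracket loses all significant
  digits as σ̃ → 0; for 2σ̃/n² < 1e-8 it is replaced by its series
  σ̃/n³ − (3/2)σ̃²/n⁵, exact to double precision there. Without the
  switch, direct evaluation at σ̃ = 1e-9 agrees with the n⁻³ law only
  to ~1e-5 relative.
* **Overdamped confinement branch.** For σ̃² < γ̃ the two bracket terms
  of the confined spectrum are complex conjugates, so the expression is
  analytically real; it is evaluated with principal complex square
  roots and the real part returned after asserting the imaginary
  residue is below 1e-9 of the real part. At σ̃² = γ̃ the removable
  0/0 is replaced by its limit (1/2πκ̃)(σ̃ + n²)^(−3/2). The physical
  relevance of this regime is unestablished; the rule simply makes the
  model total on the parameter box the optimiser explores.
* **Units.** κ is carried in k_BT units throughout; conversion to J,
  N/m, J/m⁴ is an explicit step with user-supplied temperature and
  radius in metres.

## Contour analysis

Quadrature over θ uses the periodic trapezoidal rule after sorting, so
it is spectrally accurate on the near-uniform ray grids produced by
segmentation. Mode 1 is the translation mode, absorbed by per-frame
centring, and is excluded from reported spectra; each frame's
coefficients are normalised by that frame's R, while the sequence-level
⟨R⟩ (mean of per-frame R) is what enters σ̃ and γ̃. Variances use
population (divide-by-N) moments, matching the ensemble-average
definition; at N ≈ 2000 frames the N vs N−1 distinction is negligible.
Per-mode standard errors follow Gaussian-amplitude theory with
independent frames, se_n = ⟨δ_n²⟩ √(2/N).

## Segmentation

The membrane ring is located by sampling, for each of 360 uniformly
spaced ray angles, a radial intensity profile from the current centre
by bilinear interpolation (0.5 px steps within a ±30% annulus of the
running radius). Each profile is smoothed with a Gaussian matched
roughly to the membrane image width (σ = 2 px by default) — this does
not bias a symmetric peak but suppresses the noise-induced jitter of
its maximum (0.40 → 0.12 px RMS at SNR 10) — and the maximum is refined
to subpixel by a three-point parabolic fit, which is exact for
quadratic peaks (< 0.004 px bias on noiseless rings). The centre is
iterated to the contour centroid until the shift is below 0.01 px, at
which point the translation-mode amplitudes |a₁|, |b₁| are below 1e-3.
Dark-ring (phase-contrast) images are handled by an invert flag. The
search annulus is re-anchored only when the radius estimate drifts by
more than 5%, so identical frames produce identical contours.

Detection noise adds an approximately white per-mode variance floor
(~4ε²/(N_rays R²) for per-angle error ε). At SNR 10 this inflates the
highest fitted modes by ~15–20% and biases the recovered κ̃ down by
roughly 8% in the end-to-end imaging pipeline; no floor subtraction is
applied, and users fitting noisier footage should restrict n_max. Finite
exposure time additionally blurs high modes in real video; no correction
is implemented.

## Spectrum fitting

* The bending-only model is linear in C = 1/(2πκ̃) and solved in closed
  form by weighted least squares over modes 5–18 (weights 1/se²);
  doubling all se leaves the estimate unchanged and doubles its error.
* The tension and confined models are fitted by Levenberg–Marquardt
  (lmfit) with κ̃ initialised from the bending-only fit of the upper
  modes, σ̃ from 1, γ̃ from 0; bounds κ̃ ∈ (0, 1e4], σ̃ ∈ [1e-6, 1e6],
  γ̃ ∈ [0, 1e9]. The confined model is evaluated on the complex branch
  wherever the search wanders into σ̃² < γ̃.
* Identifiability: with data only at n ≥ 5 and low tension, σ̃ is
  unidentifiable; the fit then returns a standard error exceeding the
  estimate, which callers should read as "no tension information".
  The red-cell fit defaults to modes 3–18 (mode 2 is shape/curvature
  dominated).
* Per-object fits across vesicles or cells are summarised as mean ± SD;
  time series of a treated cell are normalised to the pre-treatment
  modulus κ₀ of that same cell.

## FTIR analysis

The CH₂ symmetric stretch ν_s(CH₂) (~2850 cm⁻¹) tracks acyl-chain
conformational order. Peak picking returns the grid x-coordinate of the
tallest relative maximum in the window ("standard mode"; no
interpolation, with an optional parabolic refinement off by default).
Melting curves are ν_s(CH₂) position vs temperature.

**Melting temperature.** T_m is the temperature of the maximum of the
first derivative of the melting curve. The curve is smoothed with a
Savitzky–Golay filter (window 7, order 2) and differentiated by centred
differences; the derivative receives a second Savitzky–Golay pass
(window 11, order 2) and the maximum is localised as the
intensity-weighted centroid of the contiguous half-maximum region. The
derivative peak of a sigmoidal transition is symmetric about the
midpoint, so smoothing and centroiding do not bias its location
(< 1e-3 °C on noiseless logistics) while the raw argmax of the broad,
flat peak is noise-dominated: at 0.05 cm⁻¹ position noise and 1 °C
sampling the centroid recovers the midpoint within 1 °C in ≥ 99/100
runs (SD ≤ 0.4 °C), versus ~69/100 for argmax with 3-point refinement.
A derivative maximum on the range edge, or an essentially flat
derivative (strictly linear curve), raises a no-transition error.

**Expansivity proxy.** β(T) = (∂ν_s/∂T)/ν_s with the same curve
smoothing; β of exp(cT) is c to better than 1% on interior points, and
β peaks at T_m for a sigmoidal melt.

**W(CO)₆ band.** The C≡O antisymmetric stretch of membrane-solubilised
tungsten hexacarbonyl reports on the free volume of the bilayer core.
Its integrated area over 1960–1990 cm⁻¹ is computed after subtracting a
straight baseline through the range endpoints, optionally normalised to
the ν_s(CH₂) peak height at 25 °C ("intensity" read as baseline-
corrected height, with a flag to switch to area). The band decomposes
into a narrow core component near 1981 cm⁻¹ and a broader interfacial
component near 1975 cm⁻¹; a least-squares fit of two Gaussians plus a
linear baseline (centres bounded ±3 cm⁻¹, core σ constrained below the
interfacial σ via σ₂ = σ₁ + Δσ, Δσ ≥ 0) yields areas A_i = amp_i σ_i √2π
and the core fraction f₁ = A₁/(A₁+A₂), which is invariant to overall
intensity scaling. The decomposition is fitted over 1950–2000 cm⁻¹,
wider than the integration range: the near-flat wings are what pin down
the linear baseline, and a Cramér–Rao computation at 1% amplitude noise
shows the narrow window cannot deliver f₁ to ±0.02 at a 95% rate for
any unbiased estimator (best SD 0.0106 vs 0.0099 on the full support).
Wavenumber grids may arrive ascending or descending; they are stored
ascending.

## Synthetic data

Generators are pure functions of (parameters, seed):

* **Contour modes.** a_n and b_n are drawn i.i.d. zero-mean normal with
  variance ⟨δ_n²⟩/2 each (equipartition of independent harmonic modes),
  frames independent. This reproduces amplitude statistics only — real
  mode dynamics are temporally correlated at finite frame rates, so the
  √(2/N) standard errors are exact for the generator but optimistic for
  strongly correlated real footage.
* **Ring images.** Intensity = background + peak·exp(−d²/2σ_ring²)
  with d the radial distance to the contour at the pixel's angle;
  additive Gaussian noise (SD as a fraction of peak; SNR = 1/fraction)
  or Poisson counts; invert for phase-contrast-like dark rings. No
  optical PSF beyond the Gaussian ring profile and no motion blur.
* **Melting curves.** ν(T) = ν_gel + Δν/(1 + exp(−(T − T_m)/w)) + noise
  on T = 5–70 °C at 1 °C steps; defaults ν_gel = 2850.5 cm⁻¹,
  Δν = 2.5 cm⁻¹, w = 3 °C, noise 0.05 cm⁻¹ — a sigmoid spanning the
  gel→fluid upshift of the CH₂ stretch with the ±0.1 cm⁻¹-class
  read-out noise of band positions. Curves can be expanded into full
  Gaussian band spectra on a 0.1 cm⁻¹ grid so the peak-picking stage is
  exercised; the fine grid matches the effective sub-resolution
  precision instruments reach by zero-filling.
* **C≡O bands.** Two Gaussians with prescribed areas (defaults: centres
  1981/1975 cm⁻¹, σ 1.5/3.0 cm⁻¹, areas 3:1) plus linear baseline and
  noise on a 0.5 cm⁻¹ grid over 1950–2000 cm⁻¹.

Passing round-trips on these generators validates the estimators under
the stated statistical model; they do not certify performance on real
footage with correlated frames, uneven illumination, or non-Gaussian
FTIR baselines.

## Problem sizes and reproducibility

Validation uses the acquisition-scale protocol: 2000 frames per object,
4 objects per composition for the bending-modulus round-trips
(generating κ̃ of 44 and 170 k_BT at σ̃ = 0.01, R = 50 px, modes to 18),
2000 rendered 128² frames at SNR 10 for the imaging round-trip, and
melting curves over 5–70 °C at 1 °C with midpoints 27 and 33 °C. All
randomness flows from explicit integer seeds; `scripts/acceptance.py`
derives per-stage sub-seeds from its `--seed` via `SeedSequence`, and
identical configuration + seed yields byte-identical result JSONs.

## Known limitations

* Planar-membrane approximation only; no quasispherical (curved
  geometry) spectra.
* No temporal correlation analysis of mode amplitudes (relaxation
  times), no shear-modulus extraction from low RBC modes.
* No correction for integration-time blur or the detection noise floor
  on high modes.
* FTIR preprocessing (atmospheric compensation, water-vapour
  subtraction) is out of scope; the thermal expansion coefficient α is
  not computed — β is its spectroscopic proxy.
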