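# flickerspec

Membrane flicker spectroscopy and FTIR membrane-structure analysis.

`flickerspec` is for membrane biophysicists who measure the mechanics of
lipid bilayers and cell membranes from video microscopy, and their
structure and thermotropic behaviour from infrared spectra. It
implements two measurement chains as a tested, reusable library with a
thin command-line interface:

1. **Thermal (flicker) fluctuation spectroscopy.** Equatorial contours
   of giant unilamellar vesicles (GUVs) or red blood cells are extracted
   from video frames by maximum-intensity radial search, expanded as a
   Fourier series r(θ) = R{1 + Σ [aₙ cos nθ + bₙ sin nθ]}, and the
   per-mode variances ⟨δₙ²⟩ = Var(aₙ) + Var(bₙ) are fitted with
   planar-membrane fluctuation spectra:

   - free vesicle under tension:
     ⟨δₙ²⟩ = (1/2π)(κ̃σ̃)⁻¹ [1/n − (2σ̃ + n²)^(−1/2)],
   - bending-dominated modes (n = 5–18): ⟨δₙ²⟩ ≈ (1/2πκ̃) n⁻³,
   - skeleton-confined membrane (erythrocytes):
     ⟨δₙ²⟩ = (1/2π)(κ̃√(σ̃²−γ̃))⁻¹ [(σ̃+n²−√(σ̃²−γ̃))^(−1/2) − (σ̃+n²+√(σ̃²−γ̃))^(−1/2)],

   yielding the bending modulus κ̃ = κ/k_BT, reduced tension
   σ̃ = σ⟨R⟩²/2κ and confinement strength γ̃ = γ⟨R⟩⁴/κ.

2. **FTIR membrane-structure analysis.** Melting curves from the
   ν_s(CH₂) band position (~2850 cm⁻¹) vs temperature; the main
   transition temperature T_m from the maximum of the smoothed first
   derivative; the thermal-expansivity proxy β = (∂ν_s/∂T)/ν_s; and the
   W(CO)₆ C≡O band (1960–1990 cm⁻¹): baseline-corrected integration and
   two-Gaussian decomposition into core (1981 cm⁻¹) and interfacial
   (1975 cm⁻¹) components with the core area fraction
   f₁ = I₁/(I₁ + I₂).

A synthetic-data module generates contour sequences with the exact
statistical structure the models assume, rendered microscopy frames
with controlled noise, and sigmoidal melting curves and two-component
bands — so every stage of both chains is testable end to end without
any experimental data. See `docs/methods.md` for the models,
estimators and their assumptions.

## Worked example

Simulate 2000 contour frames of a vesicle with bending modulus
κ = 44 k_BT at reduced tension σ̃ = 0.01, estimate the fluctuation
spectrum, and fit the bending-only law over modes 5–18:

```sh
flickerspec simulate-contours --kappa 44 --sigma 0.01 --frames 2000 --seed 1 --out guv
flickerspec spectrum --out guv guv/contours.csv
flickerspec fit --out guv free guv/spectrum.csv
```

which prints

```
{"kappa_tilde": 44.25520461629649, "sigma_tilde": 0.0, "gamma_tilde": 0.0, "mean_radius": 50.0}
```

— the recovered modulus, 44.3 k_BT, agrees with the generating 44 k_BT
within the ~1% statistical error expected from 2000 frames × 14 modes
(full details, including per-parameter standard errors and reduced χ²,
are in `guv/fit.json`). The spectrum file lists each mode's
mean-squared amplitude with its standard error:

```
n,delta2,se,frames,mean_radius_px
2,0.000437109168064443,1.3822605572249736e-05,2000,50.0
3,0.00013298774862669058,4.2054418655827165e-06,2000,50.0
...
```

The FTIR side works the same way — generate synthetic melting spectra
with a transition at 27 °C, then locate T_m from the derivative
maximum:

```sh
flickerspec simulate-ftir --tm 27 --width 3 --seed 1 --out melt
flickerspec ftir-melt --out melt melt/manifest.csv
```

```
{"tm_C": 27.255439599397583}
```

The recovered 27.3 °C sits within the ~0.3 °C scatter of the
derivative-maximum estimator at this noise level. The same commands run
on real data: `extract` takes a multi-page TIFF stack, `ftir-melt`
takes a manifest CSV (`file, temperature_C`) of two-column wavenumber/
absorbance spectra, and `fit confined` fits the three-parameter
erythrocyte model. The Python API (`flickerspec.*`) exposes every stage
individually.

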