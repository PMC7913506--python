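# hemospect

Spectral imaging of skin chromophores from a plain RGB camera. The package
reconstructs per-pixel diffuse reflectance spectra from RGB responses by
Wiener estimation, models skin reflectance with a two-layer photon-packet
Monte Carlo simulation, and inverts absorbance spectra to concentrations of
methemoglobin (metHb), oxygenated hemoglobin (HbO), deoxygenated hemoglobin
(HbR) and melanin through a two-stage regression calibrated on simulated
spectra. Derived maps include total hemoglobin (HbO + HbR + metHb) and
tissue oxygen saturation StO2 = 100 * C_HbO / C_HbT. A synthetic phantom
generator makes the entire pipeline testable without any measured data.

## How it works

1. **Chromophores** (`hemospect.chromophores`) — bundled extinction spectra
   of metHb, HbO, HbR and melanin (CSV assets with provenance headers).
   Concentrations are vol.% of whole blood anchored at 150 g/L hemoglobin
   (molar mass 64,500 g/mol); melanin is a melanosome volume fraction of
   the epidermis.
2. **Monte Carlo** (`hemospect.mcsim`) — MCML-style photon packets in a
   layered slab: exponential steps, weight drop by mu_a/mu_t,
   Henyey-Greenstein scattering, Fresnel boundaries, Russian roulette.
   Deterministic per seed, exact five-way energy accounting. A
   scattering-only *path library* (`trace_paths` / `SkinPathLibrary`)
   evaluates many absorption combinations from one trace per wavelength by
   exponential reweighting.
3. **Calibration** (`hemospect.calibration`) — simulates 1550 reflectance
   spectra over the grid: melanin 1-10 vol.% (step 1), total hemoglobin
   0.2-1.0 vol.% (step 0.2), 31 oxygenation/metHb states per cell. The
   first regression (MRA1) fits each absorbance spectrum on the four
   extinction spectra plus an offset over 500-650 nm (16 wavelengths); the
   second (MRA2) maps MRA1 coefficients to true concentrations with a
   quadratic feature expansion (z = 21).
4. **Camera** (`hemospect.camera`) — system matrix F = U·E·S on the
   29-point 420-700 nm grid, Wiener matrix
   W = ⟨r rᵀ⟩ Fᵀ (F ⟨r rᵀ⟩ Fᵀ + N)⁻¹ from a training ensemble, white
   balance against a 99 % reflectance standard.
5. **Pipeline** (`hemospect.pipeline`) — per-pixel reconstruct → absorbance
   → MRA1 (precomputed 5 × 16 projection) → concentrations; ROI statistics,
   control-normalized time series ΔM = (M − M_c)/M_c, and GFC spectral
   validation with labels at 0.995 / 0.999 / 0.9999.
6. **Phantom** (`hemospect.phantom`) — ground-truthed synthetic scenes and
   methemoglobinemia-like time series rendered through the calibrated
   forward model and camera, with seeded noise and quantization.

When the inverse model is used on RGB images (rather than measured
spectra), fit it on camera-cycled spectra via
`calibration.cycle_through_camera(dataset, wiener_model)`: this keeps the
second-stage regression consistent with the information that survives the
three-channel camera.

## CLI

```bash
hemospect calibrate --photons 20000 --seed 1 --thin 2 \
    --dataset calibration_dataset.csv --model inverse_model.json
hemospect phantom --out phantom_bundle --photons 5000 --seed 1
hemospect train-wiener --ensemble spectra.csv --out wiener_model.json
hemospect calibrate --wiener wiener_model.json --model camera_model.json
hemospect process frame.png --wiener wiener_model.json --model camera_model.json --out maps
hemospect series frames/*.png --wiener wiener_model.json --model camera_model.json \
    --roi 0 0 300 300 --control 0 --out series.csv
hemospect validate measured.csv estimated.csv
```

Camera profiles are CSV (`wavelength_nm,u1,u2,u3,E,S`); a documented
default (Gaussian RGB passbands at 610/540/460 nm, flat illuminant and
sensitivity) is bundled for experimentation.

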