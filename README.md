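# lampspec

Hyperspectral reflectance reconstruction with active incandescent
illumination. An incandescent lamp driven through a sequence of filament
temperatures emits a family of blackbody spectra; a camera with a small
number of bandpass channels records one image per (temperature, channel)
pair; the sample's reflectance spectrum is then recovered by solving a
doubly regularized linear inverse problem.

The package provides:

- **radiometry** — wavelength grids, filament-temperature sequences,
  Planck spectral radiance, and the T⁴-normalized illumination matrix
  (optionally filtered by a bulb-envelope transmissivity CSV);
- **detector** — quantum-efficiency curves (a parametric silicon-like
  default is shipped; any two-column CSV overrides it) times top-hat
  bandpass filters;
- **forward_model** — system-matrix assembly, noisy signal simulation
  (per-signal or global-mean SNR conventions), and filament-temperature
  perturbations;
- **reconstruction** — Tikhonov + smoothness-penalty augmented least
  squares with minimum-norm tie-breaking and nonnegativity clamping;
  the weight rule `k2 = 1/SNR`, `k1 = k2 × 1e-4`;
- **metrics** — RMSE and relative RMSE (with a reflectance floor for
  the relative metric);
- **synthetic_spectra** — a seeded 24-spectrum panel (18 colored tiles
  with sigmoid edges, bumps and ripples + 6 gray levels) standing in
  for a physical color chart;
- **sweep** — the sensitivity-analysis battery: a default condition and
  ten single-parameter perturbations (SNR, temperature step, minimum
  temperature, filament-temperature error, spectral step, channel
  count), replicated over independent noise draws.

## Command line

```sh
# emit the canonical synthetic spectrum panel
lampspec panel --out panel.csv --seed 0

# simulate noisy multi-channel acquisitions for every spectrum
lampspec simulate --spectra panel.csv --out-dir signals/ --seed 0

# reconstruct one spectrum from its signals
lampspec reconstruct --signals signals/signals_gray_1.csv --out recon.csv

# full sensitivity battery -> RMSE/rRMSE tables + summary
lampspec sweep --out-dir sweep/ --seed 0 --plots

# per-pixel reconstruction of a (p*M)-page TIFF stack
lampspec reconstruct-cube --cube stack.tif --out cube.tif
```

All commands accept `--config cfg.yaml` with keys matching
`lampspec.sweep.RunConfig` (grid, temperature range, `p`, `snr`,
`temp_error_sd`, weights, replicate count, seeds). Every run writes a
`provenance.json` with the configuration, seeds and package version.

## Notes on scale

The illumination matrix is expressed in units of a fixed reference
radiance-per-K⁴ constant (`lampspec.constants.REFERENCE_RADIANCE_PER_K4`)
chosen so that simulated signals are of order one and the default
regularization weights are well scaled. Forward simulation and
reconstruction share the same matrix, so reconstructed reflectance is
unaffected by this choice.
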