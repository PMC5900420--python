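# shikispec

Chemometrics for non-destructive shikimic-acid phenotyping of maize under
glyphosate, from canopy Vis-NIR hyperspectral imaging and chlorophyll
fluorescence.

Glyphosate blocks EPSPS, so shikimic acid piles up in susceptible plants
while transgenic glyphosate-tolerant lines stay near baseline — which makes
shikimate the quantitative readout for screening tolerance in breeding
programs.  The wet assay is destructive and slow; this package implements
the imaging alternative: predict shikimate from canopy reflectance spectra
(427.75–948.49 nm, 412 bands) or from a panel of ~60 chlorophyll-
fluorescence parameters, discriminate damaged from healthy plants per
assessment day, and render per-pixel shikimate maps from hypercubes.

The statistical core is PLS1 regression: X (reflectance at selected
wavelengths, or ChlF parameters) and y (shikimate) are decomposed into
latent variables chosen by leave-one-out cross-validation, giving an
original-scale calibration **y = Xb + b₀** with quality reported as
R²c/RMSE_C (calibration) and R²p/RMSE_P (SPXY-held-out prediction).
Around it:

- **synth** — a generative model of the whole trial (2 genotypes × 4 days ×
  10 water / 20 glyphosate pots): Beer–Lambert canopy spectra with
  chlorophyll and water absorbers, a fluorescence table with 11 informative
  parameters (Fv/Fm, NPQ, qL, qP, ...) among 49 noise ones, and hypercubes
  over soil backgrounds.  No external data needed anywhere.
- **hsio** — ENVI (ASCII header + BIL float32) cube I/O, white/dark
  reflectance calibration, NIR/red-ratio plant segmentation, ROI averaging,
  and spectral preprocessing (db6 wavelet denoise/debaseline, SNV, MSC,
  Savitzky–Golay).
- **featsel** — successive projections algorithm (SPA) for minimal-
  collinearity wavelength chains scored by MLR validation RMSE; backward
  refinement under a cross-validated R² floor; random-frog selection
  probabilities for fluorescence parameters with the 0.4 threshold.
- **chemo** — the PLS1/NIPALS engine, PLS-DA with 1/2 dummy coding and the
  0.5/1.5/2.5 decision rule, SPXY (Kennard–Stone on joint X–y distances)
  splitting, LOO latent-variable selection, residual outlier screening,
  metrics.
- **chemimg** — pixel-wise model transfer to cubes and blue→red
  concentration-map rendering.
- **pipeline / cli** — the orchestrated study with a byte-reproducible
  JSON + Markdown report.

## Worked example

```sh
shikispec run --seed 7 --outdir out/
```

simulates the 240-plant trial, retains 216 samples, screens outliers,
splits 144/72 by SPXY, selects wavelengths (SPA + refinement), selects
fluorescence parameters (random frog at threshold 0.4), fits the PLSR and
per-day PLS-DA models, renders day-8 prediction maps, and prints:

```
spectral PLSR (5 LVs): R2c=0.934 R2p=0.898
report -> out/report.json
```

From `out/report.md` of that run:

- Spectral calibration on the refined sensitive wavelengths: R²c = 0.93,
  RMSE_C = 9.3 (n = 144); R²p = 0.90, RMSE_P = 7.9 (n = 72) — shikimate in
  the generator's fresh-weight units, healthy ≈ 30, heavily stressed ≈ 150.
- Random frog put all 11 truly informative fluorescence parameters above
  the 0.4 threshold (plus one stray noise parameter); PLSR on the selected
  parameters: R²p = 0.80, RMSE_P = 10.8.
- Per-day PLS-DA (healthy = 1: TG + WT-water; damaged = 2: WT-glyphosate)
  reaches 100% prediction accuracy from day 6 on both feature sources —
  damage is separable well before visual symptoms, which is the point of
  the method.
- Prediction maps: WT day-8 foreground mean 118.1 against a true 119.9;
  TG 29.4 against 27.3.

The same numbers re-appear on any machine for the same seed: every stage
seed derives from the master seed and the report carries no timestamps.

A fixed calibration ships with the package: an 11-wavelength PLSR equation
(446–949 nm, intercept −1126.19) usable directly for prediction and
mapping:

```python
import numpy as np, shikispec
model = shikispec.printed_equation_model()
shikispec.chemo.predict(model, np.zeros(11))   # array([-1126.19])
```

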