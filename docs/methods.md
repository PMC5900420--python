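# Methods

`shikispec` re-creates, end to end, a chemometric workflow for
non-destructive estimation of shikimic acid in maize canopies under
glyphosate stress, from two instrument streams: visible/near-infrared
(Vis-NIR) hyperspectral imaging and chlorophyll-fluorescence (ChlF)
imaging.  Because the original plant trial is not publicly deposited, the
package ships a synthetic-data generator that encodes the trial's design
and the known stress physiology; every downstream stage — preprocessing,
variable selection, PLS modelling, discriminant analysis, chemical mapping
— is exercised and validated against that generator.

## The synthetic trial

**Design.** Two genotypes (glyphosate-tolerant transgenic, TG, and its
wild-type parent, WT) are assessed 2, 4, 6 and 8 days after spraying, with
10 water-control and 20 glyphosate pots per genotype and day: 120 plants
per genotype, 240 in total.  Shikimate accumulates only where glyphosate
inhibits EPSPS, i.e. in glyphosate-treated WT plants:

    shikimate ~ N(30, 10)                       healthy (TG, and WT-water)
    shikimate ~ N(30 + 12·day, 20)              WT under glyphosate

in arbitrary fresh-weight units (the reference study never states units).
The scale was calibrated against the printed precision of the original
models: healthy plants sit near 20–40, stressed WT plants reach ≈150 at
day 8 (≥1.4× the TG level, as reported), and the within-group spreads are
sized so that a prediction set selected by SPXY keeps a reference-value
dispersion of roughly 25–30 units — the dispersion implied by a reported
R²p of 0.82 coexisting with an RMSE_P of 13.38.  With that geometry the
pipeline's RMSEs land in the low teens, making printed-magnitude
comparisons meaningful.

**Spectra.** Reflectance over 412 bands spanning 427.75–948.49 nm follows a
Beer–Lambert-style generative model on a healthy-leaf baseline b(λ) (low
visible reflectance, green bump at 550 nm, red edge near 715 nm, NIR
plateau ≈0.5):

    r(λ) = m · b(λ) · exp(−c_a g_a(λ) − c_b g_b(λ) − c_w g_w(λ)) + a + ε(λ)

with Gaussian absorber bands for chlorophyll a (430, 670 nm), chlorophyll
b (460, 645 nm) and leaf water (950 nm), multiplicative/additive scatter
(m ~ N(1, 0.04), a ~ N(0, 0.008)) and white noise (sd 0.004).  The latents
link to shikimate linearly: pigment falls (−0.010 per unit from a base of
1.60) and the effective 950-nm O–H optical depth rises (+0.004 per unit
from 0.30).  The direction of the water term is deliberate: stressed
canopies show *lower* NIR reflectance, and in an absorbance-only model
that requires the 950-nm optical depth to grow with stress (a wilting
canopy presents a longer effective path through liquid water per unit
scattering).  Chlorophyll a and b carry partially independent noise
(sd 0.12 and 0.20 around the shared pigment latent) — real canopies are
not rank-two in their pigment chemistry, and this keeps wavelength
selection from degenerating to a two-band problem.  Channel noises were
budgeted so the combined irreducible prediction error is ≈9–10 units,
reproducing calibrations with R² ≈ 0.8 and RMSE in the low teens.

**Fluorescence table.** 60 parameters per plant, named after the usual
quenching-analysis repertoire.  Eleven are informative — Fv/Fm, NPQ, qL,
qP, two quantum yields, steady-state and relaxation quantities — and are
affine in shikimate with physiologically signed slopes (photochemical
efficiency down, non-photochemical quenching up) plus Gaussian noise; the
remaining 49 are pure noise.  Noise-to-slope ratios are uniform across the
informative set (≈45 shikimate-units each), so a multi-parameter PLSR
recovers shikimate with R² in the low-to-mid 0.8s, while no single
parameter suffices.

**Cubes.** A plant cube places Beer–Lambert foreground spectra (per-pixel
concentration = plant value + spatial noise, mapped through the
deterministic link) over a flat soil background whose NIR/red ratio ≈1,
far below the vegetation segmentation threshold.

**What the generator does not emulate.** Radiative transfer (no PROSPECT:
absorbance is log-linear by construction, which is exactly the structure
PLSR assumes — real leaves are kinder to no one), instrument striping and
wavelength miscalibration, specular and geometry effects beyond global
scatter, diurnal or developmental drift in ChlF parameters, and kinetic
fluorescence transients (only the derived parameter table is produced).
Green tests therefore demonstrate the *software* recovers what the
generative model encodes at realistic noise; they do not certify
performance on real canopies.

## Processing chain

**Calibration and segmentation.** Reflectance = (raw − dark)/(white −
dark), element-wise; a zero reference difference raises, reporting the
voxel count affected.  Plants are segmented by the NIR/red band ratio
(800 nm / 670 nm > 2.0) followed by largest 8-connected component; the
threshold is configurable and the soil template fails it by a wide margin.
Band lookup by wavelength uses the nearest sampled band within 1.5 nm
(≈ half the 2.8 nm instrument resolution); farther requests raise.

**Preprocessing.** The default is Daubechies-6 wavelet treatment at
decomposition level 3 with symmetric extension.  Two modes exist because
"removing the background in the spectrum" is ambiguous: `denoise`
(default) soft-thresholds all detail levels at the universal threshold
σ√(2 ln n), σ from the MAD of the finest details; `debaseline` subtracts
the reconstruction of the level-3 approximation.  SNV (sample sd, n−1),
MSC (OLS against a reference) and Savitzky–Golay smoothing are available
alternatives; all preserve the wavelength axis exactly.

**PLS engine.** Single-response PLS (PLS1) by the NIPALS recursion on
centred data — exact in one pass per latent variable since the weight
vector is just the deflated covariance X'y normalised.  Spectral matrices
are centred only (shared units); ChlF tables are autoscaled
(heterogeneous units); both choices are exposed.  Coefficients collapse
to the original scale (β = W(PᵀW)⁻¹q), so prediction is affine and
provably identical to the score recursion (tested to 1e−10); with as many
components as predictors the solution equals ordinary least squares
(tested to 1e−8 against the normal equations, and the engine is
cross-checked against scikit-learn's PLSRegression).  Latent-variable
counts come from leave-one-out cross-validation, ties to the smaller
count.  Outlier screening is a single pass: fit on all samples, flag
|residual| > 3 sd.

**SPXY partitioning.** Kennard–Stone max–min selection on the normalised
joint distance d_X/max d_X + d_y/max d_y; the first two picks are the
most separated pair, ties break to the lowest index, and the calibration
set holds round(fraction·n) samples (216 → 144/72 at 2:1; 60 → 45/15 at
3:1).  Deterministic and permutation-equivariant.

**Wavelength selection.** SPA grows a minimal-collinearity chain from
every possible starting column (projection of all unchosen columns onto
the chain's orthogonal complement, appending the largest residual norm;
ties to the lowest index; unextendable chains stop short), scores every
chain prefix by the validation RMSE of an intercept-included MLR, and
returns the global minimiser.  Backward refinement then prunes the
selection: each round removes the wavelength whose removal least
increases leave-one-out PLSR RMSECV, stopping at a cross-validated R²
floor (default 0.75) or after `max_drop` removals (pipeline default 2,
mirroring the reference study's 13 → 11 step).

**Fluorescence-parameter selection.** Random frog maintains a feature
subset V and iterates: draw a candidate size m* ~ round(N(|V|,
0.3|V|)) clamped to [1, p]; shrink by dropping the bottom-ranked features
(|PLS coefficient| on autoscaled data), grow by ranking V against a
random outside pool of twice the deficit, and — when m* = |V| — swap one
random member for one random challenger; accept a candidate whose
5-fold-CV RMSE (3-component PLS) is no worse, and a worse one with
probability 0.1·(RMSE_V/RMSE_V*)⁴.  Both subsets are re-scored on freshly
drawn folds every iteration.  A feature's selection probability is its
visit frequency; parameters above 0.4 are retained.  Three choices here
are deliberate design, departing from the textbook sampler: the
fourth-power damping keeps near-neutral swaps churning (so probabilities
stay diffuse on noise-only tables) while a clearly superior subset is
essentially never abandoned; the same-size swap move exists because the
chain otherwise stalls whenever the proposed size equals the current one;
and per-iteration fold redraws prevent a single optimistic RMSE estimate
from freezing the walk.  Under these dynamics a feature that *is* the
response (plus small noise) reaches selection probability > 0.9 within
2000 iterations, while on a 240 × 60 noise table no feature exceeds 0.5.
The default 10 000 iterations follow published practice; 5-fold CV
replaces leave-one-out inside the sampler because LOO at 10⁴ iterations
would dominate runtime without changing the ranking.

**Discrimination.** PLS-DA regresses the dummy response (healthy = 1:
all TG plants plus WT-water; damaged = 2: WT under glyphosate) and
classifies by interval: (0.5, 1.5] → healthy, (1.5, 2.5] → damaged,
anything else unclassified and counted as incorrect.  Boundaries are
upper-inclusive — the source rule says "between" without specifying, so
the convention is fixed and documented here.  Per-day models use the
3:1 SPXY split.

**Chemical maps.** The wavelength-subset calibration transfers to every
foreground pixel (optionally after the same per-pixel preprocessing the
calibration spectra received; configurable off).  Background pixels carry
NaN, never a concentration.  Rendering maps concentrations linearly onto
a blue→red colormap over the 1st–99th percentile range by default, with
the background neutral grey and a colorbar strip appended; rendering is
byte-deterministic.  For a linear model the foreground mean of the map
equals the prediction from the ROI mean spectrum exactly; the tests
assert agreement within 1% on noiseless cubes.

## Orchestration and reproducibility

`run_pipeline` chains simulate → preprocess → select (SPA + refinement;
random frog + threshold) → train (PLSR per source) → classify (per-day
PLS-DA) → map → report.  Every stage consumes a child seed derived from
the master seed by a counter scheme recorded in the report; reports carry
the config hash and no timestamps, so a fixed (config, seed) pair
reproduces `report.json` byte for byte.  By default 216 of the 240
simulated plants are retained (the generator exposes the count rather
than hard-coding an exclusion rule, since the original study reports 240
collected but 216 analysed without stating why).

Problem sizes in the test suite are desk-scale by design: random frog
runs at 2000 iterations in tests (10 000 default), SPA chains cap at
k = 25 in the pipeline configuration, and the power/null suites use 10–20
seeded replicates.  These sizes are the package's own defaults for fast,
reproducible verification; all are configurable upward.

## Known limitations

- The generator's linear latent structure favours PLSR by construction;
  nonlinear stress responses (saturating pigment loss, heterogeneous
  canopy architecture) are out of scope.
- The per-day discriminant classes are imbalanced (2:1 healthy:damaged by
  design), so a no-information classifier scores ≈ 2/3, not 1/2 — worth
  remembering when reading per-day accuracy tables.
- SPA's returned chain length is validation-RMSE-minimal and can be small
  when few independent spectral factors exist; the refinement floor, not
  SPA itself, controls the final wavelength count.
- ENVI support covers exactly what the package writes (BIL, float32,
  little-endian, ASCII header with a wavelength list), not the format's
  full generality.
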