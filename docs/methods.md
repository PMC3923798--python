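# Methods

## The measurement being emulated

Transmission candling illuminates an egg from below and images the light
that passes through. Developed embryonic tissue and blood absorb strongly,
so two scalar features track development: the spectral mean-peak
transmittance x̄ of a fixed region of interest, and the fraction W of the
egg silhouette occupied by a low-transmittance region. The package
implements the full chain from raw sensor counts to repeated-run
classification summaries, and a phantom generator that stands in for a
physical 150-egg cohort (three groups: N non-developed, D developed, W
weakly developed; imaged on incubation days 0–4).

## Phantom generator

Each phantom is rendered deterministically from `(config, group, day,
sample_seed)`:

* **Geometry.** An axis-aligned elliptical egg (default semi-axes 80×150 px
  on a 220×400 frame — half the emulated rig's 440×804 acquisition frame,
  for speed; `full_scale()` and `tiny()` presets exist, the latter being
  the smallest egg that still contains the 1000-px ROI).
* **Spectrum.** Every shell pixel carries the same unit-peak asymmetric
  Gaussian over the 400–1000 nm grid (default 111 bands): σ = 60 nm below
  the 825 nm peak, 40 nm above. These widths put the mean transmittance
  below 650 nm and above 950 nm under 2 % of the peak, matching the
  near-zero fringes of real candling spectra.
* **Group/day structure.** Peak transmittance is
  `0.5 · egg_scale · decay(group)^day` with per-day decay factors
  N 0.98, W 0.90, D 0.82 (decline ordered D ≥ W ≥ N). `egg_scale` is a
  per-egg lognormal (σ = 0.15) emulating shell-pigmentation variability:
  large enough that day-0 groups are statistically indistinguishable and
  early-day classification hovers near chance, small enough that every egg
  stays above the 0.125 mask threshold at day 4.
* **Embryo.** An off-centre ellipse (offset 0.25 of the egg axes, random
  per-egg direction) whose area fraction follows the growth schedule
  D: 0, 0.01, 0.03, 0.10, 0.20 for days 0–4; W is the D curve delayed one
  day and halved; N is identically zero. A 3-lobe sinusoidal radial
  perturbation (amplitude 0.05) keeps the boundary from being a perfect
  conic. Inside the embryo, transmittance is multiplied by 0.25.
  Per-egg growth jitter is lognormal (σ = 0.15). The truth sidecar counts
  the exact painted masks.
* **Noise.** Multiplicative lognormal pore speckle (σ = 0.05) drawn per
  pixel and shared across bands — pores are spatial, not spectral — plus
  additive Gaussian sensor noise (σ = 0.5 % of the white−dark span) per
  pixel-band. References: dark ≈ 30 counts, white ≈ 1000 counts, same
  noise model.
* **Seeding.** Per-egg draws (brightness, embryo placement, growth jitter)
  depend only on the egg's sample seed, so one egg is self-consistent
  across its five imaging days; noise streams additionally key on the day.
  Cohort sample seeds derive from the master seed via `SeedSequence`.

What the phantom does **not** emulate: eggshell scattering, the air cell,
yolk shadowing, blood-vessel trees, pigment chemistry, or any spatial
correlation in pore structure. Passing tests therefore demonstrate that
the *pipeline* recovers what was painted under realistic noise and
group structure — not that it would reach the same accuracies on
physical eggs.

## Calibration

`R = (R_o − R_d)/(R_t − R_d)` per pixel-band. Negative corrected values
(noise below dark) are clipped to 0 because transmittance is physically
non-negative and downstream thresholds assume it. The white board's
nominal 99 % transmittance is available as an optional multiplicative
scale, default off, so that the documented 0.125 mask threshold applies to
the unscaled ratio. A denominator ≤ 1e-9 raises, reporting the offending
pixel-band count. Arithmetic follows the reference-frame dtype (float32
frames stay float32; the modelled sensor noise is orders of magnitude
above float32 resolution).

## ROI and spectral feature

The ROI is the 1000 egg-mask pixels nearest the mask centroid, ties broken
by (row, col) — deterministic and shape-agnostic, in place of the manual
placement a human operator would do. The feature band defaults to the PCA
selection (below) and is configurable; the segmentation band (825 nm) is
kept independent of it, since on real instruments the two calibrations
need not coincide.

## Band selection

Covariance PCA (thin SVD of the centered pixel×band matrix; "variance
contribution" language implies covariance, not correlation, scaling).
Deterministic sign: each loading's largest-magnitude entry is positive.
Selection takes strict local extrema of the chosen loading curve
(endpoints eligible), ranked by |loading|. Default is per-image PCA on
egg-mask pixels; on phantoms whose only variance source is whole-pixel
amplitude (pore speckle with sensor noise off), PC1 is exactly the shell
spectral curve and the selected band is the configured peak — a structural
self-check the tests assert.

## Segmentation

Egg mask: strictly-greater threshold 0.125 at the 825 nm band, largest
8-connected component, holes filled (a strongly absorbing embryo can fall
below the global threshold; the mask must contain the whole egg).

Embryo: a pixel is embryo iff it is in the egg mask and its 825 nm value
is below the local mean minus an offset, where the local mean is computed
over egg-mask pixels only (uniform filter of the masked plane divided by
the mask coverage) in a square window. Defaults: window 51 px, offset
0.02, minimum component size 25 px (suppresses pore speckle), 8-
connectivity. After component filtering, interior holes are filled within
the egg mask: once an embryo outgrows the window, its deep interior sees
an embryo-dominated local mean and only the rim is detected; filling the
closed rim recovers the full region. Without this step the method's W
would saturate near the rim area for late-day embryos. The embryo is the
locally *dark* region — developed tissue absorbs; the output encoding
(white = embryo) is just a convention.

## LVQ2.1

* Architecture: `m = round(√(n+l) + a)`, rounding half up, offset
  a ∈ [1,10] with default 8 — the value at which a scalar feature and two
  classes give the canonical m = 10.
* Initialisation: codebooks allocated to classes proportionally to class
  frequency (each class ≥ 1, largest-remainder repair), placed at the
  class mean plus seeded jitter of 0.01 × per-dimension spread, so
  codebooks of one class can specialise.
* Training: classic LVQ2.1 paired update. Nearest and second-nearest
  codebooks; update only when they disagree in class, exactly one matches
  the sample, and the sample lies in the relative window
  `min(d_i,d_j)/max(d_i,d_j) > (1−w)/(1+w)` with w = 0.3 (the classical
  default). Correct codebook moves toward the sample, wrong one away, step
  = current learning rate. The rate decays linearly from 0.1 to 0 over
  `max_epochs` (default 100); training stops early when the training
  misclassification fraction ≤ 0.01 (the "training error" goal). Class
  assignments never change during training.
* Prediction: nearest codebook, Euclidean; ties to the lowest codebook
  index. Scalar inputs (n = 1) need no normalisation; multi-feature inputs
  are min-max scaled to [0,1] with training-set bounds stored on the model.

## Evaluation protocol

Per (feature, contrast, day): five independent cycles of stratified
per-group 2/3 (floor) / 1/3 split → init → train → test. Each run re-draws
both the split and the initialisation, so the run-to-run spread reflects
both variance sources; a fixed-split mode (`refresh_split=False`) isolates
initialisation variance. Accuracies are summarised as mean ± sample sd
(ddof = 1) and `cv = 100·s/μ` rounded half up to an integer — the
convention that reproduces every printed cv cell of the reference summary
tables bundled in `eggscan.published`. Report tables are TSV, one row per
day, accuracy cells as integer-percent `mean±sd`.

## Problem sizes

The analysis drivers use a 30-egg cohort on the `tiny` geometry
(44×80 px, 21 bands) as a fast worked example. The test suite's
end-to-end trend check runs the package defaults: 150 eggs (30 N / 60 D /
60 W) × 5 days on the half-scale 220×400 / 111-band frame, generated and
processed in memory (a written full-scale cohort would be tens of
gigabytes; nothing in the feature path needs the cubes on disk). Cohort
bookkeeping checks write real ENVI files on the `tiny` geometry, where the
record count — the quantity under test — is geometry-independent.

## Known limitations

* The adaptive-threshold parameters (window, offset, minimum size) are
  tuned to the phantom's contrast regime; real cubes will need their own
  values, which is why all three are arguments, not constants.
* The ROI is placed at the mask centroid; it does not avoid the air cell,
  whose position the phantom does not model.
* LVQ training error is evaluated once per epoch (not per update), so
  early stopping has epoch granularity.
* Only pairwise contrasts are supported by the evaluation pipeline;
  three-class joint classification is out of scope.
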