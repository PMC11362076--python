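# Methods

This note records the models and procedures `deshade` implements, the
defaults and why they were chosen, what the scene simulator does and does
not emulate, and the numerical conventions that matter for reproducing
results.

## Data model

A **SpectralCube** is a `(rows, cols, bands)` array of dimensionless
reflectance with a strictly increasing wavelength vector (nm). Loaders
reject values outside [0, 1.5] unless told otherwise and divide out a
header-declared scale factor. Band lookup is nearest-center within a
tolerance of one sampling interval (2.2 nm by default, matching a 400–1,000
nm imager with 2.2 nm sampling and ~6 nm optical resolution); ties break to
the lower wavelength.

**ROIs** are pixel windows centered on ground sampling points. The field
protocol this mirrors uses a 30×30 window (900 px ≈ 0.9 m × 0.9 m), which
is even-sized; the convention here is that for even sizes the nominal
center is the upper-left pixel of the central 2×2 block, so a 30×30 ROI at
(r, c) spans rows r−14…r+15. Windows crossing the image edge are clipped
and flagged. Simulation studies in this package use 29×29 ROIs (841 px,
odd, exactly centered) because the simulated plots are 64 px wide; this is
the 900-px protocol scaled to the synthetic plot geometry.

## Spectral pretreatments

Four treatments along the wavelength axis only (spatial neighbours never
mix): `OS` (identity), `GF` (Gaussian convolution, reflect boundary), `SG`
(Savitzky–Golay local least-squares polynomial), and `GFSG` (GF then SG,
in that order — the composition is not commutative and the order is part
of the method definition).

Defaults: `gf_sigma_bands = 2` (≈ 4.4 nm), `sg_window = 11`,
`sg_polyorder = 2`. Rationale: with 2.2 nm sampling against 6 nm optical
resolution the spectra are mildly oversampled, so smoothing kernels
narrower than the instrument response remove sensor noise without eroding
real absorption features. SG boundaries fit the polynomial to the edge
window and evaluate it outward, so polynomial inputs of degree ≤ 2 are
reproduced exactly everywhere — relevant because index bands near the grid
edge (415 nm) would otherwise be biased. Per-pixel smoothing before ROI
averaging is the default (a switch reverses the order); for linear
operators the two orders agree on unclipped windows, but class-restricted
means make the distinction real.

## Vegetation masking

K-means (default k = 3) on brightness-normalised spectra (each divided by
its mean), with deterministic initialisation: pixels are ordered by their
NIR(800)/red(670) ratio and centroids seeded at quantile-spaced positions,
`n_init = 1`, fixed seed. Normalisation is what lets shaded leaves — same
spectral shape, ~0.2–0.5× amplitude — cluster with sunlit leaves rather
than with dark soil. Clusters whose mean NIR/red ratio reaches half the
maximum cluster ratio are flagged vegetation; the red edge makes leaf
ratios ~5–10 against ~1.5 for soil, so the 0.5 fraction is an insensitive
threshold. A scene of identical pixels degrades to a warning and an
all-true mask.

## The green-level cascade

The discriminating feature is the green-band (550 nm) reflectance: leaf
shadows are much darker than sunlit canopy, and (dry, bright) soil plus
soil/leaf mixed edge pixels are brighter. Level schemes bin an observed
population into `n_levels = 10` classes; `equal_width` (default) spaces
edges evenly on [min, max] — levels are intervals of an intensity scale,
which naturally leaves the extreme classes sparsely populated — while
`quantile` equalises counts. Bins are half-open `[eᵢ, eᵢ₊₁)` with the last
closed so the maximum is always labelled.

Stage 1 fits the scheme on all masked pixels; classes {4, 5} are retained
by default (the mid-intensity canopy candidates). Stage 2 refits a fresh
10-level scheme on the retained pixels only and keeps classes {3, 4, 5}.
Scheme fitting is scene-global (one scheme per flight image), matching the
whole-scene class maps a practitioner inspects; per-ROI fitting is
available behind a flag. Labels print with a stage prefix (`1-4`, `2-3`).
The class-label numbering is 0-based throughout.

Both retention defaults are configurable. The package deliberately does
not implement edge-detection, RGB colour-index or supervised shadow
classifiers; the single-feature intensity cascade *is* the method.

## Vegetation indices

Twenty classical indices are registered with their printed band lists,
e.g. `GRVI = R800/R550`, `MTCI = (R754 − R709)/(R709 − R681)`,
`SAVI = 1.5(R800 − R670)/(R800 − R670 + 0.5)`. Conventions:

* The generic red/green/NIR anchors used by `R/G` and `MACI` are fixed to
  670/550/800 nm — the anchors the named-band indices already use — and
  are configurable via `make_registry`. Single bands, not band-region
  means, are used for `R/G`.
* `NDVI` is registered with its source's (810, 560) pair; the conventional
  (800, 670) pair is covered by `HNDVI` (827, 668).
* `MACI` with default anchors is numerically identical to `GRVI`; both are
  kept so tables carry the full registry.
* `GMI = (R750/R720) − 1` is implemented as printed.
* A vanishing denominator (e.g. MTCI when R709 = R681) produces a logged
  NaN missing marker, never an exception; rows with missing cells are
  dropped downstream.

Normalised-difference indices are bounded in [−1, 1] for non-negative
reflectance (IPVI in [0, 1]); all registered indices except SAVI are
invariant to positive scaling of the spectrum (SAVI's +0.5 soil term
breaks homogeneity by design). These are tested invariants.

## Association statistics

Pearson r with two-sided p from the t transform (n−2 df); stars `*`/`**`
at exactly 0.05/0.01. Correlation reports are long-format
(class, method, index, r, p, stars, n), ordered by |r|, with pairwise
deletion of missing rows and per-cell n. Across-sample standard error is
SD/√n per index column.

Group comparisons use one-way ANOVA plus pairwise post-hoc tests — Tukey's
HSD by default, Fisher's LSD (pooled-variance t, uncorrected) by flag —
rendered as a compact letter display via insert-and-absorb: start with one
column holding all groups; for every significant pair duplicate the
columns containing both and delete one member from each copy; absorb
duplicate/subset columns; assign letters in descending-mean order. The
output satisfies, and the tests verify, the defining property: two groups
share a letter iff the post-hoc test does not separate them.

Sensitive-index selection keeps indices with `p < alpha` (0.05) and
`|r| ≥ min_abs_r` (0.2) per class. No multiple-testing correction is
applied across the 20 indices by default (reports carry raw stars);
Benjamini–Hochberg can be layered on by the caller.

## Regression

Features are the sensitive (class, index) columns concatenated across the
retained classes (`concat`), or a seeded random subset. Rows with any
missing cell are dropped. MLR runs on raw features (OLS is
scale-equivariant); PCR, PLSR and SVMR standardise inside their pipelines;
the feature matrix records the per-column standardisation parameters.

* **MLR** — ordinary least squares; requires more training rows than
  features, otherwise it errors and points at PCR/PLSR.
* **PCR** — standardise → PCA → OLS, component count 1…10 by 5-fold CV.
* **PLSR** — NIPALS partial least squares, components by 5-fold CV.
* **SVMR** — RBF kernel, grid CV over C ∈ {1, 10, 100},
  γ ∈ {scale, 0.01, 0.1}, ε ∈ {0.01, 0.1, 0.5}.

Evaluation is on a held-out split: seeded 70/30 shuffle (with ~108-sample
cohorts a single split is noisy, so the split seed is part of every
report). Metrics: R² = 1 − SS_res/SS_tot (never clamped), RMSE, MAE, in
LNC units. All fitters are deterministic given (features, seed, grid).

## The scene simulator

The simulator emulates the *structure* of a nitrogen-rate field trial,
not radiative transfer:

* **Trial layout** — 18 plots (3 × 6, 64 px each) cycling through 5
  fertiliser levels; per-plot LNC on a gradient spanning 25–55 g·kg⁻¹ with
  replicate jitter (σ = 1) plus a smooth within-plot field (σ = 1.2);
  6 sampling points per plot snapped to sunlit canopy → 108 samples whose
  recorded LNC adds assay noise (σ = 0.3 g·kg⁻¹).
* **Leaf optics** — reflectance is a per-band convex blend of two smooth
  endmember spectra (nitrogen-poor and nitrogen-rich leaves, monotone
  spline through anchor wavelengths). Nitrogen-rich leaves are darker in
  the green, have deeper 450/670 nm absorption wells, a lower NIR plateau
  and a lower, right-shifted red edge — so green reflectance decreases
  monotonically with LNC and ratio/normalised indices co-vary with it in
  the directions observed in the field (e.g. GRVI negatively).
* **Imperfect nitrogen coupling** — the pigment state driving the visible
  bands and the structure state driving the NIR each equal the local
  nitrogen level plus independent smooth confounder fields (σ = 0.18 of
  the normalised LNC range). Real leaf spectra track nitrogen only through
  chlorophyll and structure, so no single index is a clean nitrogen probe;
  this is what puts single-index correlations in a realistic 0.3–0.9 band
  and held-out SVMR R² near 0.86 instead of 1.0.
* **Canopy geometry** — clumped canopy blobs cover 65% of each plot
  (matching the ~66/34 vegetation/soil split of a mid-season flight
  scene); 30% of canopy pixels are shaded, in clumps.
* **Shadows** — multiplicative attenuation, per-pixel factor U(0.2, 0.5),
  with extra NIR attenuation U(0.05, 0.30) ramped in along the red edge
  (shade light is relatively blue-green rich). The helper
  `leaf_spectrum(..., shaded=True)` uses the 0.15 midpoint tilt.
* **Soil** — a bright, monotone dry-soil ramp (0.20 at 400 nm → 0.52 at
  1,000 nm, no red edge) with spatially clumped brightness (±15%) and
  colour-tilt fields: soil moisture and roughness vary in patches, so the
  soil contamination entering different ROIs differs in more than one
  dimension. The brightness level is a deliberate design choice: the
  green-intensity cascade can only shed soil that is *brighter* than the
  canopy at 550 nm, which is the regime (dry bright soils, vigorous
  canopy) in which this method is applicable. A 2-px collar of soil
  pixels around canopy blobs carries mixed soil/leaf spectra
  (α ∈ U(0.2, 0.85) leaf fraction; truth label stays soil) — the
  realistic contamination path into the vegetation mask.
* **Sensor** — i.i.d. Gaussian noise per band (σ = 0.008 reflectance);
  output clipped to [0.001, 1.4].

Everything is drawn from one `numpy` generator seeded by `SceneConfig.seed`,
so scenes are bit-reproducible.

**What the simulator does not emulate** — and hence what passing tests do
*not* show about real data: no BRDF or sun-geometry ray casting, no
radiative-transfer leaf model (PROSPECT-class), no atmospheric or
georeferencing effects, no within-leaf specular variation, no correlated
(striping) sensor noise, and the nitrogen–spectrum link is linear by
construction. The simulation results demonstrate that the pipeline
recovers signal under the stated contamination model, not that the method
attains any particular accuracy in the field.

## The de-interference study

`deshade.study.recovery_study` runs the full stack on (default) 20 seeded
scenes and records, per scene:

* soil and shadow fractions among the vegetation mask, the stage-1
  retained set ({4, 5}) and the stage-2 retained set ({3, 4, 5}) — the
  cascade is judged by these fractions falling;
* the number of the 20 indices whose |r| with LNC is higher for ROI means
  restricted to the retained stage-2 classes than for ROI means over all
  vegetation-mask pixels (GF&SG pretreatment, 29×29 ROIs);
* held-out R² for MLR/PCR/PLSR/SVMR on (a) sensitive features of the three
  retained classes combined, vs (b) sensitive features of the plain
  unclassified ROI mean — the no-classification workflow, i.e. the first
  of the two ROI types (raw window mean) rather than the post-
  classification mean.

Under the default conditions the cascade removes essentially all soil and
shadow (≈36% → ≈0.2% of retained pixels), improves |r| for a median ~17 of
20 indices, and the classified-feature models beat the all-pixel models in
roughly three quarters of replicates for PCR/PLSR/SVMR. MLR is the
exception by construction: the combined sensitive features (~50 columns
against ~76 training rows) overfit unregularised least squares, which is
exactly why the package points MLR users at PCR/PLSR for wide feature
sets.

Problem sizes were chosen to keep a full study inside a few minutes on one
CPU: 192×384 px scenes × 270 bands, 20 replicates, and the small CV grids
listed above.

## Numerical conventions and degenerate inputs

* Coordinates are 0-based, row-major (row, col); cubes are (row, col, band).
* Equal-width level fitting on a constant population is an error (the scale
  is undefined); quantile fitting requires ≥ n distinct values.
* Empty masks, empty retained sets and samples whose ROI lacks a class are
  errors, errors, and logged row drops respectively — the distinction is
  deliberate: a missing class in one ROI is expected under heavy
  contamination, an empty scene-level selection is a configuration fault.
* Pipeline CSV/JSON outputs are byte-deterministic under a fixed config
  and seed; the manifest stores SHA-256 hashes so reruns can be compared.

## Known limitations

* The equal-width scheme ties level boundaries to the observed min/max, so
  a single outlier pixel stretches the scale; masking ahead of the cascade
  is what keeps this benign in practice.
* Retention sets {4, 5} / {3, 4, 5} are fixed defaults, not data-driven;
  an auto mode maximising the count of LNC-significant indices is a
  natural extension.
* With ~108 samples and plot-level nitrogen, train/test splits share
  plots; reported R² is a within-scene quantity, not an across-site
  generalisation estimate.
* LNC units are g·kg⁻¹ by declaration; nothing in the pipeline can verify
  the unit of a user-supplied sample table.
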