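# Methods

`lhamap` implements a quantitative pipeline for mapping neurons that
project to the lateral hypothalamic area (LHA), as labeled by a retrograde
tracer: serial coronal sections are registered to an atlas, parcellated
into per-region crops, neurons are counted by density regression, counts
are quality-controlled, normalized, and compared between genotypes.
Because no imaging data are publicly deposited for this kind of
experiment, the package ships a synthetic-data module that emulates the
statistical structure the analysis assumes and provides exact ground
truth; every quantitative claim the test suite makes is therefore a claim
about recoverability under that generative model, not about any particular
real dataset.

## Atlas model

The packaged toy atlas (`data/toy_atlas.json`, schema version 1) carries 8
coronal plates from AP +2.6 to −3.0 mm and ~21 leaf regions as simple
polygons (mirrored across the midline) inside an elliptical section
outline, plus a small region ontology with two pooled labels
(`ORBl/vl+AI`, `PL+ORBm`). Identities and rough topology follow the mouse
forebrain (orbital/insular and medial prefrontal cortex rostrally,
amygdala and hypothalamus caudally, zona incerta dorsal to the LHA);
geometric realism is deliberately not attempted, and no real reference
atlas data are redistributed. The LHA polygons are sized so that the
bilateral LHA volume measured on the 70-µm section grid is 2.75 mm³ — the
wild-type reference volume used for atrophy compensation.

Conventions: atlas coordinates in mm, x rightward, y dorsal; AP relative
to bregma; pixel space 0-based row-major. A pixel belongs to a region iff
its center lies inside the polygon; blobs (somata) belong to the region
containing their centroid. Points exactly on the midline are assigned
"ipsi" (deterministic tie-break).

Each plate carries six outline landmarks plus one centroid landmark per
region present. The centroid landmarks matter: outline-only constellations
on neighbouring plates differ by a nearly affine map, so an affine
landmark fit cannot tell plates apart; the internal region constellation
breaks that degeneracy. Plate assignment considers a plate only when all
its landmark names were found on the section, minimizes the RMS landmark
residual, and breaks exact ties to the more anterior plate.

## Synthetic cohorts

`CohortDesign` defaults are the study conditions:

* ~50,000 labeled neurons per WT brain in expectation, realized per
  region×section×hemisphere as Poisson draws (an optional
  negative-binomial dispersion knob exists for power studies);
* contralateral fraction 0.2 (≈40,000 ipsi vs 10,000 contra);
* per-region relative densities (`DEFAULT_REGION_WEIGHTS`) chosen once to
  put the largest projections in limbic/prefrontal areas; absolute
  densities are rescaled at design construction so the expected WT total
  hits the target — no per-region reference densities exist for this kind
  of experiment, so only the total and the hemispheric split are
  calibrated;
* disease effects: multiplicative 1.8× on ORBl, ORBvl and AI counts and a
  0.75 LHA volume scale for the mSOD1 genotype;
* rendering at 5 µm/px: somata as isotropic Gaussian blobs (σ 1–2 px,
  amplitude 300–600 over a background of mean 100, white noise σ 8, and a
  smooth autofluorescence field σ 15), curvilinear dendrite artifacts
  (~0.7 per 64×64 tile, amplitude 120–250), 16-bit output;
* an injection deposit rendered as a saturating (amplitude 6000) oblate
  ellipsoid centered in the LHA with vertical semi-axis 0.28 mm (so a
  well-placed deposit stays ventral of the LHA dorsal border), default
  volume 0.45 mm³, plus an optional spherical backflow deposit placed
  fully dorsal to the LHA whose volume fraction equals the configured
  backflow.

Atrophy is polygon scaling about the region centroid (linear factor √s for
a volume scale s), affecting the rendered area, the soma placement, and
the truth volume. Sections additionally carry landmark observations of the
(possibly atrophied) LHA polygon corners, so a thin-plate-spline warp can
recover the local deformation; with a global affine warp, atrophy is
invisible by construction.

Seeding is hierarchical (cohort → brain → section), so any single brain
regenerates bit-identically without its cohort.

**Scale coupling.** The soma appearance model is calibrated at 5 µm/px.
When rendering coarser (tests and demos use 20–40 µm/px), the brain total
must be scaled by `(0.005 / pixel_size)²` to keep the per-pixel soma
density — and hence counting difficulty and the injection/soma intensity
separation — at the calibrated level; `PipelineConfig.demo` does this
automatically and scales the low-label QC threshold accordingly. Packing
the full 50,000 somata into coarse pixels makes overlapping blobs sum
above the injection plateau and is not a meaningful regime.

What the generator does **not** emulate: realistic tissue texture,
staining gradients across sections, sectioning tilt or damage, capillary
tracks, double-counting of somata spanning adjacent 70-µm sections, or
brainstem anatomy. Passing tests therefore demonstrate the internal
consistency and calibration of the analysis chain, not robustness to
histological artifacts absent from the model.

## Registration and parcellation

Warps are fitted by least squares from named landmark correspondences:
forward (section→atlas) and backward (atlas→section) are fitted
independently on the reversed correspondence, never numerically inverted.
Models: similarity (≥2 pairs), affine (default, ≥3 non-collinear pairs),
thin-plate spline (≥4). The pipeline default is the spline because LHA
atrophy is a local deformation; the reported residual is the RMS backward
error in px. Parcellation rasterizes each region polygon through the
backward warp (pixel-center rule, so same-hemisphere crops are exactly
disjoint), pads crops by 8 px of context but zeroes pixels outside the
region, and codes each crop `<brain>_<section>_<region>_<hemisphere>`.

## Segmentation and counting

Both classifiers share one feature bank: Gaussian smoothing, Laplacian of
Gaussian, gradient magnitude, difference of Gaussians (pair σ, 1.6σ),
structure-tensor eigenvalues (derivative scale σ/2, integration scale σ)
and Hessian eigenvalues (sorted descending), each at σ ∈ {1.0, 1.6, 3.5,
5.0} px — 32 channels. All filters use reflect boundary handling.

Pixel classification uses a 100-tree random forest trained on sparse
foreground/background strokes; segmentation thresholds the foreground
probability at 0.5, and empty masks are flagged so downstream stages can
drop regions without labeled somata. (The forest size and threshold are
package decisions; only the counting forest's hyperparameters are fixed
by the protocol being reproduced.)

Density counting trains a random regression forest (20 trees, max depth
80, `max_features = 0.33`, minimum leaf size 2) to predict a per-pixel
density whose target is a sum of unit-mass Gaussians (σ_dot = 2 px ≈ soma
radius) at the dot annotations, with border-truncated kernels renormalized
so the target integrates exactly to the dot count. Training pixels are
subsampled per image — every pixel with target density above 10⁻³ plus 800
random background pixels, capped at 20,000 — to keep desk-scale runtimes;
prediction is always full-resolution. Predictions are clipped at 0 before
integration (forests can emit small negatives). The count of a crop is
the integral of clipped density over its (optionally
segmentation-restricted) mask, which makes counts exactly additive over
disjoint masks.

**Accuracy definition.** The protocol being reproduced never defines its
accuracy percentage; this package uses the complement of the mean relative
count error, `100·(1 − mean_i |ĉ_i − c_i| / max(c_i, 1))`, floored at 0,
with the `max(c,1)` guard handling neuron-free tiles. Whether a mean or
median, per-image or pooled definition was originally intended is unknown;
this choice is applied uniformly.

## Quantification and QC

Region volumes are summed crop areas × 70 µm. The injection site is
delineated by thresholding at 0.5× the 99.99th-percentile stack intensity
(a robust maximum; the reproducible analogue of manual delineation at a
fixed contrast), keeping connected components ≥ 20 px; its volume is the
summed cross-section area × thickness, the backflow fraction is the volume
fraction of suprathreshold tissue dorsal of the LHA dorsal border (via the
forward warp), and the centroid region is the atlas lookup of the largest
component's center. A brain is excluded iff (strict inequalities as
printed): injection volume > 1 mm³; centroid outside the LHA
("mislocalized" is operationalized this way because the original criterion
is qualitative); backflow > 10%; or total labeled neurons < 25,000.

The injection target region itself is dropped from projection count
tables (its "counts" are the saturated deposit, not projecting somata);
its volume is kept for atrophy compensation.

Region selection pools `ORBl/ORBvl/AI` and `PL/ORBm`, drops areas whose
WT cohort-mean count (both hemispheres) is below 100, and keeps the top
k = 28 by WT mean with ties broken by region id. In the experimental
workflow this pipeline reproduces, the 28-area list was fixed once from
the measured data (the selected areas jointly carrying about half of the
total projections); deriving the list by rank from the reference cohort
is this package's explicit, deterministic reinterpretation.

## Normalization and statistics

* 50 k normalization: per-brain counts divided by the brain total and
  rescaled to 50,000 (sums to 50,000 exactly).
* LHA atrophy compensation multiplies counts by (LHA volume / 2.75 mm³),
  the literal reading of the source protocol, although a per-volume
  ("neurons per mm³") interpretation would divide by the ratio instead;
  `mode="density"` exposes the reciprocal without endorsing it.
  Composing the literal compensation
  with 50 k normalization is a no-op (the ratio cancels), which the tests
  assert.
* Two-way fixed-effects ANOVA (genotype × structure, with interaction,
  Type-II sums of squares via statsmodels OLS — for the balanced layouts
  used here this coincides with the classical decomposition, and residual
  df = N − cells; 2 genotypes × 28 structures × 3 brains gives df = 112).
  Per-structure genotype comparisons mirror common graphing-software
  practice: t = Δmean/√(MS_res·(1/n₁+1/n₂)) on the pooled residual MS with
  residual df, Sidak-adjusted `p' = 1 − (1 − p)^m` over the structure
  family. Degenerate layouts (zero residual variance with zero effect) are
  reported as F = 0, p = 1 rather than NaN.
* Pooled-variance Student t-tests from raw data or summary statistics
  (df = n₁+n₂−2); one-way ANOVA with Tukey's HSD (scipy's studentized
  range).

**Calibration.** Family-wise error control is verified by simulating null
cohorts (no genotype effect, 28 structures with a geometric mean-count
profile summing to 25,000, n = 3) under the ANOVA's own error model:
i.i.d. Gaussian errors with variance equal to the mean structure mean
(the average Poisson variance). 500 such cohorts give a family-wise
false-positive rate of ~4–5%, within the nominal band; power for a 1.8×
expansion of the pooled orbital/insular structure at n = 6 is ~100% with
off-target rates at the nominal level. Under mean-dependent Poisson noise
instead, the pooled-variance post-hoc is structurally anticonservative
for the largest structures (measured FWER ≈ 0.19 at the same settings;
see `analysis/04_statistics_calibration.py`) — a known limitation of the
pooled-MS construction this package reproduces, not a defect of the
implementation; real analyses relying on it should interpret borderline
post-hoc p-values in large structures cautiously.

## Burden scoring

Burden = area fraction surviving: rolling-ball background subtraction
(radius 20 px, via the exact rolling-ball envelope; output clipped at 0)
→ 256-bin histogram → Rényi-entropy threshold → pixels strictly above
threshold. The threshold combines the entropy-maximizing thresholds at
orders α→1 (Shannon/Kapur limit), ½ and 2 with the order-dependent
weighting rule of Sahoo, Wilkins & Yeager (1997); each component is an
exhaustive search over the 255 candidate thresholds with plateau ties
resolved to the middle candidate, and equivalence with any specific legacy
plugin is not claimed. The source protocol describes thresholding first
and background subtraction second, which is backwards relative to
standard practice; the package subtracts background first and exposes
`literal_order=True` for the literal order. On synthetic burden images the pipeline over-estimates the
true area fraction by ~0.02–0.05 (the entropy threshold sits below half
the foreground amplitude), which cancels in group comparisons; the burden
generator renders hard-edged foreground so its truth mask is exactly the
rendered object support.

## Problem sizes used by the tests

The suite exercises the full chain at sizes chosen for a single desktop
CPU: counting benchmarks use 64×64 tiles (350 per seed, 3 seeds) at the
calibrated 5 µm/px appearance; whole-brain tests render at 20–40 µm/px
with count-scaled totals; the end-to-end pipeline test runs 2 brains per
genotype over a caudal AP window; volume/QC round-trips use truth-only
(unrendered) brains where pixels are irrelevant. The statistical
calibration runs 500 null and 100 effect cohorts at the count level.
`analysis/` drivers run the same code at moderately larger sizes.

## Known limitations

* The toy atlas has ~20 regions, so the "top-28" selection rule is
  exercised at full breadth only on count-level simulations; image-level
  cohorts select from the regions the atlas has.
* Counting accuracy is measured against the generator's appearance model;
  no claim is made about transfer to real micrographs or other pixel
  scales without retraining.
* The pooled-variance Sidak post-hoc is anticonservative under
  mean-dependent count noise (above).
* Somata spanning adjacent sections are not de-duplicated (the per-section
  counting convention is reproduced as-is).
* An unbalanced-design residual df such as 1,166 cannot arise from the
  balanced layouts implemented here; Type-II SS with the fitted layout's
  residual df is used for any unbalanced input.
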