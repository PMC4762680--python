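# Methods

This note records the models, defaults and numerical choices behind
`drusenkit`, and what the synthetic validation does and does not
demonstrate about real fundus photographs.

## Image model and coordinates

Images are 2-D float rasters with a µm-per-pixel scale and a fovea
coordinate; pixels are 0-based `(row, col)` with centers on integer
coordinates and distances measured center-to-center. Color photographs
are reduced to the green channel before analysis (the red-free equivalent,
which carries drusen contrast); the channel is configurable. Intensities
stay floating-point internally and are quantized to 8- or 16-bit only on
export, so leveling and thresholding are not confounded by quantization.

## Background leveling

The illumination/reflectance background is fitted by quadratic
polynomials `[1, x, y, x², xy, y²]` in concentric annular zones centered
on the fovea (default 3 zones of equal radial width covering the field;
configurable to 1). Coordinates are centered on the fovea and scaled by
half the raster size so the normal equations stay well conditioned; a
single-zone fit is algebraically identical to a global least-squares
quadratic (asserted to 1e-9 against a direct normal-equations solve).

Zone surfaces are joined by a cubic Hermite cross-fade (`3t² − 2t³`) along
the radial coordinate over a blending band, by default 10% of the field
radius. The interpolation variable (radius) and the zone geometry are
design choices: macular reflectance is approximately radially structured
around the fovea, and a radial cross-fade guarantees a continuous surface
by construction.

Background pixels feeding the fit are the at-or-below-Otsu class of the
region's histogram. The one-call `level()` helper selects background
per zone by default: a bright reflectance dome near the fovea can
otherwise be classified wholesale as foreground by a single global
threshold. The fit is one-pass (no iterative reweighting); leveling
subtracts the surface and restores the surface mean so typical
intensities stay non-negative and druse contrast is preserved exactly.

Pixels under a druse's photometric footprint bias the fit upward if
included; the supervised workflow avoids this because operator ROIs mark
drusen-containing areas, and the tests exclude a dilated footprint when
asserting surface accuracy.

## Segmentation

Within the effective ROI (drusen ROI minus reticular and GA exclusions)
the leveled image is smoothed with a 1-px Gaussian — the enhancement step;
set `smooth_sigma=0` to disable — and thresholded once with Otsu's method.
A single global threshold per image is deliberate: spatial
nonstationarity is the leveling stage's job. Foreground pixels form
8-connected components; components under `min_druse_px` (default 4 px)
are dropped as noise. Areas are pixel counts times the squared scale;
equivalent diameter is `2·√(area/π)`; size classes use half-open bands
[0, 63), [63, 125), [125, ∞) µm — the conventional small / intermediate /
large bands leave the boundary values unassigned, and assigning them
upward keeps the bands half-open and exhaustive.

## Quantification

The grading template's subfield radii are 500, 1500 and 3000 µm (circle
diameters 1000/3000/6000 µm). Each druse goes entirely to the subfield
containing its centroid, keeping drusen number additive across subfields;
drusen centered beyond 3000 µm are excluded from every field. "Total
drusen diameter" is the sum of the equivalent-circle diameters of the
subfield's drusen: an additive, µm-scaled burden measure computable from
segmented areas without caliper measurement.

## Registration

The similarity estimator searches rotation (±6°, 1° grid) × log-scale
(±0.06, 5 points); at each candidate the translation is resolved in
closed form by upsampled phase correlation (phase normalization, Hann
window) and the candidate scored by the normalized cross-correlation of
the aligned images; a Nelder–Mead polish over (rotation, log-scale)
follows, then a final translation resolution at 1/100-px upsampling. The
procedure is deterministic, needs no keypoints, and on the default
synthetic pairs (rotation ≤ 5°, translation ≤ 20 px, scale within 5%)
recovers transforms with mean corner-landmark error ≈ 0.3 px (contract:
≤ 1 px). A descriptor-matching design was considered and rejected for
this image class: smooth blob scenes with independent per-visit noise
give unstable keypoints, while the global intensity search is stable.
When the aligned images correlate below a floor (default 0.2), the
estimator raises and recommends the manual fovea-pair fallback (pure
translation aligning operator-marked foveae). The affine family refines
the similarity solution with least squares on block-matching
correspondences.

Intensity rasters are warped with bilinear interpolation (out-of-field =
NaN), masks with nearest-neighbor so they stay binary.

In the per-subject pipeline, each visit is segmented in its own frame and
the registration instead carries the template: the final visit's template
center is the baseline fovea mapped through the estimated transform and
its µm/px scale absorbs the estimated magnification. Segmenting a warped
image would inflate druse areas through interpolation smoothing; only
binary GA masks are warped (for the overlap intersection), where a
boundary-pixel error is immaterial.

## Remodeling and GA accounting

Remodeling is the cellwise difference `D1 − D0` of the 12 metric ×
subfield cells; antisymmetry and subfield additivity hold exactly. GA
accounting intersects the registered baseline drusen mask with the final
GA mask; percentages are reported unrounded and rounded to the nearest
integer. A GA area of zero leaves "percent of GA" missing, not zero. The
cohort summary's headline numbers are means of per-subject percentages
(the pooled-pixel ratios are also returned): per-subject averaging treats
eyes, not pixels, as the unit of analysis.

## Trial statistics

Drusen characteristics are transformed by `log(Y + c)` with c = 1 before
t-tests; c = 1 keeps the many zero-drusen baseline cells finite and is
configurable. The two-sample t is the classical pooled-variance Student
form (Welch is not used); the chi-square has no continuity correction;
the paired t acts on log-scale differences within each arm separately;
treatment effects come from OLS of each remodeling cell on an arm
indicator, age, and a gender indicator (reference levels: placebo, male),
reporting the arm coefficient with a t-based 95% CI. Age uses the Pearson
correlation with the t-distributed test and a Fisher-z CI; genotypes are
unordered 3-level factors analyzed by one-way ANOVA. Significance is
flagged at p < 0.005 for the 12 planned comparisons; the exact 0.05/12 ≈
0.00417 flag is reported alongside. Degenerate inputs (zero variances,
empty groups, rank-deficient designs, single-arm cohorts) raise
descriptive errors; the study driver records them per-analysis and
continues. Missing genotypes are dropped per analysis.

A note on small-sample chi-square: on tables with n ≲ 12 the exact
permutation law of the statistic is discrete and its tail probability can
differ several-fold from the asymptotic chi-square p. The test suite
therefore checks the statistic against the hand formula and that the
asymptotic p ranks tables consistently with an exhaustive permutation
oracle, rather than demanding numeric agreement no asymptotic test can
deliver at that n.

## Synthetic data: what it emulates, and what it does not

Images are a zoned-quadratic background (optionally vignetted) plus
additive druse bumps plus i.i.d. Gaussian pixel noise, rendered
analytically in both visit frames so serial pairs are exactly related by
the stated similarity transform. A druse is an elliptical super-Gaussian
bump `A·exp(−ln2·ρ⁴)`: the profile has the plateau-and-shoulder shape of
a soft drusen deposit and equals half its peak exactly on the stated
ellipse, so the ground-truth support (the half-maximum set) is the
ellipse and its area is `π·a·b` analytically. A pure Gaussian profile was
considered and rejected: its `1/I` intensity tail makes the half-maximum
area hypersensitive to the threshold (area ∝ log₂(A/T)), which no single
global threshold can track across drusen of different brightness; the
plateau profile matches both the biology and the method's operating
assumptions. Geographic atrophy is a uniform-contrast disk at the final
visit; reticular regions are operator-style polygons.

The default segmentation conditions are 20 images at 25 µm/px with 6–11
drusen of 100–250 µm semi-axes, noise sd 3, and per-image druse contrast
drawn from 20–40 intensity units (±15% within an image) — drusen in one
photograph share material and illumination, so near-uniform within-image
brightness is the realistic regime, and every contrast is comfortably
above 3× the noise sd. Supervision is emulated by dilating the true
drusen support (`operator_roi`, default 10 px), mirroring the operator's
generous circling of drusen-containing areas. Mean Dice against ground
truth is ≈ 0.93 under these conditions (contract ≥ 0.80). Passing these
tests shows the pipeline recovers known truth under its stated
assumptions; it does not certify performance on real photographs with
vessels, optic disc, media opacity or non-additive reflectance — none of
which are rendered.

Cohorts emulate a 167-subject two-arm trial: 1:1 Bernoulli allocation,
age ~ N(73.6, 6.8²), 61.7% women, 43.1% ever-smokers, genotype
frequencies CFH (0.29, 0.47, 0.24) and ARMS2 (0.31, 0.46, 0.23) drawn as
independent multinomials (genotype counts are what the analysis consumes,
so Hardy–Weinberg structure is not enforced). Baseline drusen metrics are
log-normal around per-cell medians matching a cohort of this kind;
3-year changes are Gaussian residuals (per-cell SDs on the scale of the
trial's reported change SDs) plus additive effects: the age–inner-diameter
correlation (default −0.17, built by mixing the standardized age into the
inner-diameter residual), a mean shift for women (−40 µm) and for CFH TT
(+55 µm) on the inner diameter, and a treatment shift (default 0) on all
cells. The `all` field is the sum of the three subfields by construction.
Final = baseline + change, so a large negative change can produce a
negative final value in rare draws; the study driver clips at zero before
log-scale paired tests.

## Problem sizes and determinism

The validation suites are sized for a single CPU: 20 images of 160² px
for segmentation, 6 pairs of 256² px for registration, 500 null cohorts ×
12 regressions for the false-positive rate, 200 cohorts for correlation
recovery, and a 3-subject image study run twice for byte-identical
reproducibility. All randomness flows from explicit seeds through
`numpy.random.default_rng`; the registration optimizer, the solvers and
the CSV/JSON writers are deterministic, and the run log contains the
configuration hash and seed of every study run.

## Known limitations

- No vessels, optic disc, exudates or media opacity in synthetic images;
  reticular pseudodrusen are excluded by operator regions, never
  segmented.
- The registration contract covers modest similarity transforms typical
  of seated serial photography, not large re-fixations or nonrigid
  distortion.
- The Otsu threshold sits slightly below the half-maximum level when
  background dominates a supervised region; tight operator circling is
  assumed, as in practice.
- Drusen that merge or split between visits change the component count in
  ways D1−D0 on counts cannot attribute; area and diameter remain
  meaningful.
- CNV detection and SD-OCT drusen volume are out of scope.
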