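# Methods

This note records the model behind each pipeline stage, the parameters that
matter, the design choices made where the method description left the design
open, and what the phantom-based validation does and does not establish.

## Problem setting and assumptions

The pipeline classifies postmenopausal subjects into normal / osteopenia /
osteoporosis from two grayscale ROI crops (nominally 128×128, 8-bit) taken
below the left and right mental foramen of a panoramic radiograph. It
assumes each ROI shows one bright, roughly horizontal cortical band crossing
the crop, trabecular texture above it, and darker tissue below; it does not
model teeth, the mental foramen itself, or hyoid superimposition. ROI
placement is upstream of the package: inputs are pre-cropped images or
explicit crop coordinates. Coordinates are 0-based `(row, col)` with row 0
at the top; left ROIs are not mirrored (the pipeline is
orientation-agnostic per side).

## Line-operator enhancement

The line operator scores pixel p as
`max over orientations of (mean gray on the length-l line through p) −
(mean gray of the N×N square around p)`,
with l = 5 px, 12 orientations (15° steps), N = 5, and image borders
reflected. The score is invariant to adding a constant gray offset and, for
orientation counts divisible by 4, equivariant to quarter-turn rotations —
line segments are rasterized with offsets snapped to 9 decimals before
rounding so that exact half-integer offsets (cos 60° and friends) round
identically at 90°-paired angles, keeping the kernel set closed under
rotation.

The operator runs on a Gaussian pyramid (default 4 levels; capped at
⌊log₂ min(h,w)⌋ − 2 for small images). **Per-level normalization before
fusion** is a deliberate choice: each level's response is clamped at zero
(dark lines are noise for this task — cortical bone is bright) and divided
by its own maximum before bilinear upsampling and pixelwise-max fusion.
Without it, the sharp fine-scale edge responses dominate a single global
normalization and the interior of a 20–40 px band — which only responds at
coarse scales — is left indistinguishable from background, which in turn
starves the segmentation stage. With it, the enhanced image
(ROI × response) shows the full band at high intensity.

## Statistical region merging

*Initial partition.* Watershed on the Sobel gradient magnitude, with
markers from the h-minima transform at depth `gradient_threshold`
(default 10 gray levels): gradient minima shallower than the threshold do
not seed regions, which merges texture-induced shards. Every region is
4-connected and carries area, mean gray and centroid.

*Seeds.* Object candidates are the `top_k` (default 5) regions with the
best rank-sum of the area and mean-gray orderings; the object seed is the
candidate nearest the image center — the anatomy guarantees the band runs
through the ROI center. The background seed has the lowest mean gray among
regions whose centroid is farther from the center than the median centroid
distance (ties: smaller area, then smaller id).

*Merging.* Unlabeled regions merge one at a time into the class (object or
background) minimizing |region mean − class mean|, the class mean being
area-weighted and updated after every merge; ties resolve to the lowest
region id. Merging is **not** restricted to regions spatially adjacent to a
labeled class. An adjacency restriction looks attractive for mask
coherence, but the band typically crosses the entire ROI and seals the zone
beneath it off from a background seed placed above it; under an adjacency
rule that zone can only ever join the object class, which misclassifies
roughly half the image. Spatial coherence is instead restored afterwards:
the mask is the largest 4-connected component of the object class, with
holes up to 10 px² filled.

The distance statistic (absolute difference of area-weighted mean grays) is
the simplest choice consistent with a region-merging scheme driven by
region statistics; it is exposed in the module so alternatives can be
swapped in.

## Width morphometry

The upper border (topmost mask pixel per column) is fitted by least squares
with `row = poly(col)` for candidate degrees 1–5; the selected degree
minimizes 5-fold cross-validated squared error (folds assigned by column
order, fixed), since raw SSE alone always prefers the highest degree.
Near-ties within float noise resolve to the lower degree, so an exactly
polynomial border recovers its true degree.

Widths are sampled every 1 px across the central 80% of the fitted domain
(10% margin per side, where border fits are least stable). At each sample
the tangent is the polynomial's analytic derivative and the width is the
distance marched from the border point along the inward unit normal, in
0.25 px steps with nearest-neighbor mask lookups, until the mask is left.
A half-pixel correction (+0.5 − step/2) accounts for the march starting at
the top pixel's center and overshooting the exit by half a step on average;
without it, widths are biased low by ~0.5 px, which matters at 5% tolerance
on a 10 px band. Samples starting on background or exiting the image are
skipped; fewer than 3 surviving samples is an error. On rasterized bands
rotated 0–40° with thickness 10–30 px the recovered average width is within
2.8% of the true perpendicular thickness, whereas column height errs by
1/cos θ (15.5% at 30°).

`measure_side` fills enclosed holes in the mask before fitting and
marching: intracortical pores sit inside the band, and letting them
terminate the march would report a pore depth instead of the band
thickness (observed as a collapse of the minimum-width feature on porous
phantoms). Widths are reported in pixels; an optional px→mm factor is
config-only and off by default.

## Texture

Each ROI is normalized by the affine map sending its 1st/99th intensity
percentiles to 0/255 (clipped), making images with different illumination
comparable; constant images map to the midpoint by convention. The texture
feature is the mean normalized gray over the cortical mask, with enclosed
holes filled for the same reason as in morphometry: the pores *are* the
porosity signal, and a segmentation that excises them would bias the mean
upward exactly for the most porous bone. Note that percentile anchoring
deliberately removes per-image brightness differences, so the class signal
carried by this feature is porosity (dark pixel fraction), not absolute
band brightness.

## Classification

Features are the canonical 8-vector (r_min, r_max, r_avg, l_min, l_max,
l_avg widths; r, l textures). The classifier is a one-vs-one RBF-SVM on
standardized features. Evaluation uses stratified k-fold CV (k ∈ {2, 3, 5,
10}) with a seeded shuffle; per outer fold, standardization and a grid
search over C ∈ {0.1, 1, 10, 100} and γ ∈ {0.001, 0.01, 0.1, 1} (inner
3-fold accuracy) see only the training split, so no statistics leak from
the held-out fold. Stratification protects the 17-member osteoporosis class
at k = 10. Printed accuracies round half-up to two decimals, matching how
such tables are conventionally printed.

## Phantom generator

Each record is a left/right ROI pair with ground truth. Per side: the band
width is drawn from the class/side distribution of the published per-class
feature table (normal right 27.7 ± 6.4 px, … osteoporosis left
21.6 ± 4.4 px), truncated at 5 px; the upper border is a mild random
quadratic (|slope| ≤ 0.08 at center, curvature ≤ 0.0015), and the band of
constant perpendicular thickness is rendered beneath it, so the true
min/max/avg widths all equal the sampled target. The surround is band-passed
Gaussian noise (trabecular texture, base gray 85) above and a smoother
darker zone (base 70) below. Band gray is an affine remap (130 + value) of
the published per-class texture means — those means live on a normalized
scale and cannot literally be a band gray, but the remap preserves their
class ordering — with half their printed SD. Porosity is punched as dark
(gray 70) circles of radius 1–3 px at 0.5 / 1.5 / 3.0 holes per 100 px of
band length for normal / osteopenia / osteoporosis; rates are generator
choices that give the texture feature a causal class signal. A linear
illumination ramp of ±15 gray in a random direction and Gaussian pixel
noise (σ = 4) are added before 8-bit quantization; ground-truth masks are
rendered from the analytic geometry before any noise. Everything is
deterministic per record seed; dataset seeds derive from a master seed.
"Easy mode" (σ = 1, no illumination ramp) isolates the segmentation
geometry from noise robustness.

What the phantoms do **not** emulate: anatomy other than the band
(teeth, foramen, hyoid), film-specific noise spectra, edentulous
morphology, and the real covariance between width and porosity within a
patient. Passing phantom tests therefore demonstrates that the pipeline
recovers the parameters it assumes — not clinical accuracy on real
radiographs, whose published headline figures depend on a dataset that is
not distributed.

## Validation design and problem sizes

- Metric oracles: ME and RAE are checked against brute-force pixel counting
  over all pairs of 3×3 masks, plus hand-computed cases.
- Geometry: rotated-band sweep, 5 angles × 3 thicknesses.
- Segmentation: easy-mode phantoms must reach ME ≤ 0.05 per image; the
  pipeline typically achieves ME ≈ 0.002.
- End-to-end: one phantom study at the 68/38/17 composition (123 subjects,
  246 ROIs, full segmentation), checking that per-class mean recovered
  widths preserve the class ordering and that 10-fold CV accuracy with all
  8 features does not trail width-only features by more than 1 percentage
  point (accuracies averaged over 3 CV shuffle seeds to damp fold noise).
- Permuted-label null: on the imbalanced 68/38/17 design an
  information-free classifier reaches the majority rate (~55%), so the
  permutation check runs on a balanced 17-per-class subsample, where chance
  is exactly 1/3; the observed accuracy must fall within the binomial 95%
  band around 1/3.

The phantom classes deliberately overlap as much as the published per-class
distributions do, so absolute phantom CV accuracy (~53–60%) is far below
the published real-data accuracy; only orderings and relative comparisons
are meaningful at this overlap.

## Known limitations

- The merging distance is a stand-in for the (uncited-formula) statistic of
  the original region-merging literature; it is config-swappable.
- The semiautomatic variant (user-clicked seeds) is available through the
  library API by constructing `SeedAssignment` directly; the CLI only
  exposes the automatic path.
- Sensitivity/specificity confidence intervals use the Clopper–Pearson
  exact method; other CI conventions will differ in the third decimal.
- Panoramic mandibular index and Klemetti index are out of scope.
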