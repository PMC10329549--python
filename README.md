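# corticad

Computer-aided assessment of mandibular cortical bone on dental panoramic
radiographs, for osteoporosis screening research.

Low bone mineral density (BMD) manifests in the mandible: the inferior
cortical band below the mental foramen thins and grows porous as patients
progress from normal bone through osteopenia to osteoporosis (WHO T-score
bins: t ≥ −1 normal, −2.5 < t < −1 osteopenia, t ≤ −2.5 osteoporosis).
Because panoramic radiographs are routine in dental practice, the mandibular
cortical width (MCW) and cortical texture are attractive opportunistic
screening signals. `corticad` implements a complete pipeline that takes
128×128 ROI crops below the left and right mental foramen and produces a
three-class prediction, together with the evaluation machinery and a phantom
generator so every stage can be validated without patient data.

## Pipeline

1. **Line-operator enhancement.** Each pixel is scored by
   `max_θ (mean gray along an oriented line of length l) − (mean gray of the
   N×N neighborhood)`, computed on a Gaussian image pyramid so both thin and
   thick bright structures respond; the per-scale responses are normalized,
   fused by pixelwise maximum, and multiplied back into the ROI
   (gray-preserving multiplication).
2. **Statistical region merging.** The enhanced ROI is over-segmented by
   gradient watershed; an object seed (large, bright, central region) and a
   background seed (small, dark, peripheral region) are chosen
   automatically; remaining regions merge one at a time into the class with
   the nearest area-weighted mean gray. The largest connected component is
   the cortical mask.
3. **Width morphometry.** The mask's upper border is fitted by the
   polynomial (degree 1–5, chosen by cross-validation) with least squared
   error; at each sampled column the width is measured by marching from the
   border point along the inward normal of the fitted curve — a
   perpendicular thickness, not a column height (which overestimates a band
   tilted by θ by 1/cos θ).
4. **Texture.** ROIs are percentile-normalized to a common intensity scale;
   the texture feature is the mean normalized gray over the cortical mask —
   porous bone contains more dark pixels, lowering the mean.
5. **Classification.** Eight features per subject (min/max/avg width ×2
   sides, texture ×2 sides) feed a one-vs-one RBF-SVM, evaluated by
   stratified k-fold cross-validation with per-fold standardization and
   hyperparameter grid search.
6. **Evaluation.** Segmentation: misclassification error
   ME = 1 − (|B∩B| + |F∩F|)/n and relative foreground area error
   RAE = |A_g − A_p| / max(A_g, A_p). Classification: 3-class confusion
   matrix, and after collapsing to low-bone-density vs normal: sensitivity,
   specificity, accuracy, LR+ = sens/(1−spec), LR− = (1−sens)/spec with
   Clopper–Pearson intervals.
7. **Phantoms.** Class-conditional synthetic ROI pairs with ground truth: a
   bright band of constant perpendicular thickness under a curved border,
   trabecular texture, punched pores, illumination gradient and pixel
   noise. Width distributions per class and side follow published per-class
   measurements (e.g. normal right 27.7 ± 6.4 px).

## Worked example

```python
from corticad import (generate_phantom_pair, segment_cortical, measure_side,
                      texture_feature, misclassification_error,
                      relative_foreground_area_error)

rec = generate_phantom_pair("osteoporosis", seed=42)
print(f"true perpendicular width : {rec.true_widths['right'][2]:.2f} px")
mask = segment_cortical(rec.right_roi)
me = misclassification_error(rec.right_mask, mask)
rae = relative_foreground_area_error(rec.right_mask, mask)
print(f"segmentation ME / RAE    : {me:.4f} / {rae:.4f}")
w_min, w_max, w_avg = measure_side(rec.right_roi, mask)
print(f"width min/max/avg        : {w_min:.2f} / {w_max:.2f} / {w_avg:.2f} px")
print(f"texture (mean intensity) : {texture_feature(rec.right_roi, mask):.2f}")
```

prints

```
true perpendicular width : 24.15 px
segmentation ME / RAE    : 0.0070 / 0.0368
width min/max/avg        : 23.38 / 24.62 / 24.01 px
texture (mean intensity) : 226.31
```

The phantom sampled a 24.15 px osteoporotic band; segmentation disagrees
with the ground-truth mask on 0.7% of pixels and the measured average width
(24.01 px) recovers the true thickness to within 0.6%. The texture value is
the mean normalized gray over the segmented band.

## Command line

```
corticad --seed 1 --out phantoms generate                 # 68/38/17 dataset
corticad --out run segment  phantoms/manifest.csv         # masks + ME/RAE
corticad --out run features phantoms/manifest.csv         # 8-column CSV
corticad --out run classify run/features.csv              # k-fold CV table
```

Every command writes a JSON run report embedding the resolved configuration
and seed, so a run can be reproduced bit-for-bit.

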