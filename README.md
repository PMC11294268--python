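# segvar

Interobserver variability analysis for 2D lesion segmentations — built for
the setting of intraoperative B-mode ultrasound of brain tumours, where
several experienced readers outline the same lesion on a grayscale image and
an MRI-informed annotation serves as the reference standard. Tumour margins
on ultrasound are often genuinely indistinct, so readers disagree; `segvar`
provides the machinery to measure that disagreement, to test whether
relaxing segmentations to bounding boxes reduces it, and to quantify how
visually distinct a margin actually is.

## What it computes

**Agreement metrics.** For two binary masks A and B (with boundary-pixel
sets A_c, B_c):

- IoU = |A∩B| / |A∪B| (Jaccard index)
- DSC = 2|A∩B| / (|A|+|B|) (Sørensen–Dice; DSC = 2·IoU/(1+IoU))
- HD = max( max_{a∈A_c} min_{b∈B_c} ‖a−b‖ , max_{b∈B_c} min_{a∈A_c} ‖a−b‖ )
  — the symmetric Hausdorff distance in pixels, sensitive to the single
  worst boundary disagreement.

**Bounding-box relaxation.** Boxes take the extremal row/column coordinates
of a segmentation and are evaluated with the same three metrics after
rasterisation; a containment fraction scores how much of a reference
segmentation falls inside another reader's box.

**Boundary dispersion.** Intensities sampled in a ±10-pixel perpendicular
band around a contour are density-estimated (Gaussian KDE) and classified by
peak count — bimodal (crisp margin), unimodal (indistinct), or other — with
a blurred-circle phantom calibrating the classifier.

**Aggregation.** Per-image metric values become Metric[mean : IQR]
summaries, IQR-reduction percentages between the segmentation and box
variants, and cross-annotator means. A packaged per-image agreement table
from a 30-image, three-annotator reading study validates this layer: all of
its printed summary rows are recomputed from the per-image values.

**Synthetic cohorts.** A generator produces star-convex reference lesions,
simulated annotators with correlated, omission-dominated boundary
disagreement of controllable scale, and speckled ultrasound-like textures
with controllable boundary blur — so every pipeline stage is testable
without patient data. See `docs/methods.md` for the model and its
assumptions.

## Worked example

```python
import segvar

spec = segvar.SyntheticSpec(seed=7, image_size=(256, 256),
                            lesion=segvar.LesionSpec(radius=60),
                            jitter_sigma=4.0)
cohort = segvar.generate_cohort(spec, n_images=30)

seg_ious, box_ious = [], []
for ci in cohort:
    for rec in segvar.versus_reference(ci.reference, ci.annotators, "Seg"):
        seg_ious.append(rec.iou)
    for rec in segvar.versus_reference(ci.reference, ci.annotators, "BBox"):
        box_ious.append(rec.iou)

s, b = segvar.summarize(seg_ious), segvar.summarize(box_ious)
print(f"Seg  IoU[{s.mean:.3f}:{s.iqr:.3f}]  (n={s.n})")
print(f"BBox IoU[{b.mean:.3f}:{b.iqr:.3f}]  (n={b.n})")
print(f"IQR reduction: {segvar.iqr_reduction(seg_ious, box_ious).reduction_percent}%")

profile = segvar.dispersion_study(cohort[0].image, cohort[0].reference)
print(f"boundary band: {profile.modality}, peaks at {[round(p) for p in profile.peaks]}")
```

prints

```
Seg  IoU[0.836:0.123]  (n=90)
BBox IoU[0.938:0.051]  (n=90)
IQR reduction: 59%
boundary band: bimodal, peaks at [82, 167]
```

Thirty simulated images, three simulated readers each: against the
reference, raw segmentations average IoU 0.836 with an interquartile range
of 0.123 across readings; converting every annotation to its bounding box
raises the average to 0.938 and halves the spread (59% IQR reduction) —
boxes forgive boundary-shape disagreement while preserving lesion extent.
The first image's boundary band is bimodal (two intensity populations, one
per side of a crisp margin at this low blur setting).

The same analyses are available from the command line: `segvar metrics`,
`segvar summarize`, `segvar reproduce-tables`, `segvar dispersion`,
`segvar simulate` (see `segvar --help`).

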