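# Methods

`segvar` quantifies interobserver variability in 2D lesion segmentation, in
the setting where several readers outline the same lesion on a grayscale
(B-mode ultrasound-like) image and one MRI-informed annotation serves as the
reference standard. It implements four connected analyses: pairwise
agreement metrics on mask pairs, bounding-box relaxation of segmentations,
a boundary intensity-dispersion classifier with a blur-phantom calibrator,
and the aggregation machinery that turns per-image metric values into the
summary statistics a reading study reports. A packaged 30-image agreement
table (three annotators, segmentation and box variants) anchors the
aggregation layer; a synthetic cohort generator stands in for the
unpublished image and mask data everywhere else.

## Agreement metrics

For two same-shape binary masks A and B:

* IoU = |A∩B| / |A∪B| and DSC = 2|A∩B| / (|A|+|B|), by pixel counting.
  They are linked by DSC = 2·IoU/(1+IoU); the package treats this identity
  as an invariant and tests it to machine precision.
* HD is the symmetric Hausdorff distance between the two boundary-pixel
  sets: max of the two directed max–min Euclidean distances. It is the
  *full* Hausdorff distance, not HD95 — the statistic is meant to expose the
  single worst boundary disagreement.

Conventions that the numbers depend on:

* Coordinates are 0-based (row, col) pixel indices, row increasing downward;
  all distances are Euclidean in pixel index space. No physical spacing or
  orientation metadata is applied, matching pixel-unit HD reporting.
* A boundary pixel is a foreground pixel with a background pixel among its
  8 neighbours; image-border pixels count as boundary (outside = background).
  Contour coordinates sit at pixel centres. The 4- vs 8-connectivity choice
  moves HD by at most about one pixel; 8-connectivity is fixed here.
* A comparison where *both* masks are empty raises instead of returning a
  conventional value — an empty-vs-empty agreement is meaningless in a
  reading study, and silently returning 0 (or 1) would poison aggregates.
  HD additionally requires both masks nonempty.

The KD-tree implementation of HD is verified in the test suite against an
exhaustive double-loop oracle over all point pairs.

## Bounding-box relaxation

A segmentation's box takes the extremal row/column coordinates of its
foreground (inclusive integer bounds). Boxes are *evaluated* by rasterising
them back to filled rectangles and applying the same three metrics, so box
area counts lattice pixels and the box contour used for HD is the perimeter
pixel set of the rectangle (not just the four corners). Degenerate
single-row/column boxes are legal. The containment fraction of a reference
mask in a box is |reference ∩ box| / |reference|; a mask is always fully
contained in its own box, so sub-unit values arise only across annotators.

## Boundary intensity dispersion

The dispersion analysis asks whether a lesion margin is visually distinct:
sample the image in a perpendicular band around the segmentation contour,
estimate the intensity distribution, and classify its modality.

* **Band sampling.** At each contour pixel, intensities are read at unit
  steps along the local normal, `halfwidth` (default 10) pixels to each
  side, plus the contour pixel itself — 2·10+1 = 21 samples per contour
  point. Normals are the gradient of the signed distance transform of the
  mask, smoothed with a 1-px Gaussian — stable on jagged rasterised
  contours, where a purely local tangent estimate is noisy. (When only
  contour points are available, a local-PCA tangent fallback is used.)
  Values are bilinearly interpolated; positions outside the image are
  dropped, not clamped. Whether the band includes the contour pixel itself
  is a convention; it is included here.
* **Density estimate.** Gaussian KDE with Scott's-rule bandwidth, evaluated
  on a 256-point grid over [0, 255] and renormalised to unit trapezoidal
  integral on the grid (kernels centred at 0 or 255 leak mass outside the
  8-bit range). Sample sets with near-zero spread (below 1e-6, far under
  the 8-bit quantum) are degenerate and classified unimodal by convention.
* **Modality.** Local maxima with prominence ≥ 5% of the global density
  maximum are counted: one peak → unimodal, two → bimodal, three or more →
  other. The relative prominence floor suppresses KDE ripple on
  near-uniform bands and makes the class invariant to affine intensity
  rescaling; the density is zero-padded before peak-finding so modes
  sitting exactly at 0 or 255 count. The 5% value is a single documented
  configuration constant; any reasonable setting should agree to within
  ±1 peak.

**Blur-phantom calibration.** A two-level disc (inside/outside contrast)
with Gaussian or box filtering of increasing strength sweeps the margin
from crisp to indistinct: sharp → bimodal band, heavy blur → unimodal, with
a one-way transition in between (possibly through "other"). The optional
protrusions variant adds four radial spurs (width 3 px, length half the
radius) to the *shape* before filtering while the returned mask stays the
ideal disc — the defined boundary is unaffected by either the spurs or the
blur. The default calibration phantom is a radius-60 disc in a 256×256
image: with the band fixed at ±10 px, the modality transition happens at
blur sigma ≈ 1.5× the band halfwidth (a truncated intensity ramp keeps two
end modes until the blur scale exceeds the band scale), so "severe blur"
expressed as sigma = radius/3 lands in the unimodal regime only for radii
of roughly 50 px and above — which is also the realistic lesion scale
relative to a 10-px band in study-sized (≈10⁶-pixel) images.

## Synthetic reading-study generator

No patient data ships with the package, so a generator emulates the study
conditions: one reference lesion per image, K annotator masks, and a
grayscale texture.

* **Lesions** are star-convex: a radial outline r(θ) = R·s(θ)·(1 + Σₖ aₖ
  cos(kθ+φₖ)) with an elliptical stretch s(θ) and random lobe phases,
  rasterised by comparing each pixel's polar radius to the interpolated
  outline. Star-convexity is a deliberate simplification so annotator
  disagreement can act directly on the radial outline; real tumours are not
  star-convex, but every metric and pipeline stage is fully exercised.
* **Annotators** perturb the outline with smooth periodic noise (white
  noise on a 720-bin angular grid, Gaussian-smoothed with wrap-around so
  outlines close smoothly, standardised to zero mean and unit variance,
  then scaled to `jitter_sigma` pixels). The perturbation mixes a dominant
  one-sided *inward omission* component (default 70%) with a symmetric
  placement-jitter component (30%). The rationale: readers working from the
  grayscale image alone tend to omit stretches of an indistinct,
  infiltrative margin that an MRI-informed reference includes, while
  agreeing much better on the lesion's overall extent. This structure is
  what makes box annotation forgiving — derived boxes are anchored by the
  angles where the omission vanishes — and without it (pure symmetric
  jitter) box agreement is *more* variable than segmentation agreement and
  the study's IQR-reduction effect does not appear.
* **Per-image difficulty** varies by a log-normal multiplier on
  `jitter_sigma` (log-sd `jitter_heterogeneity`, default 1.0, capped at
  half the lesion radius). Reading studies show exactly this: some lesions
  are crisp and read near-identically, others are fuzzy and produce
  order-of-magnitude larger disagreement. A constant difficulty level
  produces unrealistically tight per-image metric distributions.
* **Texture**: inside/outside mean echogenicity, multiplicative unit-mean
  log-normal speckle (a standard ultrasound texture surrogate), then a
  Gaussian boundary blur; clipped to [0, 255]. Physically accurate
  ultrasound simulation (attenuation, shadowing, beam effects) is a
  non-goal.
* **Validity bound**: `jitter_sigma` larger than the reference's mean
  radius — a perturbation as large as the lesion itself — raises a
  degenerate-simulation error, as does a perturbed mask that collapses to
  fewer than 4 pixels. Zero jitter returns the reference bit-identically.
* **Determinism**: all randomness is spawned from the master seed via
  `SeedSequence`; identical seeds give bit-identical cohorts.

What passing tests on this generator do and do not show: they demonstrate
that the pipeline's statistics respond correctly to controlled disagreement
(monotone in jitter, perfect scores at zero jitter, box-IQR shrinkage under
omission-dominated disagreement), not that real interobserver variability
has these magnitudes. The packaged agreement table is the only link to real
data, and only at the per-image metric level.

## Aggregation

* Summaries are reported as Metric[mean : IQR] with the median alongside.
  Quartiles use linear interpolation of order statistics (the "type 7"
  convention, numpy's default); IQR = Q3 − Q1. This convention is fixed
  project-wide because it reproduces every packaged IQR-reduction
  percentage exactly.
* IQR reductions are rounded to the nearest integer percent; a zero
  segmentation-variant IQR makes the reduction undefined and raises.
* Cross-annotator summary values are means of per-annotator means, not
  pooled over all annotator×image values (with equal image counts per
  annotator the two differ only in higher moments; the mean-of-means
  definition reproduces the packaged cross-annotator values).
* The packaged table stores 3-decimal per-image values. Its integrity check
  verifies DSC against 2·IoU/(1+IoU) within 0.0016 — the worst-case
  propagation of two independent half-ulp (0.0005) roundings through the
  identity (0.0005·2/(1+IoU)² + 0.0005) — rather than a tighter bound the
  stored precision cannot support; two rows sit between 0.001 and 0.0013.
  Recomputed column means are checked against the table's printed summary
  rows within ±0.005 (IoU/DSC) and ±0.05 (HD).

## Problem sizes

The test suite and the acceptance script run on deliberately small
configurations chosen to exercise every code path with comfortable margins:
160×160 images with radius-40 lesions for cohort statistics (50 replicate
pairs per jitter level across four levels), the 256×256 radius-60 phantom
for dispersion, 1,000 random 16×16–24×24 mask pairs for the metric
identities, and 100 random contour pairs of up to 500 points for the
Hausdorff oracle. These sizes are the package's own defaults for
verification; the library itself is size-agnostic and handles study-scale
(≈1280×960) images directly.

## Known limitations

* 2D only; no volumetric metrics, no physical spacing, no HD95/ASSD.
* Star-convex synthetic lesions cannot represent multi-lobed or folded
  tumour outlines, and the annotator model cannot produce disconnected or
  hole-containing annotations.
* The dispersion classifier's peak count depends on the KDE bandwidth and
  the prominence floor near class boundaries; single-peak-margin decisions
  should not be over-interpreted.
* The packaged table permits validating aggregation only; per-image mask
  recomputation is impossible without the study's images and masks, and
  statistics whose inputs are unpublished (e.g. cross-annotator containment
  percentages) are exercised only as properties on synthetic data.
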