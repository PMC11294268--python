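"""Synthetic lesions, simulated annotators and ultrasound-like textures.

No patient data ships with this package, so every pipeline stage is exercised
on synthetic material built from three ingredients:

1. **Reference lesions** — star-convex masks rasterised from a radial outline
   r(θ) = radius · s(θ) · (1 + Σₖ aₖ cos(kθ + φₖ)), where s(θ) applies an
   elliptical axis stretch and the cosine lobes give an irregular, tumour-like
   silhouette. Star-convexity is a deliberate simplification: it lets
   annotator disagreement act directly on the radial outline.
2. **Simulated annotators** — each annotator re-draws the boundary with a
   smooth, angularly correlated radial perturbation: white noise on an
   angular grid, smoothed with a periodic Gaussian kernel whose width is the
   correlation length expressed in arc-length pixels, standardised to a
   target radial scale (``jitter_sigma``, pixels). Correlated rather than
   independent jitter mimics how human annotators deviate over whole
   boundary stretches, not pixel by pixel. The perturbation mixes two
   components: a dominant *inward omission* term (one-sided, annotators
   leaving out stretches of an indistinct margin that the reference
   standard includes) and a smaller symmetric placement-jitter term — so
   simulated readers disagree far more about boundary shape than about the
   lesion's overall extent, the structure that makes box annotation
   forgiving. Per-image difficulty varies by a log-normal multiplier on
   ``jitter_sigma`` (some lesions read crisply, some are fuzzy).
3. **US-like texture** — inside/outside mean echogenicity levels,
   multiplicative log-normal speckle (unit mean), then a Gaussian blur of the
   boundary; blur strength sweeps the margin from crisp to indistinct, the
   axis probed by the dispersion substudy.

Everything is deterministic under a fixed master seed: per-image and
per-annotator generators are spawned from it with ``numpy``'s SeedSequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .agreement_metrics import EmptyMaskError

__all__ = [
    "SyntheticSpec",
    "TextureSpec",
    "LesionSpec",
    "CohortImage",
    "DegenerateSimulationError",
    "make_reference_lesion",
    "simulate_annotator",
    "render_us_texture",
    "generate_cohort",
]


class DegenerateSimulationError(RuntimeError):
    """A simulated perturbation collapsed the mask to (near) nothing."""


@dataclass(frozen=True)
class LesionSpec:
    """Radial-outline parameters of the reference lesion."""

    centre: tuple[float, float] | None = None  # (row, col); None = image centre
    radius: float = 60.0
    ellipticity: float = 0.15  # relative stretch of the row vs col axis
    lobe_amplitude: float = 0.12  # fractional radial modulation
    lobe_frequency: int = 4  # highest cosine harmonic used


@dataclass(frozen=True)
class TextureSpec:
    """Echogenicity and noise parameters of the rendered B-mode-like image."""

    inside_mean: float = 170.0  # hyperechogenic lesion
    outside_mean: float = 80.0
    speckle_sigma: float = 0.25  # log-normal sigma of multiplicative speckle
    blur_sigma: float = 2.0  # boundary blur, pixels


@dataclass(frozen=True)
class SyntheticSpec:
    """Full study-generator configuration.

    Defaults mirror a 30-image, three-annotator reading study with moderate
    boundary disagreement: ``jitter_sigma`` is the per-annotator radial
    boundary perturbation scale in pixels and ``jitter_corr_length`` its
    angular correlation expressed as arc length in pixels.
    """

    image_size: tuple[int, int] = (256, 256)
    lesion: LesionSpec = field(default_factory=LesionSpec)
    annotators: int = 3
    jitter_sigma: float = 4.0
    jitter_corr_length: float = 10.0
    omission_fraction: float = 0.7
    jitter_heterogeneity: float = 1.0
    texture: TextureSpec = field(default_factory=TextureSpec)
    seed: int = 0

    def __post_init__(self):
        if self.annotators < 2:
            raise ValueError("agreement studies need at least 2 annotators")
        if min(self.jitter_sigma, self.jitter_corr_length) < 0:
            raise ValueError("jitter scales must be >= 0")
        if not 0 <= self.omission_fraction <= 1:
            raise ValueError("omission_fraction must be in [0, 1]")
        if self.jitter_heterogeneity < 0:
            raise ValueError("jitter_heterogeneity must be >= 0")


@dataclass(frozen=True)
class CohortImage:
    """One synthetic study image: texture, reference mask, annotator masks."""

    image: np.ndarray
    reference: np.ndarray
    annotators: tuple[np.ndarray, ...]


_N_THETA = 720  # angular grid resolution for outlines and jitter


def _outline(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Radial outline r(θ) on the fixed angular grid, in pixels."""
    les = spec.lesion
    theta = np.linspace(0, 2 * np.pi, _N_THETA, endpoint=False)
    r = np.ones(_N_THETA)
    for k in range(2, les.lobe_frequency + 1):
        amp = les.lobe_amplitude / max(1, les.lobe_frequency - 1)
        r += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    # elliptical stretch: scale radius anisotropically with angle
    stretch = 1 + les.ellipticity * np.cos(2 * theta)
    return les.radius * r * stretch


def _rasterise(
    centre: tuple[float, float], r_of_theta: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Fill the star-convex region ρ(θ) <= r(θ) on the pixel lattice."""
    cy, cx = centre
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = yy - cy, xx - cx
    rho = np.hypot(dy, dx)
    theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    idx = theta / (2 * np.pi) * _N_THETA
    r_interp = np.interp(idx.ravel(), np.arange(_N_THETA), r_of_theta, period=_N_THETA)
    return (rho.ravel() <= r_interp).reshape(shape)


def _centre(spec: SyntheticSpec) -> tuple[float, float]:
    if spec.lesion.centre is not None:
        return spec.lesion.centre
    return ((spec.image_size[0] - 1) / 2.0, (spec.image_size[1] - 1) / 2.0)


def make_reference_lesion(spec: SyntheticSpec) -> np.ndarray:
    """Deterministic star-convex reference mask for the given spec."""
    rng = np.random.default_rng(spec.seed)
    r = _outline(spec, rng)
    cy, cx = _centre(spec)
    rmax = r.max()
    rows, cols = spec.image_size
    if rmax > min(cy, cx, rows - 1 - cy, cols - 1 - cx):
        raise ValueError("lesion outline does not fit inside the image")
    return _rasterise((cy, cx), r, spec.image_size)


def _extract_radial_outline(mask: np.ndarray) -> tuple[tuple[float, float], np.ndarray]:
    """Centroid and per-angle maximum radius of a star-convex mask."""
    pts = np.argwhere(mask)
    if pts.size == 0:
        raise EmptyMaskError("cannot extract the outline of an empty mask")
    cy, cx = pts.mean(axis=0)
    dy, dx = pts[:, 0] - cy, pts[:, 1] - cx
    rho = np.hypot(dy, dx)
    theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    bins = np.floor(theta / (2 * np.pi) * _N_THETA).astype(int)
    r = np.full(_N_THETA, -np.inf)
    np.maximum.at(r, bins, rho)
    # fill angular bins with no pixel (thin shapes) by periodic interpolation
    good = np.isfinite(r)
    if not good.all():
        idx = np.arange(_N_THETA)
        r[~good] = np.interp(idx[~good], idx[good], r[good], period=_N_THETA)
    return (cy, cx), r + 0.5  # half-pixel compensation for lattice truncation


def _periodic_smooth(noise: np.ndarray, sigma_bins: float) -> np.ndarray:
    if sigma_bins <= 0:
        return noise
    return ndimage.gaussian_filter1d(noise, sigma=sigma_bins, mode="wrap")


#: Mean absolute value of a standard normal, used to put the one-sided
#: omission component on the same pixel scale as the symmetric component.
_HALF_NORMAL_MEAN = np.sqrt(2 / np.pi)


def _smooth_unit_noise(rng, sigma_bins: float) -> np.ndarray:
    """Periodic smooth noise standardised to zero mean and unit variance."""
    g = _periodic_smooth(rng.standard_normal(_N_THETA), sigma_bins)
    sd = g.std()
    return (g - g.mean()) / sd if sd > 0 else g


def simulate_annotator(
    reference: np.ndarray,
    jitter_sigma: float,
    jitter_corr_length: float,
    seed: int | np.random.Generator,
    omission_fraction: float = 0.7,
) -> np.ndarray:
    """One simulated annotator's segmentation of a star-convex reference.

    The reference's radial outline is perturbed by smooth periodic noise of
    scale ``jitter_sigma`` pixels, correlated over arcs of roughly
    ``jitter_corr_length`` pixels, and re-rasterised. A fraction
    ``omission_fraction`` of the perturbation is one-sided inward (the
    annotator omits stretches of an indistinct margin the reference
    includes); the remainder is symmetric boundary-placement jitter. With
    the default mix a simulated annotator's overall extent stays close to
    the reference while the boundary shape disagrees, so derived bounding
    boxes agree much better than the segmentations themselves.
    ``jitter_sigma = 0`` returns the reference unchanged.

    Raises :class:`DegenerateSimulationError` when ``jitter_sigma`` exceeds
    the reference's mean radius (the perturbation scale is no smaller than
    the lesion itself) or when the perturbed mask collapses to (near)
    nothing.
    """
    reference = np.asarray(reference, dtype=bool)
    if jitter_sigma == 0:
        return reference.copy()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    centre, r = _extract_radial_outline(reference)
    mean_r = float(np.mean(r))
    if jitter_sigma > mean_r:
        raise DegenerateSimulationError(
            f"jitter_sigma {jitter_sigma} exceeds the mean lesion radius "
            f"{mean_r:.1f}; the perturbation model is out of its domain"
        )
    arc_per_bin = 2 * np.pi * mean_r / _N_THETA
    sigma_bins = jitter_corr_length / max(arc_per_bin, 1e-9)
    inward = -np.abs(_smooth_unit_noise(rng, sigma_bins)) / _HALF_NORMAL_MEAN
    symmetric = _smooth_unit_noise(rng, sigma_bins)
    noise = jitter_sigma * (
        omission_fraction * inward + (1 - omission_fraction) * symmetric
    )
    r_new = np.clip(r + noise, 0.0, None)
    mask = _rasterise(centre, r_new, reference.shape)
    if mask.sum() < 4:
        raise DegenerateSimulationError(
            "boundary perturbation collapsed the annotation to (near) nothing"
        )
    return mask


def render_us_texture(
    reference: np.ndarray,
    spec: SyntheticSpec,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Speckled, boundary-blurred grayscale rendering of a lesion mask.

    Inside/outside mean levels from ``spec.texture``, multiplied by unit-mean
    log-normal speckle, then Gaussian-blurred; clipped to [0, 255].
    Deterministic given the seed (defaults to ``spec.seed``).
    """
    reference = np.asarray(reference, dtype=bool)
    tex = spec.texture
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(spec.seed if seed is None else seed)
    )
    image = np.where(reference, tex.inside_mean, tex.outside_mean).astype(float)
    if tex.speckle_sigma > 0:
        s = tex.speckle_sigma
        speckle = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=image.shape)
        image = image * speckle
    if tex.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, sigma=tex.blur_sigma)
    return np.clip(image, 0.0, 255.0)


def generate_cohort(spec: SyntheticSpec, n_images: int) -> list[CohortImage]:
    """A reproducible synthetic reading study of ``n_images`` images.

    Each image gets its own lesion geometry (fresh lobe phases), a rendered
    texture, a per-image difficulty level — ``jitter_sigma`` scaled by a
    log-normal multiplier with log-sd ``jitter_heterogeneity``, capped at
    half the lesion radius — and ``spec.annotators`` simulated
    segmentations; all randomness is spawned from ``spec.seed``.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    cohort = []
    streams = np.random.SeedSequence(spec.seed).spawn(n_images)
    for img_ss in streams:
        child = img_ss.spawn(spec.annotators + 3)
        lesion_seed = int(child[0].generate_state(1)[0] % (2**31))
        img_spec = replace(spec, seed=lesion_seed)
        reference = make_reference_lesion(img_spec)
        image = render_us_texture(reference, img_spec, seed=np.random.default_rng(child[1]))
        difficulty = np.random.default_rng(child[2]).lognormal(
            0.0, spec.jitter_heterogeneity
        )
        sigma_i = min(spec.jitter_sigma * difficulty, 0.5 * spec.lesion.radius)
        annotators = tuple(
            simulate_annotator(
                reference,
                sigma_i,
                spec.jitter_corr_length,
                np.random.default_rng(child[3 + k]),
                omission_fraction=spec.omission_fraction,
            )
            for k in range(spec.annotators)
        )
        cohort.append(CohortImage(image=image, reference=reference, annotators=annotators))
    return cohort
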