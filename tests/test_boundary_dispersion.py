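"""Boundary-band sampling, KDE modality classification, and the blur phantom."""

import numpy as np
import pytest

import segvar
from segvar.boundary_dispersion import (
    BlurConfig,
    classify_modality,
    dispersion_study,
    estimate_density,
    make_blurred_circle,
    sample_boundary_band,
)
from segvar.agreement_metrics import extract_contour


def disc_mask(radius=40, size=(128, 128)):
    yy, xx = np.mgrid[0 : size[0], 0 : size[1]]
    cy, cx = (size[0] - 1) / 2, (size[1] - 1) / 2
    return np.hypot(yy - cy, xx - cx) <= radius


class TestSampleBoundaryBand:
    def test_constant_image_yields_constant_samples(self):
        mask = disc_mask()
        samples = sample_boundary_band(
            np.full(mask.shape, 42.0), extract_contour(mask), halfwidth=10, mask=mask
        )
        assert samples.size > 0
        # bilinear interpolation of a constant: equal up to float rounding
        np.testing.assert_allclose(samples, 42.0, rtol=0, atol=1e-9)

    def test_interior_contour_sample_count_is_l_times_band(self):
        # every band position of a well-interior contour is in-image:
        # 2*halfwidth + 1 samples per contour point
        mask = disc_mask(radius=30)
        contour = extract_contour(mask)
        samples = sample_boundary_band(
            np.zeros(mask.shape), contour, halfwidth=10, mask=mask
        )
        assert samples.size == len(contour) * 21

    def test_step_edge_samples_come_from_both_levels(self):
        # vertical step edge: 0 left half, 255 right half; mask = left half
        img = np.zeros((64, 64))
        img[:, 32:] = 255.0
        mask = np.zeros((64, 64), bool)
        mask[:, :32] = True
        contour = np.array([[r, 31] for r in range(20, 44)])
        samples = sample_boundary_band(img, contour, halfwidth=5, mask=mask)
        # bilinear interpolation only ever lands on grid columns -> {0, 255}
        assert set(np.unique(samples)) <= {0.0, 255.0}
        assert (samples == 0).any() and (samples == 255).any()

    def test_band_symmetry_on_circle_phantom(self):
        # symmetric phantom: every contour point contributes a full band, so
        # inward and outward counts per point are equal (halfwidth each side)
        mask = disc_mask(radius=35)
        contour = extract_contour(mask)
        samples = sample_boundary_band(
            np.zeros(mask.shape), contour, halfwidth=10, mask=mask
        )
        assert samples.size == len(contour) * (2 * 10 + 1)

    def test_out_of_image_samples_are_dropped(self):
        mask = np.zeros((20, 20), bool)
        mask[0:3, 0:3] = True  # touches the image corner
        contour = extract_contour(mask)
        samples = sample_boundary_band(
            np.zeros((20, 20)), contour, halfwidth=10, mask=mask
        )
        assert samples.size < len(contour) * 21

    def test_contour_outside_image_raises(self):
        with pytest.raises(ValueError, match="outside"):
            sample_boundary_band(np.zeros((10, 10)), np.array([[5, 12]]), halfwidth=5)

    def test_halfwidth_below_one_raises(self):
        with pytest.raises(ValueError, match="halfwidth"):
            sample_boundary_band(np.zeros((10, 10)), np.array([[5, 5]]), halfwidth=0)


class TestEstimateDensity:
    def test_density_integrates_to_one(self, rng):
        d = estimate_density(rng.normal(128, 20, size=500))
        assert np.trapezoid(d.density, d.grid) == pytest.approx(1.0, abs=1e-3)

    def test_single_gaussian_peaks_near_its_mean(self, rng):
        d = estimate_density(rng.normal(100, 8, size=2000))
        assert d.grid[np.argmax(d.density)] == pytest.approx(100, abs=5)

    def test_balanced_extremes_give_two_endpoint_maxima(self, rng):
        samples = np.r_[np.zeros(500), np.full(500, 255.0)] + rng.normal(0, 1, 1000)
        d = estimate_density(np.clip(samples, 0, 255))
        assert classify_modality(d) == "bimodal"

    def test_constant_samples_raise_degenerate_signal(self):
        with pytest.raises(ValueError):
            estimate_density(np.full(50, 7.0))


class TestClassifyModality:
    def test_well_separated_mixtures(self, rng):
        # components 5 sigma apart -> clearly resolved peaks
        uni = rng.normal(128, 10, 3000)
        bi = np.r_[rng.normal(60, 10, 1500), rng.normal(190, 10, 1500)]
        tri = np.r_[
            rng.normal(40, 8, 1000), rng.normal(128, 8, 1000), rng.normal(215, 8, 1000)
        ]
        assert classify_modality(estimate_density(uni)) == "unimodal"
        assert classify_modality(estimate_density(bi)) == "bimodal"
        assert classify_modality(estimate_density(tri)) == "other"

    def test_invariant_to_affine_intensity_rescaling(self, rng):
        samples = np.r_[rng.normal(60, 6, 800), rng.normal(180, 6, 800)]
        cls1 = classify_modality(estimate_density(samples))
        cls2 = classify_modality(estimate_density(samples * 0.4 + 30))
        assert cls1 == cls2 == "bimodal"


class TestBlurredCircle:
    def test_no_blur_gives_exactly_two_values(self):
        img, mask = make_blurred_circle(40, (128, 128), inside=0, outside=255)
        assert set(np.unique(img)) == {0.0, 255.0}
        np.testing.assert_array_equal(mask, disc_mask(40, (128, 128)))

    @pytest.mark.parametrize(
        "blur",
        [
            BlurConfig("gaussian", 8.0),
            BlurConfig("box", 6.0),
            BlurConfig("box", 6.0, protrusions=True),
        ],
        ids=["gaussian", "box", "box+protrusions"],
    )
    def test_mask_is_always_the_ideal_disc(self, blur):
        _, mask = make_blurred_circle(40, (128, 128), 0, 255, blur)
        np.testing.assert_array_equal(mask, disc_mask(40, (128, 128)))

    def test_blur_produces_intensity_continuum_in_band(self):
        img, mask = make_blurred_circle(
            40, (128, 128), 0, 255, BlurConfig("gaussian", 8.0)
        )
        band = sample_boundary_band(img, extract_contour(mask), 10, mask=mask)
        assert len(np.unique(band)) > 2

    def test_protrusions_alter_image_but_not_mask(self):
        plain, m1 = make_blurred_circle(40, (128, 128), 0, 255, BlurConfig("box", 4.0))
        spiky, m2 = make_blurred_circle(
            40, (128, 128), 0, 255, BlurConfig("box", 4.0, protrusions=True)
        )
        assert (plain != spiky).any()
        np.testing.assert_array_equal(m1, m2)

    def test_circle_too_large_raises(self):
        with pytest.raises(ValueError, match="fit"):
            make_blurred_circle(60, (128, 128))


class TestDispersionStudy:
    def test_sharp_boundary_is_bimodal(self):
        img, mask = make_blurred_circle(60, (256, 256), inside=0, outside=255)
        profile = dispersion_study(img, mask)
        assert profile.modality == "bimodal"
        lo, hi = sorted(profile.peaks)
        assert lo < 30 and hi > 225

    def test_severe_blur_is_unimodal(self):
        img, mask = make_blurred_circle(
            60, (256, 256), 0, 255, BlurConfig("gaussian", 20.0)  # sigma = radius/3
        )
        assert dispersion_study(img, mask).modality == "unimodal"

    def test_constant_image_is_unimodal_by_convention(self):
        mask = disc_mask()
        profile = dispersion_study(np.full(mask.shape, 9.0), mask)
        assert profile.modality == "unimodal"
        assert profile.density is None

    def test_blur_sweep_transitions_monotonically(self):
        # once the band stops being bimodal it never becomes bimodal again,
        # and once unimodal it stays unimodal
        _, mask = make_blurred_circle(60, (256, 256))
        sequence = []
        for sigma in np.linspace(0, 30, 11):
            img, _ = make_blurred_circle(
                60, (256, 256), 0, 255, BlurConfig("gaussian", float(sigma))
            )
            sequence.append(dispersion_study(img, mask).modality)
        assert sequence[0] == "bimodal"
        assert sequence[-1] == "unimodal"
        left_bimodal = sequence.index(
            next(s for s in sequence if s != "bimodal")
        )
        assert "bimodal" not in sequence[left_bimodal:]
        first_uni = sequence.index("unimodal")
        assert all(s == "unimodal" for s in sequence[first_uni:])
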