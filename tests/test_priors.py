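"""Classical lesion priors and the Haar pyramid."""

import numpy as np
import pytest

from drwnet.priors import (
    HaarPyramid,
    PriorConfig,
    build_prior_stack,
    detect_exudates,
    detect_hemorrhages,
    detect_microaneurysms,
    extract_vessels,
    haar_decompose,
    haar_reconstruct,
    resize_prior_stack,
    suppress_optic_disc,
)
from drwnet.synth import SceneConfig, generate_scene


def _uniform_fundus(size=96, value=0.5):
    return np.full((size, size, 3), value)


class TestDiscSuppression:
    def test_changes_only_near_mask(self, scene_g3):
        out, mask = suppress_optic_disc(scene_g3.image, scene_g3.disc_mask)
        far = ~np.asarray(mask)
        # biharmonic inpainting touches only masked pixels
        assert np.allclose(out[far], scene_g3.image[far])

    def test_empty_mask_is_identity(self):
        img = _uniform_fundus()
        out, _ = suppress_optic_disc(img, np.zeros(img.shape[:2], dtype=bool))
        assert np.array_equal(out, img)

    def test_bright_blob_attenuated(self):
        img = _uniform_fundus(96, 0.4)
        yy, xx = np.mgrid[0:96, 0:96]
        blob = np.exp(-((yy - 48) ** 2 + (xx - 48) ** 2) / (2 * 6.0**2))
        img = np.clip(img + 0.5 * blob[..., None], 0, 1)
        mask = blob > 0.3
        out, _ = suppress_optic_disc(img, mask)
        assert out[mask].max() < img[mask].max()


class TestVessels:
    def test_flat_image_zero_density(self):
        _, mask, density = extract_vessels(np.full((64, 64), 0.5))
        assert density == 0.0
        assert mask.sum() == 0

    def test_synthetic_vessel_recovered(self, scene_g3):
        from drwnet.preprocess import to_gray_norm

        gray = to_gray_norm(scene_g3.image)
        _, mask, density = extract_vessels(gray)
        truth = scene_g3.vessel_mask
        recall = (mask & truth).sum() / truth.sum()
        assert recall >= 0.5
        assert 0.0 <= density <= 1.0


class TestMicroaneurysms:
    def test_blank_field_no_blobs(self):
        blobs, prior = detect_microaneurysms(_uniform_fundus())
        assert len(blobs) == 0
        assert prior.sum() == 0

    def test_single_dark_dot_found_near_center(self):
        img = _uniform_fundus(96, 0.6)
        yy, xx = np.mgrid[0:96, 0:96]
        dot = (yy - 40) ** 2 + (xx - 55) ** 2 <= 1.5**2
        img[dot] = 0.15
        blobs, prior = detect_microaneurysms(
            img, disc_mask=np.zeros((96, 96), dtype=bool)
        )
        assert len(blobs) == 1
        y, x, _ = blobs[0]
        assert np.hypot(y - 40, x - 55) <= 2.0
        assert prior.max() == pytest.approx(1.0, abs=1e-6)

    def test_dot_inside_disc_suppressed(self):
        img = _uniform_fundus(96, 0.6)
        yy, xx = np.mgrid[0:96, 0:96]
        dot = (yy - 40) ** 2 + (xx - 55) ** 2 <= 1.5**2
        img[dot] = 0.15
        disc = (yy - 40) ** 2 + (xx - 55) ** 2 <= 8**2
        blobs, _ = detect_microaneurysms(img, disc_mask=disc)
        assert len(blobs) == 0


class TestExudates:
    def test_blank_field_empty(self):
        assert detect_exudates(
            _uniform_fundus(), np.zeros((96, 96), dtype=bool)
        ).sum() == 0

    def test_bright_blob_detected(self):
        img = _uniform_fundus(96, 0.45)
        yy, xx = np.mgrid[0:96, 0:96]
        blob = (yy - 30) ** 2 + (xx - 60) ** 2 <= 5**2
        img[blob] = [0.95, 0.9, 0.3]
        out = detect_exudates(img, np.zeros((96, 96), dtype=bool))
        assert (out & blob).sum() / blob.sum() >= 0.8

    def test_disc_region_excluded(self):
        img = _uniform_fundus(96, 0.45)
        yy, xx = np.mgrid[0:96, 0:96]
        disc = (yy - 48) ** 2 + (xx - 48) ** 2 <= 8**2
        img[disc] = [0.95, 0.9, 0.6]
        out = detect_exudates(img, disc)
        assert (out & disc).sum() == 0


class TestHemorrhages:
    def test_blank_field_empty(self):
        assert detect_hemorrhages(_uniform_fundus()).sum() == 0

    def test_area_filter_keeps_blob_rejects_speck(self):
        img = _uniform_fundus(128, 0.55)
        yy, xx = np.mgrid[0:128, 0:128]
        blob = (yy - 40) ** 2 + (xx - 40) ** 2 <= 7**2   # ~150 px
        img[blob] = 0.15
        img[100, 100] = 0.15                              # 1-px speck
        out = detect_hemorrhages(img)
        assert (out & blob).sum() / blob.sum() >= 0.7
        assert not out[100, 100]

    def test_elongated_ridge_excluded(self):
        img = _uniform_fundus(128, 0.55)
        img[60:63, 10:110] = 0.15  # vessel-like dark ridge (ecc ~ 1)
        out = detect_hemorrhages(img)
        assert out.sum() == 0


class TestPriorStack:
    def test_grade0_scene_has_empty_lesion_channels(self, scene_g0):
        stack = build_prior_stack(scene_g0.image, disc_mask=scene_g0.disc_mask)
        assert stack.ma.sum() == 0
        assert stack.hem.sum() == 0
        assert stack.ex.sum() == 0

    def test_four_channels_in_unit_range(self, scene_g3):
        stack = build_prior_stack(scene_g3.image, disc_mask=scene_g3.disc_mask)
        assert stack.stacked.shape == (*scene_g3.image.shape[:2], 4)
        assert stack.stacked.min() >= 0.0
        assert stack.stacked.max() <= 1.0
        assert stack.vessel_density == pytest.approx(
            (stack.vessels > PriorConfig().vessel_threshold).mean(), abs=0.2
        )

    def test_resize_preserves_unit_range(self, scene_g3):
        stack = build_prior_stack(scene_g3.image, disc_mask=scene_g3.disc_mask)
        small = resize_prior_stack(stack.stacked, 64)
        assert small.shape == (64, 64, 4)
        assert small.min() >= 0.0 and small.max() <= 1.0

    def test_detector_recall_on_generated_lesions(self):
        """Across seeds, each detector recovers most generated lesion pixels."""
        recalls = {"ma": [], "hem": [], "ex": []}
        for seed in range(12):
            scene = generate_scene(4, 1000 + seed, SceneConfig(size=128))
            stack = build_prior_stack(scene.image, disc_mask=scene.disc_mask)
            for key, mask in (
                ("ma", scene.ma_mask),
                ("hem", scene.hem_mask),
                ("ex", scene.ex_mask),
            ):
                if mask.sum():
                    detected = getattr(stack, key) > 0.25
                    recalls[key].append((detected & mask).sum() / mask.sum())
        for key, vals in recalls.items():
            assert np.mean(vals) >= 0.7, f"{key} recall {np.mean(vals):.2f}"

    def test_translation_equivariance_interior(self):
        """Shifting the input shifts detections (interior pixels)."""
        img = _uniform_fundus(128, 0.5)
        yy, xx = np.mgrid[0:128, 0:128]
        blob = (yy - 50) ** 2 + (xx - 50) ** 2 <= 5**2
        img[blob] = [0.95, 0.9, 0.3]
        shifted = np.roll(img, (10, 10), axis=(0, 1))
        zero = np.zeros((128, 128), dtype=bool)
        out = detect_exudates(img, zero)
        out_shifted = detect_exudates(shifted, zero)
        interior = np.zeros((128, 128), dtype=bool)
        interior[20:108, 20:108] = True
        rolled = np.roll(out, (10, 10), axis=(0, 1))
        assert np.array_equal(rolled & interior, out_shifted & interior)


class TestHaar:
    def test_constant_image_zero_details(self):
        pyr = haar_decompose(np.full((32, 32), 0.7), levels=4)
        assert len(pyr.levels) == 4
        for level in pyr.levels:
            for band in ("HI_1", "HI_2", "HI_3"):
                assert np.allclose(level[band], 0.0, atol=1e-12)

    def test_hand_computed_2x2_coefficients(self):
        pyr = haar_decompose(np.array([[1.0, 0.0], [0.0, 0.0]]), levels=1)
        lvl = pyr.levels[0]
        assert lvl["LW"][0, 0] == pytest.approx(0.5)
        for band in ("HI_1", "HI_2", "HI_3"):
            assert abs(lvl[band][0, 0]) == pytest.approx(0.5)

    def test_each_level_halves_dimensions(self, rng):
        pyr = haar_decompose(rng.uniform(0, 1, (64, 64)), levels=4)
        sizes = [lvl["LW"].shape for lvl in pyr.levels]
        assert sizes == [(32, 32), (16, 16), (8, 8), (4, 4)]

    def test_exact_roundtrip(self, rng):
        img = rng.uniform(0, 1, (64, 64))
        back = haar_reconstruct(haar_decompose(img, levels=4))
        assert np.abs(back - img).max() < 1e-10

    def test_roundtrip_with_odd_sizes(self, rng):
        img = rng.uniform(0, 1, (101, 67))
        back = haar_reconstruct(haar_decompose(img, levels=4))
        assert np.abs(back - img).max() < 1e-10

    def test_energy_conservation_orthonormal(self, rng):
        img = rng.uniform(0, 1, (64, 64))
        pyr = haar_decompose(img, levels=4)
        energy = np.sum(pyr.approximation**2)
        for lvl in pyr.levels:
            for band in ("HI_1", "HI_2", "HI_3"):
                energy += np.sum(lvl[band] ** 2)
        assert energy == pytest.approx(np.sum(img**2), rel=1e-8)

    def test_matches_pywavelets_approximation(self, rng):
        """Independent oracle: PyWavelets' orthonormal Haar DWT."""
        pywt = pytest.importorskip("pywt")
        img = rng.uniform(0, 1, (32, 32))
        ours = haar_decompose(img, levels=1).levels[0]
        cA, (cH, cV, cD) = pywt.dwt2(img, "haar")
        assert np.allclose(ours["LW"], cA, atol=1e-10)
        assert np.allclose(np.abs(ours["HI_3"]), np.abs(cD), atol=1e-10)
        assert np.allclose(
            np.abs(ours["HI_1"]) + np.abs(ours["HI_2"]),
            np.abs(cH) + np.abs(cV),
            atol=1e-10,
        )

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            haar_decompose(np.zeros((8, 8)), levels=4)
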