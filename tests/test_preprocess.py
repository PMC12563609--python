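"""Standardization pipeline: denoise/smooth/edges/crop/normalize + balancing."""

import numpy as np
import pandas as pd
import pytest

from drwnet.preprocess import (
    AugmentPolicy,
    BalancePolicy,
    augment,
    balance_dataset,
    canny_edges,
    crop_resize,
    gaussian_smooth,
    preprocess_image,
    to_gray_norm,
    wiener_denoise,
)


class TestWiener:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32), 0.5)
        assert np.allclose(wiener_denoise(img), img, atol=1e-12)

    def test_noise_variance_reduced(self):
        reductions = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noisy = np.clip(0.5 + rng.normal(0, 0.05, (64, 64)), 0, 1)
            out = wiener_denoise(noisy)
            reductions.append(out.var() < noisy.var())
        assert all(reductions)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            wiener_denoise(np.zeros((8, 8)), window=4)

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            wiener_denoise(np.zeros((8, 8, 3)))


class TestGaussianSmooth:
    def test_constant_preserved(self):
        img = np.full((16, 16), 0.3)
        assert np.allclose(gaussian_smooth(img), img, atol=1e-12)

    def test_impulse_response_equals_kernel(self):
        """Closed-form check: response of a centered unit impulse on a 5x5
        field is the normalized truncated Gaussian kernel itself."""
        sigma = 1.5
        ax = np.arange(5) - 2.0
        g = np.exp(-(ax**2) / (2 * sigma**2))
        expected = np.outer(g, g)
        expected /= expected.sum()
        img = np.zeros((5, 5))
        img[2, 2] = 1.0
        assert np.allclose(gaussian_smooth(img, sigma=sigma, ksize=5), expected, atol=1e-12)

    def test_averaging_contracts_extremes(self):
        checker = np.indices((16, 16)).sum(axis=0) % 2
        out = gaussian_smooth(checker.astype(float))
        assert out.min() > 0.0 and out.max() < 1.0

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(np.zeros((8, 8)), sigma=0.0)


class TestCanny:
    def test_constant_image_no_edges(self):
        assert canny_edges(np.full((32, 32), 0.7)).sum() == 0

    def test_vertical_step_detected_at_step(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 1.0
        edges = canny_edges(img)
        cols = np.where(edges.any(axis=0))[0]
        assert len(cols) > 0
        assert np.all(np.abs(cols - 15.5) <= 1.5)

    def test_subthreshold_step_ignored(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 0.05  # gradient below the 0.1 lower bound
        assert canny_edges(img).sum() == 0

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            canny_edges(np.zeros((8, 8)), low=0.3, high=0.1)


class TestCropResize:
    def _content(self, size):
        img = np.zeros((size, size, 3))
        yy, xx = np.mgrid[0:size, 0:size]
        c = size / 2
        img[((yy - c) ** 2 + (xx - c) ** 2) < (0.45 * size) ** 2] = 0.6
        return img

    def test_upscale_small_input(self):
        assert crop_resize(self._content(300)).shape == (644, 644, 3)

    def test_downscale_large_input(self):
        assert crop_resize(self._content(1024)).shape == (644, 644, 3)

    def test_black_border_removed(self):
        inner = self._content(200)
        padded = np.zeros((240, 240, 3))
        padded[20:220, 20:220] = inner
        out_pad = crop_resize(padded, target=100)
        out_inner = crop_resize(inner, target=100)
        assert np.abs(out_pad - out_inner).max() < 0.15  # border trimmed first

    def test_all_black_image_rejected(self):
        with pytest.raises(ValueError, match="empty field"):
            crop_resize(np.zeros((64, 64, 3)))


class TestGrayNorm:
    def test_gray_pixel_unchanged_before_rescale(self):
        # luminance weights sum to 1, so r=g=b maps to the same value
        img = np.zeros((4, 4, 3))
        img[0, 0] = [0.4, 0.4, 0.4]
        img[3, 3] = [1.0, 1.0, 1.0]
        gray = to_gray_norm(img)
        assert np.isclose(gray[0, 0], 0.4)  # (0.4-0)/(1-0)

    def test_full_unit_range_for_nonconstant(self, rng):
        gray = to_gray_norm(rng.uniform(0.2, 0.8, (16, 16, 3)))
        assert np.isclose(gray.min(), 0.0)
        assert np.isclose(gray.max(), 1.0)

    def test_constant_image_maps_to_zeros(self):
        assert np.all(to_gray_norm(np.full((8, 8, 3), 0.5)) == 0.0)


class TestAugment:
    def test_flip_and_rotation_are_involutions(self):
        img = np.arange(64, dtype=float).reshape(8, 8)
        assert np.array_equal(np.rot90(np.rot90(np.rot90(np.rot90(img)))), img)
        assert np.array_equal(img[:, ::-1][:, ::-1], img)

    def test_seeded_determinism(self, rng):
        img = rng.uniform(0, 1, (32, 32, 3))
        mask = rng.uniform(0, 1, (32, 32)) > 0.8
        policy = AugmentPolicy(seed=42)
        out1 = augment(img, policy, {"m": mask})
        out2 = augment(img, policy, {"m": mask})
        assert np.array_equal(out1[0], out2[0])
        assert np.array_equal(out1[1]["m"], out2[1]["m"])

    def test_masks_follow_geometry(self, rng):
        """A mask transformed with the image stays aligned with it."""
        img = np.zeros((32, 32, 3))
        img[4:8, 10:14] = 1.0
        mask = img[..., 0] > 0.5
        policy = AugmentPolicy(
            seed=3, gaussian_noise=False, brightness_contrast=False, hist_eq=False
        )
        out_img, out_masks = augment(img, policy, {"m": mask})
        bright = out_img[..., 0] > 0.5
        assert np.array_equal(bright, out_masks["m"])

    def test_output_in_unit_range(self, rng):
        img = rng.uniform(0, 1, (32, 32, 3))
        for seed in range(5):
            out, _ = augment(img, AugmentPolicy(seed=seed))
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_mismatched_mask_rejected(self, rng):
        with pytest.raises(ValueError):
            augment(np.zeros((16, 16, 3)), AugmentPolicy(), {"m": np.zeros((8, 8))})


class TestBalanceDataset:
    def _manifest(self, counts):
        rows = []
        for grade, n in counts.items():
            rows += [{"path": f"g{grade}_{i}.png", "grade": grade, "seed": i} for i in range(n)]
        return pd.DataFrame(rows)

    def test_severe_and_pdr_fivefold(self):
        out = balance_dataset(self._manifest({3: 10, 4: 10}))
        assert (out["grade"] == 3).sum() == 50
        assert (out["grade"] == 4).sum() == 50

    def test_mild_moderate_one_point_five(self):
        out = balance_dataset(self._manifest({1: 10, 2: 10}))
        assert (out["grade"] == 1).sum() == 15
        assert (out["grade"] == 2).sum() == 15

    def test_grade0_untouched_and_rounding_half_up(self):
        out = balance_dataset(self._manifest({0: 10, 1: 3}))
        assert (out["grade"] == 0).sum() == 10
        assert (out["grade"] == 1).sum() == 5  # 3 * 1.5 = 4.5 -> 5

    def test_replicas_have_distinct_augmentation_ids(self):
        out = balance_dataset(self._manifest({4: 4}))
        per_path = out.groupby("path")["augmentation_id"].nunique()
        assert (per_path == 5).all()

    def test_empty_manifest(self):
        out = balance_dataset(self._manifest({}))
        assert len(out) == 0

    def test_factors_below_one_rejected(self):
        with pytest.raises(ValueError):
            BalancePolicy(factor_severe_pdr=0.5)


def test_full_pipeline_outputs_well_formed(scene_g3):
    pre = preprocess_image(scene_g3.image, target=128)
    assert pre.rgb.shape == (128, 128, 3)
    assert pre.gray.shape == (128, 128)
    assert pre.edge_map.dtype == bool
    assert np.isfinite(pre.rgb).all() and np.isfinite(pre.gray).all()
    assert pre.gray.min() >= 0 and pre.gray.max() <= 1
    assert len(pre.provenance) >= 5
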