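"""Five-step image standardization pipeline plus augmentation and balancing.

Steps, in order: adaptive Wiener denoising (3x3), Gaussian smoothing
(sigma=1.5, 5x5), Canny edge detection (hysteresis thresholds 0.1/0.3 of the
normalized intensity scale), border trim + central crop + bicubic resize to
the 644 working resolution, luminance grayscale conversion with min-max
normalization.  Geometric/photometric augmentation and class-balanced
oversampling (5x for severe/proliferative grades, 1.5x for mild/moderate)
operate on top.

All convolutions use reflect padding so the dark-border trim rule is never
triggered by boundary artifacts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature as skfeature
from skimage.transform import resize as _sk_resize

logger = logging.getLogger(__name__)

WORKING_SIZE = 644

__all__ = [
    "PreprocessedImage",
    "AugmentPolicy",
    "BalancePolicy",
    "wiener_denoise",
    "gaussian_smooth",
    "canny_edges",
    "crop_resize",
    "to_gray_norm",
    "augment",
    "balance_dataset",
    "preprocess_image",
]


@dataclass
class PreprocessedImage:
    rgb: np.ndarray          # target x target x 3, [0, 1]
    gray: np.ndarray         # target x target, [0, 1], min-max normalized
    edge_map: np.ndarray     # binary target x target
    provenance: list = field(default_factory=list)


@dataclass
class AugmentPolicy:
    """Geometric + photometric augmentation settings."""

    rotations: tuple = (90, 180, 270)
    flip_prob: float = 0.5
    max_translation_frac: float = 0.10
    hist_eq: bool = False
    gaussian_noise: bool = True
    brightness_contrast: bool = True
    noise_sd_range: tuple = (0.01, 0.05)
    brightness_contrast_frac: float = 0.20
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0,1]")
        if not 0.0 <= self.max_translation_frac <= 0.5:
            raise ValueError("max_translation_frac must be in [0,0.5]")


@dataclass
class BalancePolicy:
    """Oversampling factors for class balancing."""

    factor_severe_pdr: float = 5.0
    factor_mild_moderate: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.factor_severe_pdr < 1 or self.factor_mild_moderate < 1:
            raise ValueError("oversampling factors must be >= 1")


def wiener_denoise(gray: np.ndarray, window: int = 3) -> np.ndarray:
    """Local-variance-adaptive Wiener filter (default 3x3 window).

    Classic estimator: with local mean mu and local variance s2 over the
    window and noise power nu estimated as the mean local variance,

        out = mu + max(s2 - nu, 0) / max(s2, nu) * (x - mu).

    Flat regions (s2 <= nu) collapse to the local mean; high-variance detail
    passes through.  Reflect boundaries keep a constant image exactly fixed.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError("wiener_denoise expects a 2-D grayscale image")
    if window % 2 == 0:
        raise ValueError("window size must be odd")
    mu = ndimage.uniform_filter(gray, size=window, mode="reflect")
    s2 = ndimage.uniform_filter(gray**2, size=window, mode="reflect") - mu**2
    s2 = np.maximum(s2, 0.0)
    nu = s2.mean()
    denom = np.maximum(s2, nu)
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(denom > 0, np.maximum(s2 - nu, 0.0) / denom, 0.0)
    out = mu + gain * (gray - mu)
    return np.clip(out, 0.0, 1.0)


def _gaussian_kernel(sigma: float, ksize: int) -> np.ndarray:
    ax = np.arange(ksize) - (ksize - 1) / 2.0
    g = np.exp(-(ax**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def gaussian_smooth(
    gray: np.ndarray, sigma: float = 1.5, ksize: int = 5
) -> np.ndarray:
    """Convolve with a normalized truncated Gaussian (reflect boundaries)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError("gaussian_smooth expects a 2-D image")
    kernel = _gaussian_kernel(sigma, ksize)
    return ndimage.convolve(gray, kernel, mode="reflect")


def canny_edges(
    gray: np.ndarray, low: float = 0.1, high: float = 0.3
) -> np.ndarray:
    """Hysteresis-linked edge map with thresholds on the normalized scale."""
    if low >= high:
        raise ValueError("lower threshold must be below upper threshold")
    gray = np.asarray(gray, dtype=np.float64)
    return skfeature.canny(
        gray, sigma=1.0, low_threshold=low, high_threshold=high
    )


def crop_resize(
    rgb: np.ndarray,
    border_thresh_frac: float = 0.05,
    target: int = WORKING_SIZE,
) -> np.ndarray:
    """Trim near-black borders, center-crop to square, bicubic-resize.

    Rows/columns whose maximum intensity falls below ``border_thresh_frac`` of
    the global maximum are considered non-informative border and removed
    before the central square crop.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim == 2:
        rgb = rgb[..., None].repeat(3, axis=-1)
    h, w = rgb.shape[:2]
    if h < 16 or w < 16:
        raise ValueError("image too small to crop")
    intensity = rgb.max(axis=-1)
    if intensity.max() <= 0:
        raise ValueError("empty field of view")
    thresh = border_thresh_frac * intensity.max()
    row_keep = np.where(intensity.max(axis=1) >= thresh)[0]
    col_keep = np.where(intensity.max(axis=0) >= thresh)[0]
    if row_keep.size == 0 or col_keep.size == 0:
        raise ValueError("empty field of view")
    cropped = rgb[row_keep[0] : row_keep[-1] + 1, col_keep[0] : col_keep[-1] + 1]
    ch, cw = cropped.shape[:2]
    side = min(ch, cw)
    r0 = (ch - side) // 2
    c0 = (cw - side) // 2
    square = cropped[r0 : r0 + side, c0 : c0 + side]
    out = _sk_resize(
        square, (target, target), order=3, mode="reflect", anti_aliasing=side > target
    )
    return np.clip(out, 0.0, 1.0)


_LUMA = np.array([0.2126, 0.7152, 0.0722])


def to_gray_norm(rgb: np.ndarray) -> np.ndarray:
    """Luminance-weighted grayscale followed by min-max normalization.

    A constant image has no dynamic range; it maps to all zeros (logged).
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    gray = rgb @ _LUMA if rgb.ndim == 3 else rgb.copy()
    lo, hi = gray.min(), gray.max()
    if hi - lo < 1e-12:
        logger.warning("constant image in min-max normalization; returning zeros")
        return np.zeros_like(gray)
    return (gray - lo) / (hi - lo)


def _rot90s(arr: np.ndarray, k: int) -> np.ndarray:
    return np.rot90(arr, k=k, axes=(0, 1))


def _translate(arr: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift with zero fill; pixels shifted outside the frame are dropped."""
    out = np.zeros_like(arr)
    h, w = arr.shape[:2]
    ys = slice(max(dy, 0), min(h, h + dy))
    xs = slice(max(dx, 0), min(w, w + dx))
    ys_src = slice(max(-dy, 0), min(h, h - dy))
    xs_src = slice(max(-dx, 0), min(w, w - dx))
    out[ys, xs] = arr[ys_src, xs_src]
    return out


def augment(image: np.ndarray, policy: AugmentPolicy, masks: dict | None = None):
    """Apply seeded geometric + photometric augmentation.

    Geometric transforms (rotation by a multiple of 90 degrees, flips,
    translation up to ±10%) are applied identically to the image and any
    masks; photometric transforms touch the image only.  Returns
    ``(image, masks)``; ``masks`` is ``None`` when not supplied.
    """
    rng = np.random.default_rng(policy.seed)
    img = np.asarray(image, dtype=np.float64).copy()
    masks = {k: np.asarray(v).copy() for k, v in masks.items()} if masks else None
    h, w = img.shape[:2]
    if masks:
        for m in masks.values():
            if m.shape[:2] != (h, w):
                raise ValueError("mask shape must match image shape")

    ops = []
    if policy.rotations and rng.uniform() < 0.75:
        k = int(rng.choice([r // 90 for r in policy.rotations]))
        ops.append(("rot", k))
    if rng.uniform() < policy.flip_prob:
        ops.append(("fliph", None))
    if rng.uniform() < policy.flip_prob:
        ops.append(("flipv", None))
    if policy.max_translation_frac > 0:
        dy = int(rng.integers(-1, 2) * rng.uniform(0, policy.max_translation_frac) * h)
        dx = int(rng.integers(-1, 2) * rng.uniform(0, policy.max_translation_frac) * w)
        if dy or dx:
            ops.append(("shift", (dy, dx)))

    def apply_geo(arr):
        for name, arg in ops:
            if name == "rot":
                arr = _rot90s(arr, arg)
            elif name == "fliph":
                arr = arr[:, ::-1].copy()
            elif name == "flipv":
                arr = arr[::-1, :].copy()
            elif name == "shift":
                arr = _translate(arr, *arg)
        return arr

    img = apply_geo(img)
    if masks:
        masks = {k: apply_geo(v) for k, v in masks.items()}

    if policy.hist_eq and rng.uniform() < 0.5:
        from skimage import exposure

        img = exposure.equalize_hist(img)
    if policy.gaussian_noise and rng.uniform() < 0.5:
        sd = rng.uniform(*policy.noise_sd_range)
        img = img + rng.normal(0, sd, size=img.shape)
    if policy.brightness_contrast and rng.uniform() < 0.5:
        b = rng.uniform(-policy.brightness_contrast_frac, policy.brightness_contrast_frac)
        cfac = 1.0 + rng.uniform(
            -policy.brightness_contrast_frac, policy.brightness_contrast_frac
        )
        img = (img - 0.5) * cfac + 0.5 + b
    img = np.clip(img, 0.0, 1.0)
    return img, masks


def balance_dataset(
    manifest: pd.DataFrame, policy: BalancePolicy | None = None
) -> pd.DataFrame:
    """Class-balanced oversampling of a ``path,grade,seed`` manifest.

    Severe (3) and proliferative (4) rows are replicated to 5x their original
    count; mild (1) and moderate (2) to 1.5x (rounded half up); grade 0 is
    left untouched.  Replicas receive distinct ``augmentation_id`` values so
    downstream augmentation draws independent transforms.
    """
    policy = policy or BalancePolicy()
    if len(manifest) == 0:
        out = manifest.copy()
        out["augmentation_id"] = pd.Series(dtype=int)
        return out
    if "grade" not in manifest.columns:
        raise ValueError("manifest must have a 'grade' column")
    rng = np.random.default_rng(policy.seed)
    pieces = []
    for grade, group in manifest.groupby("grade", sort=True):
        n = len(group)
        if grade in (3, 4):
            target = int(math.floor(n * policy.factor_severe_pdr + 0.5))
        elif grade in (1, 2):
            target = int(math.floor(n * policy.factor_mild_moderate + 0.5))
        else:
            target = n
        reps = []
        base = group.copy()
        base["augmentation_id"] = 0
        reps.append(base)
        extra = target - n
        i = 0
        aug_round = 1
        while extra > 0:
            take = min(extra, n)
            rep = group.iloc[:take].copy()
            rep["augmentation_id"] = [
                aug_round * 10000 + int(rng.integers(0, 10000)) for _ in range(take)
            ]
            reps.append(rep)
            extra -= take
            aug_round += 1
        pieces.append(pd.concat(reps, ignore_index=True))
    return pd.concat(pieces, ignore_index=True)


def preprocess_image(
    rgb: np.ndarray,
    target: int = WORKING_SIZE,
    include_edge_channel: bool = False,
) -> PreprocessedImage:
    """Run the full standardization pipeline on one RGB image."""
    provenance = []
    rgb = crop_resize(rgb, target=target)
    provenance.append({"step": "crop_resize", "target": target})
    gray_raw = rgb @ _LUMA
    gray_raw = wiener_denoise(np.clip(gray_raw, 0, 1), window=3)
    provenance.append({"step": "wiener", "window": 3})
    gray_raw = gaussian_smooth(gray_raw, sigma=1.5, ksize=5)
    provenance.append({"step": "gaussian", "sigma": 1.5, "ksize": 5})
    edges = canny_edges(np.clip(gray_raw, 0, 1), low=0.1, high=0.3)
    provenance.append({"step": "canny", "low": 0.1, "high": 0.3})
    gray = to_gray_norm(rgb)
    provenance.append({"step": "to_gray_norm"})
    if include_edge_channel:
        provenance.append({"step": "edge_channel", "enabled": True})
    return PreprocessedImage(
        rgb=rgb, gray=gray, edge_map=edges, provenance=provenance
    )
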