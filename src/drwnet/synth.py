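"""Synthetic fundus scene generator.

Produces fundus-like RGB images with ground-truth lesion masks and an ICDR
grade (0-4), so that every downstream stage — preprocessing, classical lesion
priors, feature extraction and network training — can be exercised without any
real dataset.  The scene model is deliberately simple but matches the
appearance the classical detectors are designed for:

* dark circular field of view (FOV) on a black background,
* bright optic disc rendered as a Gaussian blob,
* a vessel tree of recursive branching curves (dark red, ~2 px wide),
* microaneurysms (MA): small dark dots, 2-5 px across,
* hemorrhages (HEM): larger irregular dark blobs,
* exudates (EX): bright yellow sharp-edged blobs.

Lesion burden is non-decreasing with grade; grade 0 carries no lesions and
grade 1 carries microaneurysms only, mirroring the ICDR definition of mild
non-proliferative disease.  Lesion sizes are specified in absolute pixels so
the classical detectors behave consistently across working resolutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as draw_disk

__all__ = ["SceneConfig", "SyntheticScene", "generate_scene", "generate_dataset"]

ICDR_GRADES = (0, 1, 2, 3, 4)

# grade -> ((ma_lo, ma_hi), (hem_lo, hem_hi), (ex_lo, ex_hi)); counts inclusive
_DEFAULT_LESION_COUNTS = {
    0: ((0, 0), (0, 0), (0, 0)),
    1: ((2, 5), (0, 0), (0, 0)),
    2: ((5, 9), (1, 3), (1, 3)),
    3: ((9, 14), (4, 7), (3, 6)),
    4: ((12, 18), (8, 12), (6, 10)),
}


@dataclass
class SceneConfig:
    """Rendering parameters for the synthetic scene generator."""

    size: int = 644
    lesions_per_grade: dict = field(
        default_factory=lambda: dict(_DEFAULT_LESION_COUNTS)
    )
    illumination_jitter: float = 0.08
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError(f"scene size must be >= 64, got {self.size}")
        prev = (0, 0, 0)
        for g in sorted(self.lesions_per_grade):
            ranges = self.lesions_per_grade[g]
            lows = tuple(r[0] for r in ranges)
            if any(l < p for l, p in zip(lows, prev)):
                raise ValueError(
                    "lesion count ranges must be non-decreasing in grade"
                )
            prev = lows


@dataclass
class SyntheticScene:
    """A rendered fundus-like image with per-lesion ground truth."""

    image: np.ndarray  # H x W x 3 float in [0, 1]
    disc_mask: np.ndarray
    vessel_mask: np.ndarray
    ma_mask: np.ndarray
    hem_mask: np.ndarray
    ex_mask: np.ndarray
    grade: int
    seed: int

    @property
    def lesion_mask(self) -> np.ndarray:
        """Union of MA, HEM and EX masks (the segmentation target)."""
        return self.ma_mask | self.hem_mask | self.ex_mask

    @property
    def fov_mask(self) -> np.ndarray:
        h, w = self.image.shape[:2]
        yy, xx = np.mgrid[0:h, 0:w]
        c, r = (h - 1) / 2.0, 0.48 * h
        return (yy - c) ** 2 + (xx - c) ** 2 <= r**2


def _stamp_disks(mask: np.ndarray, centers, radii) -> None:
    for (cy, cx), rad in zip(centers, radii):
        rr, cc = draw_disk((cy, cx), rad, shape=mask.shape)
        mask[rr, cc] = True


def _draw_vessel_tree(rng, size: int, origin: tuple[float, float]) -> np.ndarray:
    """Recursive branching random curves starting at the optic disc."""
    mask = np.zeros((size, size), dtype=bool)
    c = (size - 1) / 2.0
    fov_r = 0.46 * size

    def grow(y, x, angle, length, width, depth):
        n = max(int(length), 2)
        ys = np.empty(n)
        xs = np.empty(n)
        a = angle
        for i in range(n):
            a += rng.normal(0.0, 0.08)
            y += np.sin(a)
            x += np.cos(a)
            ys[i], xs[i] = y, x
        for yy, xx in zip(ys, xs):
            if (yy - c) ** 2 + (xx - c) ** 2 > fov_r**2:
                break
            rr, cc = draw_disk((yy, xx), max(width, 1.0), shape=mask.shape)
            mask[rr, cc] = True
        if depth > 0 and width > 0.8:
            spread = rng.uniform(0.3, 0.7)
            grow(y, x, a - spread, length * 0.75, width * 0.8, depth - 1)
            grow(y, x, a + spread, length * 0.75, width * 0.8, depth - 1)

    n_roots = 4
    for k in range(n_roots):
        ang = rng.uniform(0, 2 * np.pi)
        grow(origin[0], origin[1], ang, 0.28 * size, 1.6, 3)
    return mask


def _place_lesions(rng, size, count, radius_fn, forbidden, fov_r, center, occupied):
    """Sample lesion centers inside the FOV, away from the disc, the vessel
    tree, the aperture rim and previously placed lesions (kept separated so
    each lesion is an isolated, countable object)."""
    mask = np.zeros((size, size), dtype=bool)
    placed = 0
    attempts = 0
    while placed < count and attempts < count * 80:
        attempts += 1
        ang = rng.uniform(0, 2 * np.pi)
        rad = fov_r * np.sqrt(rng.uniform(0.02, 0.72))
        cy = center + rad * np.sin(ang)
        cx = center + rad * np.cos(ang)
        yi, xi = int(round(cy)) % size, int(round(cx)) % size
        if forbidden[yi, xi] or occupied[yi, xi]:
            continue
        radius_fn(mask, cy, cx)
        rr, cc = draw_disk((cy, cx), 14.0, shape=occupied.shape)
        occupied[rr, cc] = True
        placed += 1
    mask &= ~forbidden
    return mask


def generate_scene(
    grade: int, seed: int, config: SceneConfig | None = None
) -> SyntheticScene:
    """Render one synthetic fundus scene for the given ICDR grade.

    Fully deterministic: identical ``(grade, seed, config.size)`` produce a
    bit-identical scene.
    """
    if not isinstance(grade, (int, np.integer)) or grade not in ICDR_GRADES:
        raise ValueError(f"grade must be an integer in 0..4, got {grade!r}")
    config = config or SceneConfig()
    size = config.size
    rng = np.random.default_rng([int(seed), int(grade), int(size)])

    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    fov_r = 0.48 * size
    fov = (yy - c) ** 2 + (xx - c) ** 2 <= fov_r**2

    # background fundus color with a smooth illumination gradient
    base = np.array([0.62, 0.28, 0.10])
    gx = rng.uniform(-1, 1) * config.illumination_jitter
    gy = rng.uniform(-1, 1) * config.illumination_jitter
    illum = 1.0 + gx * (xx - c) / size + gy * (yy - c) / size
    img = np.zeros((size, size, 3), dtype=np.float64)
    for ch in range(3):
        img[..., ch] = base[ch] * illum
    img *= fov[..., None]

    # optic disc: bright Gaussian blob displaced from center
    disc_r = 0.075 * size
    disc_ang = rng.uniform(-0.4, 0.4) + (0.0 if rng.uniform() < 0.5 else np.pi)
    dy = c + 0.30 * size * np.sin(disc_ang)
    dx = c + 0.30 * size * np.cos(disc_ang)
    d2 = (yy - dy) ** 2 + (xx - dx) ** 2
    blob = np.exp(-d2 / (2 * (disc_r / 1.5) ** 2))
    img[..., 0] += 0.35 * blob * fov
    img[..., 1] += 0.45 * blob * fov
    img[..., 2] += 0.25 * blob * fov
    disc_mask = (d2 <= disc_r**2) & fov

    # vessel tree rooted at the disc
    vessel_mask = _draw_vessel_tree(rng, size, (dy, dx)) & fov
    img[vessel_mask] *= np.array([0.45, 0.35, 0.5])

    # lesions: kept off the disc and off the visible vessel tree —
    # microaneurysms arise in capillaries below imaging resolution, and
    # hemorrhages/exudates occluding a major vessel would be atypical
    (ma_rng, hem_rng, ex_rng) = config.lesions_per_grade.get(
        grade, _DEFAULT_LESION_COUNTS[grade]
    )
    vessel_zone = ndimage.binary_dilation(
        vessel_mask, structure=np.ones((9, 9), dtype=bool)
    )
    forbidden = (d2 <= (disc_r * 1.6) ** 2) | vessel_zone

    n_ma = int(rng.integers(ma_rng[0], ma_rng[1] + 1))
    n_hem = int(rng.integers(hem_rng[0], hem_rng[1] + 1))
    n_ex = int(rng.integers(ex_rng[0], ex_rng[1] + 1))

    def ma_stamp(mask, cy, cx):
        _stamp_disks(mask, [(cy, cx)], [rng.uniform(1.2, 2.5)])

    def hem_stamp(mask, cy, cx):
        # irregular blob = union of jittered disks
        k = int(rng.integers(3, 7))
        centers = [
            (cy + rng.normal(0, 2.5), cx + rng.normal(0, 2.5)) for _ in range(k)
        ]
        _stamp_disks(mask, centers, rng.uniform(3.0, 6.0, size=k))

    def ex_stamp(mask, cy, cx):
        k = int(rng.integers(2, 5))
        centers = [
            (cy + rng.normal(0, 1.5), cx + rng.normal(0, 1.5)) for _ in range(k)
        ]
        _stamp_disks(mask, centers, rng.uniform(2.0, 4.5, size=k))

    occupied = np.zeros((size, size), dtype=bool)
    ma_mask = _place_lesions(rng, size, n_ma, ma_stamp, forbidden, fov_r, c, occupied)
    hem_mask = _place_lesions(rng, size, n_hem, hem_stamp, forbidden, fov_r, c, occupied)
    ex_mask = _place_lesions(rng, size, n_ex, ex_stamp, forbidden, fov_r, c, occupied)
    ma_mask &= fov
    hem_mask &= fov
    ex_mask &= fov

    img[ma_mask] *= np.array([0.35, 0.22, 0.4])
    img[hem_mask] *= np.array([0.30, 0.18, 0.35])
    img[ex_mask] = img[ex_mask] * 0.2 + np.array([0.95, 0.9, 0.25]) * 0.8

    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=img.shape)
        img += noise * fov[..., None]

    img = np.clip(img, 0.0, 1.0)
    return SyntheticScene(
        image=img,
        disc_mask=disc_mask,
        vessel_mask=vessel_mask,
        ma_mask=ma_mask,
        hem_mask=hem_mask,
        ex_mask=ex_mask,
        grade=int(grade),
        seed=int(seed),
    )


def generate_dataset(
    n_per_grade: dict[int, int],
    seed: int,
    config: SceneConfig | None = None,
    out_dir=None,
):
    """Generate a dataset of scenes plus a ``path,grade,seed`` manifest.

    If ``out_dir`` is given, images and 0/255 masks are written as PNG files;
    otherwise the paths in the manifest are virtual identifiers.
    """
    config = config or SceneConfig()
    scenes: list[SyntheticScene] = []
    rows = []
    for grade in sorted(n_per_grade):
        count = n_per_grade[grade]
        if count < 0:
            raise ValueError("counts must be >= 0")
        for i in range(count):
            scene_seed = int(seed) * 100003 + grade * 1009 + i
            scene = generate_scene(grade, scene_seed, config)
            scenes.append(scene)
            name = f"scene_g{grade}_s{scene_seed}.png"
            if out_dir is not None:
                _write_scene(scene, out_dir, name)
                path = str(out_dir / name) if hasattr(out_dir, "/") else f"{out_dir}/{name}"
            else:
                path = name
            rows.append({"path": path, "grade": grade, "seed": scene_seed})
    manifest = pd.DataFrame(rows, columns=["path", "grade", "seed"])
    return scenes, manifest


def _write_scene(scene: SyntheticScene, out_dir, name: str) -> None:
    import os

    from PIL import Image

    os.makedirs(str(out_dir), exist_ok=True)
    img8 = (scene.image * 255).round().astype(np.uint8)
    Image.fromarray(img8).save(os.path.join(str(out_dir), name))
    stem = name.rsplit(".", 1)[0]
    for key in ("disc", "vessel", "ma", "hem", "ex"):
        mask = getattr(scene, f"{key}_mask")
        Image.fromarray((mask * 255).astype(np.uint8)).save(
            os.path.join(str(out_dir), f"{stem}_{key}.png")
        )
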