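"""Classical lesion-prior extraction and the 4-level Haar decomposition.

The prior stack P holds one channel per structure class, each in [0, 1]:

* ``vessels`` — Frangi vesselness followed by morphological cleanup,
* ``ma``      — Laplacian-of-Gaussian blob detection on the inpainted,
  inverted green channel (microaneurysms),
* ``hem``     — local adaptive thresholding with size/shape filtering
  (hemorrhages), vessel pixels excluded,
* ``ex``      — white top-hat enhancement + Otsu thresholding after optic
  disc suppression (exudates).

The Haar pyramid uses the orthonormal convention (each 2-D level divides by
2), chosen so that energy is conserved and the inverse transform is exact;
odd dimensions are edge-padded to even per level, with the padding recorded
for exact inversion.

All detector constants below are configuration defaults tuned for the 644
working resolution; none are learned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters as skfilters
from skimage import measure as skmeasure
from skimage import morphology as skmorph
from skimage.feature import blob_log
from skimage.restoration import inpaint_biharmonic
from skimage.transform import resize as _sk_resize

logger = logging.getLogger(__name__)

__all__ = [
    "PriorConfig",
    "PriorStack",
    "HaarPyramid",
    "suppress_optic_disc",
    "extract_vessels",
    "detect_microaneurysms",
    "detect_exudates",
    "detect_hemorrhages",
    "build_prior_stack",
    "resize_prior_stack",
    "haar_decompose",
    "haar_reconstruct",
]

_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class PriorConfig:
    """Constants for the classical detectors (644-pixel working scale)."""

    frangi_sigmas: tuple = (1.0, 2.0, 3.0, 4.0)
    vessel_threshold: float = 0.10       # on the normalized vesselness map
    vessel_min_size: int = 30            # px, morphological cleanup
    log_min_sigma: float = 1.0
    log_max_sigma: float = 3.0
    log_num_sigma: int = 5
    log_threshold: float = 0.05
    ma_min_contrast: float = 0.08        # blob center vs surrounding annulus
    tophat_radius: int = 15              # structuring element, px
    tophat_closing_radius: int = 4       # fills thin dark vessels beforehand
    ex_min_response: float = 0.10        # absolute floor on the top-hat response
    adaptive_block: int = 31             # local-mean window, px (odd)
    adaptive_offset: float = 0.05
    hem_area_range: tuple = (20, 2000)   # px
    hem_max_eccentricity: float = 0.98
    hem_min_solidity: float = 0.40
    fov_threshold: float = 0.05          # fraction of max intensity
    fov_erosion: int = 5                 # px, keeps the FOV rim out of play


@dataclass
class PriorStack:
    """Multi-channel lesion-prior tensor (channels in [0, 1])."""

    vessels: np.ndarray
    ma: np.ndarray
    hem: np.ndarray
    ex: np.ndarray
    vessel_density: float

    @property
    def stacked(self) -> np.ndarray:
        """H x W x 4 tensor, channel order (vessels, ma, hem, ex)."""
        return np.stack([self.vessels, self.ma, self.hem, self.ex], axis=-1)


def _fov_interior(rgb: np.ndarray, config: "PriorConfig") -> np.ndarray:
    """Eroded field-of-view mask: lesion detections on the dark rim of the
    circular field are artifacts of the aperture edge, not pathology."""
    intensity = rgb @ _LUMA if rgb.ndim == 3 else rgb
    peak = intensity.max()
    if peak <= 0:
        return np.ones(intensity.shape, dtype=bool)
    fov = intensity > config.fov_threshold * peak
    fov = ndimage.binary_fill_holes(fov)
    if fov.all():
        return fov
    return ndimage.binary_erosion(fov, skmorph.disk(config.fov_erosion))


def _vessel_like(vessel_mask: np.ndarray, min_length: float = 25.0) -> np.ndarray:
    """Curvilinear components of a vessel mask (skips blob-shaped ones).

    The Frangi response also rings on the rims of dark round lesions; using
    the raw mask to exclude vasculature would erase the lesions themselves.
    A vessel segment is elongated or branching (high eccentricity or low
    solidity) AND long — rims of small blobs fail the length test.
    """
    out = np.zeros(vessel_mask.shape, dtype=bool)
    for prop in skmeasure.regionprops(skmeasure.label(vessel_mask)):
        if prop.axis_major_length < min_length:
            continue
        if prop.eccentricity > 0.9 or prop.solidity < 0.5:
            out[tuple(prop.coords.T)] = True
    return out


def _auto_disc_mask(rgb: np.ndarray) -> np.ndarray:
    """Brightest-blob heuristic: top-2% intensity, largest component, dilated."""
    intensity = rgb @ _LUMA if rgb.ndim == 3 else rgb
    if np.ptp(intensity) < 1e-6:  # no bright structure to find
        return np.zeros(intensity.shape, dtype=bool)
    thr = np.quantile(intensity, 0.98)
    cand = intensity >= thr
    lbl, n = ndimage.label(cand)
    if n == 0:
        return np.zeros(intensity.shape, dtype=bool)
    sizes = ndimage.sum(cand, lbl, index=np.arange(1, n + 1))
    mask = lbl == (1 + int(np.argmax(sizes)))
    if mask.mean() > 0.10:  # implausibly large for an optic disc
        return np.zeros(intensity.shape, dtype=bool)
    return skmorph.dilation(mask, skmorph.disk(3))


def suppress_optic_disc(rgb: np.ndarray, disc_mask: np.ndarray | None = None):
    """Inpaint the optic disc region; everything outside the mask is unchanged.

    Returns ``(rgb_inpainted, disc_mask_used)``.  When no mask is supplied a
    brightest-blob heuristic locates the disc (logged).
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if disc_mask is None:
        disc_mask = _auto_disc_mask(rgb)
        logger.info("optic disc auto-detected (%d px)", int(disc_mask.sum()))
    disc_mask = np.asarray(disc_mask, dtype=bool)
    if not disc_mask.any():
        return rgb.copy(), disc_mask
    channel_axis = -1 if rgb.ndim == 3 else None
    out = inpaint_biharmonic(rgb, disc_mask, channel_axis=channel_axis)
    return np.clip(out, 0.0, 1.0), disc_mask


def extract_vessels(gray: np.ndarray, config: PriorConfig | None = None):
    """Frangi vesselness + cleanup -> (vesselness, binary mask, density)."""
    config = config or PriorConfig()
    gray = np.asarray(gray, dtype=np.float64)
    vness = skfilters.frangi(
        gray, sigmas=config.frangi_sigmas, black_ridges=True
    )
    peak = vness.max()
    if peak > 0:
        vness = vness / peak
    mask = vness > config.vessel_threshold
    mask = skmorph.remove_small_objects(mask, max_size=config.vessel_min_size - 1)
    return vness, mask, float(mask.mean())


def detect_microaneurysms(
    rgb: np.ndarray,
    disc_mask: np.ndarray | None = None,
    config: PriorConfig | None = None,
    vessel_mask: np.ndarray | None = None,
):
    """LoG blob detection on the inpainted, inverted green channel.

    Returns ``(blobs, prior_map)`` where ``blobs`` is an (n, 3) array of
    (row, col, sigma) and the prior map carries a unit-height Gaussian bump
    at each detection.  Blobs on the disc, on the vasculature (when a vessel
    mask is given) or on the field-of-view rim are discarded — all three are
    dark/round-ish confounders of microaneurysms.
    """
    config = config or PriorConfig()
    rgb = np.asarray(rgb, dtype=np.float64)
    green = rgb[..., 1] if rgb.ndim == 3 else rgb
    if disc_mask is None:
        disc_mask = _auto_disc_mask(rgb)
    if disc_mask.any():
        green = inpaint_biharmonic(green, disc_mask)
    interior = _fov_interior(rgb, config)
    inv = 1.0 - green
    blobs = blob_log(
        inv,
        min_sigma=config.log_min_sigma,
        max_sigma=config.log_max_sigma,
        num_sigma=config.log_num_sigma,
        threshold=config.log_threshold,
    )
    if vessel_mask is not None and vessel_mask.any():
        # only curvilinear components: the Frangi response also rings on the
        # microaneurysm itself, which must not veto its own detection
        vexcl = skmorph.dilation(
            _vessel_like(np.asarray(vessel_mask, dtype=bool)), skmorph.disk(1)
        )
    else:
        vexcl = np.zeros(green.shape, dtype=bool)
    h, w = green.shape
    yy0, xx0 = np.mgrid[0:h, 0:w]
    keep = []
    for y, x, s in blobs:
        yi, xi = int(round(y)), int(round(x))
        if disc_mask[yi, xi] or not interior[yi, xi] or vexcl[yi, xi]:
            continue
        # isolated-dot test: the blob core must be darker than its annulus,
        # which must itself be clean background (rejects vessel junctions)
        d2 = (yy0 - y) ** 2 + (xx0 - x) ** 2
        core = d2 <= max(s, 1.0) ** 2
        ring = (d2 > (2 * s) ** 2) & (d2 <= (3 * s) ** 2)
        if ring.sum() == 0 or core.sum() == 0:
            continue
        # upper-quantile of the annulus: a dark structure passing through
        # the surround (a vessel limb or tip) disqualifies the candidate
        if inv[core].mean() - np.quantile(inv[ring], 0.8) < config.ma_min_contrast:
            continue
        keep.append((y, x, s))
    blobs = np.array(keep).reshape(-1, 3)
    prior = np.zeros(green.shape, dtype=np.float64)
    if len(blobs):
        yy, xx = np.mgrid[0 : green.shape[0], 0 : green.shape[1]]
        for y, x, s in blobs:
            bump = np.exp(-(((yy - y) ** 2 + (xx - x) ** 2) / (2 * s**2)))
            np.maximum(prior, bump, out=prior)
    return blobs, prior


def detect_exudates(
    rgb: np.ndarray,
    disc_mask: np.ndarray | None = None,
    config: PriorConfig | None = None,
) -> np.ndarray:
    """White top-hat + Otsu after optic-disc suppression -> binary map."""
    config = config or PriorConfig()
    rgb = np.asarray(rgb, dtype=np.float64)
    suppressed, disc_mask = suppress_optic_disc(rgb, disc_mask)
    gray = suppressed @ _LUMA if suppressed.ndim == 3 else suppressed
    # closing fills thin dark vessels so gaps between them do not masquerade
    # as bright blobs in the top-hat residue
    closed = skmorph.closing(gray, skmorph.disk(config.tophat_closing_radius))
    tophat = skmorph.white_tophat(closed, skmorph.disk(config.tophat_radius))
    if np.ptp(tophat) < 1e-12:
        logger.warning("degenerate top-hat response; returning empty exudate map")
        return np.zeros(gray.shape, dtype=bool)
    thr = max(skfilters.threshold_otsu(tophat), config.ex_min_response)
    mask = tophat > thr
    mask &= ~skmorph.dilation(disc_mask, skmorph.disk(3))
    mask &= _fov_interior(rgb, config)
    mask = skmorph.remove_small_objects(mask, max_size=4)
    return mask


def detect_hemorrhages(
    rgb: np.ndarray,
    vessel_mask: np.ndarray | None = None,
    config: PriorConfig | None = None,
) -> np.ndarray:
    """Adaptive thresholding + size/shape filtering -> binary map.

    Vessel pixels are excluded before component analysis to avoid mistaking
    elongated vessel segments for hemorrhages; surviving components must fall
    in the configured area range, be sufficiently round (eccentricity bound)
    and sufficiently solid.
    """
    config = config or PriorConfig()
    rgb = np.asarray(rgb, dtype=np.float64)
    green = rgb[..., 1] if rgb.ndim == 3 else rgb
    inv = 1.0 - green
    local_mean = skfilters.threshold_local(
        inv, block_size=config.adaptive_block, method="mean"
    )
    interior = _fov_interior(rgb, config)
    if vessel_mask is not None and np.asarray(vessel_mask).any():
        not_vessel = ~skmorph.dilation(
            _vessel_like(np.asarray(vessel_mask, dtype=bool)), skmorph.disk(1)
        )
    else:
        not_vessel = np.ones(inv.shape, dtype=bool)
    dark = (inv > local_mean + config.adaptive_offset) & interior & not_vessel
    out = np.zeros(dark.shape, dtype=bool)
    lo, hi = config.hem_area_range
    for prop in skmeasure.regionprops(skmeasure.label(dark)):
        if not (lo <= prop.area <= hi):
            continue
        if prop.eccentricity >= config.hem_max_eccentricity:
            continue
        if prop.solidity < config.hem_min_solidity:
            continue
        out[tuple(prop.coords.T)] = True
    if not out.any():
        return out
    # the adaptive threshold undershoots blob extent (the blob raises its own
    # local mean); grow accepted components inside a looser dark support
    support = (inv > local_mean + config.adaptive_offset / 2) & interior & not_vessel
    grown = skmorph.reconstruction(
        out & support, support | out, method="dilation"
    ).astype(bool)
    for prop in skmeasure.regionprops(skmeasure.label(grown)):
        if prop.area > hi:  # a grown component leaking into background
            grown[tuple(prop.coords.T)] = False
    return grown | out


def build_prior_stack(
    rgb: np.ndarray,
    disc_mask: np.ndarray | None = None,
    config: PriorConfig | None = None,
) -> PriorStack:
    """Run all four detectors and stack their maps (vessels, ma, hem, ex)."""
    config = config or PriorConfig()
    rgb = np.asarray(rgb, dtype=np.float64)
    if disc_mask is None:
        disc_mask = _auto_disc_mask(rgb)
    gray = rgb @ _LUMA if rgb.ndim == 3 else rgb
    vness, vmask, density = extract_vessels(gray, config)
    _, ma_map = detect_microaneurysms(rgb, disc_mask, config, vessel_mask=vmask)
    hem_map = detect_hemorrhages(rgb, vmask, config)
    ex_map = detect_exudates(rgb, disc_mask, config)
    return PriorStack(
        vessels=np.clip(vness, 0, 1),
        ma=np.clip(ma_map, 0, 1),
        hem=hem_map.astype(np.float64),
        ex=ex_map.astype(np.float64),
        vessel_density=density,
    )


def resize_prior_stack(stack: np.ndarray, size: int) -> np.ndarray:
    """Bilinear-resize an H x W x K prior tensor to size x size, clamped."""
    out = _sk_resize(stack, (size, size), order=1, mode="reflect", anti_aliasing=False)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Haar pyramid


@dataclass
class HaarPyramid:
    """Four-level orthonormal 2-D Haar decomposition.

    ``levels[i]`` holds the approximation band ``LW`` after level ``i+1``
    plus the three detail bands ``HI_1`` (horizontal), ``HI_2`` (vertical)
    and ``HI_3`` (diagonal) and the edge padding applied at that level.
    """

    levels: list = field(default_factory=list)
    input_shape: tuple = ()

    @property
    def approximation(self) -> np.ndarray:
        return self.levels[-1]["LW"]


def _haar_forward_level(x: np.ndarray):
    pad = (x.shape[0] % 2, x.shape[1] % 2)
    if pad[0] or pad[1]:
        x = np.pad(x, ((0, pad[0]), (0, pad[1])), mode="edge")
    a = x[0::2, 0::2]
    b = x[0::2, 1::2]
    c = x[1::2, 0::2]
    d = x[1::2, 1::2]
    lw = (a + b + c + d) / 2.0
    hi1 = (a - b + c - d) / 2.0   # horizontal detail
    hi2 = (a + b - c - d) / 2.0   # vertical detail
    hi3 = (a - b - c + d) / 2.0   # diagonal detail
    return lw, hi1, hi2, hi3, pad


def _haar_inverse_level(lw, hi1, hi2, hi3, pad, out_shape):
    a = (lw + hi1 + hi2 + hi3) / 2.0
    b = (lw - hi1 + hi2 - hi3) / 2.0
    c = (lw + hi1 - hi2 - hi3) / 2.0
    d = (lw - hi1 - hi2 + hi3) / 2.0
    h2, w2 = lw.shape
    x = np.empty((2 * h2, 2 * w2), dtype=lw.dtype)
    x[0::2, 0::2] = a
    x[0::2, 1::2] = b
    x[1::2, 0::2] = c
    x[1::2, 1::2] = d
    return x[: out_shape[0], : out_shape[1]]


def haar_decompose(gray: np.ndarray, levels: int = 4) -> HaarPyramid:
    """Recursive orthonormal Haar transform of the approximation band."""
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError("haar_decompose expects a 2-D image")
    if min(gray.shape) < 2**levels:
        raise ValueError(
            f"input of shape {gray.shape} too small for {levels} levels"
        )
    pyr = HaarPyramid(input_shape=gray.shape)
    current = gray
    for _ in range(levels):
        in_shape = current.shape
        lw, hi1, hi2, hi3, pad = _haar_forward_level(current)
        pyr.levels.append(
            {
                "LW": lw,
                "HI_1": hi1,
                "HI_2": hi2,
                "HI_3": hi3,
                "pad": pad,
                "in_shape": in_shape,
            }
        )
        current = lw
    return pyr


def haar_reconstruct(pyr: HaarPyramid) -> np.ndarray:
    """Exact inverse of :func:`haar_decompose`."""
    current = pyr.levels[-1]["LW"]
    for entry in reversed(pyr.levels):
        current = _haar_inverse_level(
            current,
            entry["HI_1"],
            entry["HI_2"],
            entry["HI_3"],
            entry["pad"],
            entry["in_shape"],
        )
    return current
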