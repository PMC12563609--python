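"""Per-image feature extraction (20 descriptors) and per-grade summaries.

The descriptor set covers the categories used for biomarker interpretation:
lesion counts and areas (MA / HEM / EX), vessel density, intensity
statistics, gray-level co-occurrence texture statistics, morphological shape
measures of lesion components, and spatial context relative to the optic
disc.  Six of the names (``hm_count``, ``ex_count``, ``vessel_density``,
``int_mean``, ``tx_contrast_mean``, ``tx_homogeneity_mean``) are the canonical
radar-chart labels; the remaining fourteen complete a fixed, reproducible
schema within the same categories.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure as skmeasure
from skimage.feature import graycomatrix, graycoprops

from .preprocess import PreprocessedImage
from .priors import PriorStack

FEATURE_NAMES = (
    "hm_count",
    "hm_area",
    "ex_count",
    "ex_area",
    "ma_count",
    "ma_area",
    "vessel_density",
    "int_mean",
    "int_std",
    "tx_contrast_mean",
    "tx_homogeneity_mean",
    "tx_energy",
    "tx_entropy",
    "tx_correlation",
    "shape_eccentricity_mean",
    "shape_solidity_mean",
    "shape_compactness_mean",
    "lesion_area_frac",
    "disc_distance_mean",
    "count_total",
)

GLCM_LEVELS = 32
GLCM_OFFSETS = ((0, 1), (1, 0))  # distance-1 horizontal and vertical

__all__ = ["FEATURE_NAMES", "extract_features", "summarize_by_grade"]


def _count_components(mask: np.ndarray) -> int:
    return int(ndimage.label(np.asarray(mask) > 0.5)[1])


def _glcm_stats(gray: np.ndarray) -> dict:
    q = np.clip((gray * (GLCM_LEVELS - 1)).round().astype(int), 0, GLCM_LEVELS - 1)
    distances = [1]
    angles = [0.0, np.pi / 2]  # offsets (0,1) and (1,0)
    glcm = graycomatrix(
        q.astype(np.uint8),
        distances=distances,
        angles=angles,
        levels=GLCM_LEVELS,
        symmetric=True,
        normed=True,
    )
    contrast = graycoprops(glcm, "contrast").mean()
    homogeneity = graycoprops(glcm, "homogeneity").mean()
    energy = graycoprops(glcm, "energy").mean()
    correlation = graycoprops(glcm, "correlation").mean()
    p = glcm.reshape(GLCM_LEVELS * GLCM_LEVELS, -1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -(p * np.log2(p, where=p > 0, out=np.zeros_like(p))).sum(axis=0)
    return {
        "tx_contrast_mean": float(contrast),
        "tx_homogeneity_mean": float(homogeneity),
        "tx_energy": float(energy),
        "tx_entropy": float(ent.mean()),
        "tx_correlation": float(np.nan_to_num(correlation)),
    }


def _shape_stats(lesion_mask: np.ndarray, disc_mask: np.ndarray | None, size: int):
    props = skmeasure.regionprops(skmeasure.label(lesion_mask))
    if not props:
        return {
            "shape_eccentricity_mean": 0.0,
            "shape_solidity_mean": 0.0,
            "shape_compactness_mean": 0.0,
            "disc_distance_mean": 0.0,
        }
    ecc, sol, comp, dist = [], [], [], []
    if disc_mask is not None and disc_mask.any():
        dy, dx = ndimage.center_of_mass(disc_mask)
    else:
        dy = dx = (size - 1) / 2.0
    for p in props:
        ecc.append(p.eccentricity)
        sol.append(p.solidity)
        per = max(p.perimeter, 1.0)
        comp.append(min(4 * np.pi * p.area / per**2, 1.0))
        cy, cx = p.centroid
        dist.append(np.hypot(cy - dy, cx - dx) / size)
    return {
        "shape_eccentricity_mean": float(np.mean(ecc)),
        "shape_solidity_mean": float(np.mean(sol)),
        "shape_compactness_mean": float(np.mean(comp)),
        "disc_distance_mean": float(np.mean(dist)),
    }


def extract_features(
    preprocessed: PreprocessedImage,
    priors: PriorStack,
    disc_mask: np.ndarray | None = None,
) -> dict:
    """Compute the 20 named descriptors for one image.

    Counts are connected components of the binarized prior maps; areas are
    pixel fractions of the field; texture statistics come from a symmetric
    32-level gray co-occurrence matrix at distance-1 horizontal/vertical
    offsets on the normalized gray image.
    """
    gray = preprocessed.gray
    n_px = gray.size
    hem = priors.hem > 0.5
    ex = priors.ex > 0.5
    ma = priors.ma > 0.5
    lesions = hem | ex | ma

    values = {
        "hm_count": float(_count_components(hem)),
        "hm_area": float(hem.sum()) / n_px,
        "ex_count": float(_count_components(ex)),
        "ex_area": float(ex.sum()) / n_px,
        "ma_count": float(_count_components(ma)),
        "ma_area": float(ma.sum()) / n_px,
        "vessel_density": float(priors.vessel_density),
        "int_mean": float(gray.mean()),
        "int_std": float(gray.std()),
    }
    values.update(_glcm_stats(gray))
    values.update(_shape_stats(lesions, disc_mask, gray.shape[0]))
    values["lesion_area_frac"] = float(lesions.sum()) / n_px
    values["count_total"] = (
        values["hm_count"] + values["ex_count"] + values["ma_count"]
    )
    assert set(values) == set(FEATURE_NAMES)
    return {name: values[name] for name in FEATURE_NAMES}


def summarize_by_grade(table: pd.DataFrame):
    """Per-grade arithmetic means plus radar-normalized data.

    ``table`` must carry a ``grade`` column and the 20 feature columns.
    Returns ``(summary, radar)`` where ``radar`` rescales each feature to
    [0, 1] across grades (constant features map to 0).
    """
    if len(table) == 0:
        raise ValueError("feature table is empty")
    if "grade" not in table.columns:
        raise ValueError("feature table must have a 'grade' column")
    cols = [c for c in FEATURE_NAMES if c in table.columns]
    summary = table.groupby("grade", sort=True)[cols].mean()
    span = summary.max() - summary.min()
    radar = (summary - summary.min()) / span.where(span > 0, 1.0)
    radar = radar.where(span > 0, 0.0)
    return summary, radar
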