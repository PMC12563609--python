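"""Compute the 20-descriptor feature vector per image and summarize by grade.

The per-grade means of the radar features (hemorrhage count, exudate count,
vessel density, mean intensity, texture contrast/homogeneity) track disease
severity.
"""

import numpy as np
import pandas as pd

from drwnet.features import extract_features, summarize_by_grade
from drwnet.preprocess import PreprocessedImage, to_gray_norm
from drwnet.priors import build_prior_stack
from drwnet.synth import SceneConfig, generate_scene

rows = []
for grade in range(5):
    for seed in range(4):
        scene = generate_scene(grade, seed, SceneConfig(size=256))
        pre = PreprocessedImage(
            rgb=scene.image,
            gray=to_gray_norm(scene.image),
            edge_map=np.zeros(scene.image.shape[:2], dtype=bool),
        )
        stack = build_prior_stack(scene.image, disc_mask=scene.disc_mask)
        rows.append(
            {**extract_features(pre, stack, disc_mask=scene.disc_mask), "grade": grade}
        )

summary, radar = summarize_by_grade(pd.DataFrame(rows))
radar_cols = ["hm_count", "ex_count", "vessel_density", "int_mean",
              "tx_contrast_mean", "tx_homogeneity_mean"]
print(summary[radar_cols].round(3).to_string())
print(
    "\nPer-grade means of the six radar descriptors: lesion counts rise with"
    "\nseverity while intensity/texture statistics shift as lesions accumulate."
)
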