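"""Generate synthetic fundus scenes and inspect grade-dependent lesion burden.

Each scene is a fundus-like RGB image with ground-truth masks for the optic
disc, vessel tree, microaneurysms (MA), hemorrhages (HEM) and exudates (EX),
plus an ICDR grade 0-4.  Lesion burden rises with grade; grade 1 carries
microaneurysms only.
"""

import numpy as np

from drwnet.synth import SceneConfig, generate_scene

config = SceneConfig(size=256)
print(f"{'grade':>5} {'MA px':>7} {'HEM px':>7} {'EX px':>7} {'lesion %':>9}")
for grade in range(5):
    areas = []
    for seed in range(5):
        s = generate_scene(grade, seed, config)
        areas.append(
            (s.ma_mask.sum(), s.hem_mask.sum(), s.ex_mask.sum(), s.lesion_mask.mean())
        )
    ma, hem, ex, frac = np.mean(areas, axis=0)
    print(f"{grade:>5} {ma:>7.0f} {hem:>7.0f} {ex:>7.0f} {100 * frac:>8.2f}%")

print(
    "\nMean lesion pixel counts over 5 seeds per grade: grade 0 is lesion-free,"
    "\ngrade 1 shows only microaneurysms, and total burden rises monotonically."
)
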