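"""From instance ground truth to three-class training patches.

Converts an instance mask into the contour / center / background
annotation with clumped-gap loss weights, then assembles 64x64 training
patches in which the defocused and saturated variants of each tile share
the identical target.
"""

import numpy as np

from triseg import simdata
from triseg.datasets import assemble_real_augmented_set, split_dataset, SplitConfig
from triseg.labels import instance_to_annotation

from dataclasses import replace

base = simdata.preset("dense", field_shape=(128, 128), n_nuclei=15)
specimens = [
    simdata.simulate_specimen(replace(base, seed=s)) for s in range(5)
]
pack = instance_to_annotation(specimens[0].instances, contour_width_px=2, gap_weight=3.0)
counts = np.bincount(pack.classmap.ravel(), minlength=3)
print(f"background/contour/center pixels: {counts[0]}/{counts[1]}/{counts[2]}")
print(f"gap-weighted pixels: {(pack.gapweight > 1).sum()} (weight 3 between clumped nuclei)")

patches = assemble_real_augmented_set(
    specimens,
    channels=("dna",),
    real=("defocus_plus", "defocus_minus", "saturated"),
    patch_size_px=64,
)
print(f"{len(patches)} patches (4 per tile position: in-focus + 3 artefact variants)")
train, val, test = split_dataset(
    patches, SplitConfig(ratios=(0.36, 0.24, 0.40), seed=0)
)
# Splitting is tile-level: all patches and artefact variants of one tile
# land in the same subset, so artefacts never leak across splits.
print(f"split sizes (tile-level): {len(train)}/{len(val)}/{len(test)}")
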