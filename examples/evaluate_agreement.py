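"""Score a prediction (or a second annotator) against reference masks.

The sweeping-IoU curve reports the fraction of reference nuclei whose
best one-to-one match reaches each IoU threshold from 0.55 to 0.80;
F1/precision/recall/AP summarize detection at the conventional 50%
overlap.  The same machinery measures inter-observer agreement between
two annotation sets.
"""

import numpy as np
from scipy import ndimage as ndi

from triseg import simdata
from triseg.metrics import annotator_agreement

spec = simdata.simulate_specimen(
    simdata.preset("dense", field_shape=(192, 192), n_nuclei=30, seed=13)
)
ann_a = spec.instances

# emulate a second annotator: slightly tighter outlines, one missed cell
ann_b = np.zeros_like(ann_a)
for lab in np.unique(ann_a[ann_a > 0]):
    if lab == 5:
        continue  # annotator B missed this nucleus
    eroded = ndi.binary_erosion(ann_a == lab)
    ann_b[eroded] = lab

scores, curve = annotator_agreement(ann_a, ann_b)
print(f"agreement F1@0.5 = {scores.f1:.3f}  (AP {scores.ap:.3f})")
print("retained fraction by IoU threshold:")
for t, f in zip(curve.thresholds, curve.retained_fraction):
    print(f"  {t:.2f}: {f:.3f}")
# Tighter outlines cost little at 0.55 but increasingly more toward
# 0.80 — the stringent end of the sweep is sensitive to mask shape, not
# just detection.
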