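"""The two headline comparisons, at a small demonstration scale.

(1) Real vs computed augmentation: three DNA-only models — unaugmented
(+rotations), Gaussian-blur augmented, and real defocus/saturation
augmented — evaluated on defocused test tiles.
(2) NES scenarios: B = DNA only, C = DNA+NES, D = DNA+NES+real
augmentation, all tested on defocused data.

This demonstration uses the minimum allowed seeds/tiles and runs in
roughly 15 minutes on one CPU; the test suite runs the same comparisons
at the documented scale.
"""

import numpy as np

from triseg.experiments import run_augmentation_comparison, run_scenarios

print("== real vs computed augmentation (defocused test) ==")
rep = run_augmentation_comparison(sim_preset="dense", n_tiles=12, seeds=(0, 1, 2))
for arm in ("unaugmented", "gaussian", "real"):
    mean, sem = rep.mean_sem(arm)
    print(f"  {arm:12s} retained@0.60 = {mean[1]:.3f} +/- {sem[1]:.3f}")

print("== NES + real augmentation scenarios (defocused test) ==")
rep2 = run_scenarios(scenarios=("B", "C", "D"), seeds=(0, 1, 2))
for name in ("B", "C", "D"):
    med = float(np.median(rep2.retained_at(name, 0.60)))
    print(f"  scenario {name}: median retained@0.60 = {med:.3f}")
# Expected orderings: real >= gaussian >= unaugmented, and D >= C >= B.
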