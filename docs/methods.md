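# Methods

## The problem

Whole-slide fluorescence images of tissue are never uniformly in focus
and routinely contain saturated cells: the depth of field of high-NA
objectives is smaller than section thickness, and sections are not
coplanar with the coverslip. Segmentation models trained only on clean
fields degrade badly on such data. Two remedies are implemented here:
training with *real* artefact acquisitions (defocused ±z and saturated
frames registered to the in-focus image, sharing one annotation set) and
adding a *nuclear-envelope staining* (NES) channel that outlines nuclei
directly. The package implements the full loop — simulation, annotation,
training, instance extraction, evaluation, quantification — so both
remedies can be exercised and measured without any external data.

## Specimen simulator

A specimen is a noiseless scene of elliptical nuclei on a dim
autofluorescence floor (0.04 of nominal full scale), from which five
registered channels are rendered. Defaults describe a 20× acquisition
down-sampled 2× to 0.65 µm/px.

**Geometry.** Nuclei are rejection-sampled ellipses: equivalent radius
uniform in 3.0–5.5 µm, a configurable fraction elongated with axis
ratio 1.6–2.6, orientation uniform. `sparse` packing enforces a 4-px
clearance; `dense` allows touching but never overlapping instances;
`clumped` concentrates centers around cluster sites. Instance labels
are positive integers, each one 4-connected component; placement that
cannot satisfy the density raises rather than silently degrading. A
placement drawing more nuclei than fit simply stops at the achievable
count after a bounded number of attempts.

**Defocus.** Out-of-focus blur is modelled as convolution with a
uniform disk (pillbox) of radius `r = c·|z| / pixel_size` with c = 1
(unitless, NA-like), i.e. ≈ 4.6 px at z = 3 µm. The below-focus kernel
is 1.3× wider (`asymmetry_factor`), reflecting the above/below
asymmetry of real optics. A pillbox rather than a Gaussian is a
deliberate modelling choice: if simulated defocus were Gaussian, the
comparison between real-defocus augmentation and computed Gaussian-blur
augmentation would be vacuous. The true kernel of any given microscope
is unknown and certainly not exactly a pillbox; the kernel family and
its constants are therefore configuration, not physics (a Gaussian
option exists). No attempt is made at rigorous PSF models (Born–Wolf
etc.) or 3-D stacks.

**Saturation.** The saturated channel is `clip(gain · image)` at the
detector maximum. With `saturation_exposure="auto"` the gain is found by
bisection so that 70–80 % of *foreground* (nucleus) pixels saturate —
the acquisition target for long-exposure frames. Saturation is monotone
in gain by construction.

**Noise and quantization.** Poisson shot noise (≈100 photons on a
unit-intensity pixel, SNR ≈ 10 on nuclei) plus additive Gaussian read
noise (σ = 2 counts) are applied after blurring and before clipping to
the 16-bit range; the nominal full scale maps to ~30 % of the dtype
range so the saturated channel has headroom.

**NES.** The envelope stain is an annulus of configurable width
(default 1 µm) around each instance boundary, rendered for a
configurable fraction of nuclei. `nes_irregularity` ∈ [0, 1] blends the
clean ring toward a diffuse, perturbed envelope, emulating the folded
and invaginated envelopes of many cell types (the
`glioblastoma-like` preset uses 0.8).

**What the simulator does not emulate** — and hence what passing tests
do not show about real tissue: chromatin substructure beyond smooth
texture, overlapping nuclei in z projection, stain spectral bleed,
stitching seams, anisotropic or spatially varying blur, and true
annotation noise. Results on simulated fields demonstrate that the
machinery behaves as designed, not that any particular accuracy will be
achieved on tissue.

## Annotation model

Training targets mirror a manual protocol in which annotators draw
closed nucleus contours that are then filled to produce centers:

* **contour** = instance minus its 4-connected erosion iterated
  `contour_width_px` times (default 2 px). Contours are *inner*
  boundaries, so touching nuclei retain distinct contours.
* **center** = the remaining interior.
* **clumped-cell gap** = background pixels within `gap_radius_px`
  (default 2) of two or more distinct instances. The gap is encoded as
  a loss *weight* (default 3) rather than a fourth class: the model
  stays three-class while mistakes between clumped nuclei are penalized
  extra. The gap magnitude and the loss weighting are exposed as
  configuration because no canonical value exists.
* **border nuclei** cannot carry a closed contour; they are annotated
  center-only and contribute a centroid to `border_centers`.

`fill_contours` is 4-connected hole filling and is idempotent; on
sparse fields, filling the contour class reconstructs the foreground
exactly — an invariant the test suite asserts.

## Datasets

Tiles are normalized to full dynamic range (min→0, max→1; percentile
clipping optional; constant tiles map to zero) and cropped into 64×64
patches, row-major, partial windows dropped. Computed augmentation
applies 90°/180° rotations, reflections, 20 % upscaling (bilinear for
intensities, nearest-neighbour for label/weight maps, center-cropped
back) and optional Gaussian blur of the intensity channels (all
channels blurred together). Real augmentation emits, per tile, the
in-focus patch plus one patch per registered artefact channel, all
sharing a single target derived once from the instance map — target
arrays are literally shared, so bit-identity across variants holds by
construction.

Splits are 0.36 : 0.24 : 0.40 (train/val/test) with largest-remainder
rounding, deterministic per seed, at *tile* granularity: all patches
and artefact variants of a tile stay in one subset. Patch-level
splitting exists but leaks texture across subsets and is not the
default. When comparison arms differ in size, the smaller arm is padded
with rotated copies of its own patches (never subsampled), keeping
dataset size out of the comparison.

## Segmentation model

A standard UNet predicts per-pixel background/contour/center
probabilities. Reference defaults: 4 levels, 80 first-level features
doubling per level, batch normalization, dropout 0.35 at the bottom,
Adam at 5·10⁻⁵ decayed ×0.98 every 5000 steps, batch 32, ≤ ~100 epochs
with early stopping; "input features" is read as the first-level
convolutional feature count. The loss is per-pixel weighted
cross-entropy — the gap-weight map supplies the weights — plus an L1
term on convolution weights (coefficient 10⁻⁵ by default, normalized
per parameter); early stopping monitors validation loss (the natural
default given that the stopping metric is otherwise unspecified) and
the best-validation checkpoint is returned.

The engine is written directly in NumPy (im2col convolutions with
analytic gradients, channels-last layout), which keeps the package free
of deep-learning-framework dependencies and makes training bit-
deterministic for fixed seeds. The cost is scale: the working
configuration is the **tiny** model — depth 3, 8 base features, 64×64
patches, batch 8, learning rate 2·10⁻³, ≤ 500 optimizer steps — which
trains in about a minute on one CPU core and segments the simulated
fields nearly perfectly in focus. The experiment harness further caps
training at 200 steps per model so that a full multi-arm, multi-seed
comparison fits in minutes; these sizes are package defaults chosen for
desk-scale work, and every scale parameter is configuration. The
backprop implementation is verified against float64 finite differences
in the test suite. The model interface (build/train/predict) is the
extension point where other architectures could be plugged in.

Whole-image inference tiles the image (default 128 px tiles, 64 px
overlap) and averages logits before the softmax. Because convolutions
zero-pad internally, each tile's outer `overlap/2` band is excluded
from the blend except at image borders; with overlap comparable to the
receptive field, tiled and whole-image inference agree to < 10⁻⁴.

## Instance extraction

Probability maps become instances by marker-controlled watershed:
seeds are 4-connected components of `P_center ≥ 0.5` (≥ 5 px),
foreground is `1 − P_background ≥ 0.5`, and the topography is
`P_contour − P_center`, so contour evidence forms ridges between
touching nuclei. Components outside `[min_area, max_area]` are removed;
`min_area` defaults to the area of a 2.5 µm-radius disk at the working
pixel size (46 px). Labels are consecutive in raster order of seed
first-pixels and ties resolve by seed order, making the labeling fully
deterministic. Thresholds are exposed rather than fixed: downstream
pipelines tune this step per dataset.

## Evaluation

Matching between ground truth and prediction is a globally optimal
one-to-one assignment maximizing total IoU among pairs with IoU ≥ t
(solved as an assignment problem; exact ties prefer lower ids). Global
assignment was chosen over greedy matching because it is deterministic,
order-independent, and identical to greedy on the unambiguous cases
that dominate; the test suite proves it equal to exhaustive enumeration
for maps with ≤ 8 objects per side. The retained-fraction curve re-runs
the matching at every threshold of the 0.55–0.80 sweep (re-matching and
once-at-0.5 re-thresholding coincide wherever matches are unambiguous,
which is the dominant case; re-matching is the implemented, more
conservative choice). At 50 % overlap the counts give precision,
recall, F1 and AP = TP/(TP+FP+FN), with zero-denominator cases defined
as 0. Pixel accuracy is deliberately not offered: it rewards class
imbalance and says nothing about mask shape. `annotator_agreement`
scores one annotation set against another with the same machinery.

## Quantification and gating

Per-cell features are exact label-wise sums (float64) divided by areas,
so `Σ mean·area` reproduces the channel total over labeled pixels to
machine precision — exactly for integer images. Gating fits a
two-component univariate Gaussian mixture to `log(value + 1)` (natural
log; the pseudocount guards zeros) by EM with k-means initialization,
≤ 500 iterations, tolerance 10⁻⁶; a cell is positive when the
posterior of the higher-mean component exceeds 0.5, so component
relabeling can never flip calls. Fits with a component weight below
2 % or mean separation below 0.1 log units are flagged degenerate and
return all-negative. Gating is per-marker univariate; joint
multivariate gating is out of scope. Note the degeneracy guard is a
parameter heuristic: a genuinely unimodal but broad population can
still be split into two overlapping components without tripping it.

On statistical expectations: for two equal-variance populations whose
means differ by Δ, the best achievable assignment accuracy is
Φ(Δ/2σ). The gating tests therefore check near-Bayes recovery — ≥ 98 %
when means sit 3σ on either side of the decision midpoint, and within
two points of the empirical Bayes rate at 3σ total separation (where
the optimum itself is only ≈ 93 %).

## Experiments

Both scripted comparisons simulate 128×128 tiles (dense preset, ~15
nuclei per tile), split 0.36/0.24/0.40 at tile level, train the tiny
UNet 200 steps per arm, and evaluate on the test tiles — pooling the
above- and below-focus acquisitions for "defocused" testing. Within a
seed, every arm sees bit-identical specimens, so differences are
attributable to the training condition alone. Results are aggregated
as mean ± SEM over seeds per threshold (no hypothesis testing; with
3–5 seeds, orderings and SEM bands are the honest summary).

* **Augmentation comparison** (DNA only): unaugmented (+90/180°
  rotations), Gaussian-blur augmented (σ ∈ {1.5, 3} px, bracketing the
  matched-RMS width of the defocus kernels), and real augmentation
  (defocus ±z + saturated). Arms are rotation-padded to equal size.
  Expected ordering under defocused testing: real ≥ Gaussian ≥
  unaugmented.
* **Scenario grid**: A = DNA-only training, in-focus test; B = DNA-only,
  defocused test; C = DNA+NES, defocused test; D = DNA+NES + real
  augmentation, defocused test. Expected ordering: D ≥ C ≥ B. The NES
  channel at test time is the registered in-focus acquisition.

The default experiment scale (12 tiles, 200 steps, 5 seeds for the
augmentation comparison, 3 seeds for the scenario grid in the test
suite — the 5-seed scenario configuration is the documented full run
and runs identically via `run_scenarios(seeds=range(5))`) was fixed
once as the package's desk-scale condition.

## Numerical and degenerate-input choices

* Determinism: all randomness flows from `numpy.random.Generator`
  seeded explicitly; sub-seeds derive via `SeedSequence`; training,
  watershed labeling and matching tie-breaks are deterministic.
* Reflect padding for all image-domain convolutions (flux conserved to
  < 0.5 % for interior content); zero padding inside the network.
* Constant images normalize to zeros; empty instance maps yield empty
  annotations, empty feature tables and errors only where a quantity is
  undefined (curve with no ground truth, IoU of an empty mask, auto
  saturation without foreground).
* Masks are written 16-bit while labels fit, 32-bit beyond 65 535;
  float masks must be exactly integral.

## Known limitations

The NumPy engine makes full-scale training (80 features, tens of
thousands of patches) impractical — the package demonstrates the
methodology at desk scale rather than reproducing tissue-scale
accuracy numbers. The simulator's simplifications listed above mean
absolute retained fractions on simulated data are optimistic relative
to tissue. Mask R-CNN / PSPNet-style alternative backends are out of
scope (the pluggable model interface is the seam for them), as are
stitching, 3-D segmentation, cytoplasm expansion and
UMAP/HDBSCAN-style downstream clustering.
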