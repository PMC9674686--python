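# triseg

Three-class nuclei segmentation for multiplexed tissue images, built
around two ideas that make segmentation robust on real whole-slide data:

1. **Real augmentation** — training on empirically degraded acquisitions
   (the focal plane displaced ±3 µm, long-exposure saturated frames)
   registered to the in-focus image, so one set of annotations serves all
   variants. Real defocus is not Gaussian: this toolkit's simulator
   renders it with an asymmetric pillbox kernel precisely so that real
   and computed (Gaussian-blur) augmentation can be compared honestly.
2. **A nuclear-envelope staining (NES) channel** — lamin/nucleoporin-style
   staining as a second input channel alongside DNA, outlining nuclei
   whose chromatin signal alone is ambiguous.

The package is usable end-to-end with **no external data**: a built-in
specimen simulator generates registered channel stacks (in-focus DNA,
±z defocused DNA, saturated DNA, NES) with instance ground truth, for
several tissue-style presets (`sparse`, `dense`, `clumped`,
`glioblastoma-like`).

## What it contains

| module | role |
| --- | --- |
| `triseg.simdata` | specimen simulator: nucleus placement, pillbox defocus, auto-targeted saturation (70–80 % of foreground pixels), NES rings, Poisson–Gaussian camera noise |
| `triseg.labels` | instance masks → background/contour/center classes + clumped-gap loss weights; contour filling; border-nucleus centroids |
| `triseg.datasets` | dynamic-range normalization, 64×64 patching, 90°/reflection/20 %-upscale/Gaussian augmentation, real-augmentation assembly, rotation balancing, 0.36:0.24:0.40 tile-level splits |
| `triseg.segnet` | three-class UNet (NumPy engine with analytic backprop), Adam + step decay, weighted cross-entropy with gap weights, L1, early stopping; tiled whole-image inference |
| `triseg.instseg` | probability maps → instances: center-seeded watershed on `P_contour − P_center` with area filters |
| `triseg.metrics` | sweeping-IoU retained-fraction curves (0.55–0.80), optimal one-to-one matching, F1/precision/recall/AP, annotator agreement |
| `triseg.quant` | per-cell mean intensities; two-component Gaussian-mixture gating on log intensities; double-positive fractions |
| `triseg.experiments` | scripted comparisons: real vs computed augmentation, and the DNA / DNA+NES / DNA+NES+real scenario grid |
| `triseg.io` / `triseg.cli` | TIFF stacks and masks, YAML/JSON config, and the `triseg` command line |

The model quality readout throughout is the **retained fraction**: the
proportion of ground-truth nuclei whose best one-to-one matched
prediction reaches IoU ≥ t, swept over t ∈ {0.55, …, 0.80}. Detection
quality at the conventional 50 % overlap is summarized by precision
TP/(TP+FP), recall TP/(TP+FN), their harmonic mean F1, and
AP = TP/(TP+FP+FN).

## Worked example

`examples/train_and_segment.py` simulates 12 dense-tissue tiles, trains
the tiny UNet (depth 3, 8 base features) for 200 steps, and segments a
held-out tile:

```
trained 100 epochs; final val loss 0.0444
instances: 15 predicted vs 15 true
F1@0.5 = 1.000  (TP 15, FP 0, FN 0)
retained fraction: {'0.55': 1.0, '0.60': 1.0, '0.65': 1.0, '0.70': 1.0, '0.75': 1.0, '0.80': 1.0}
```

All 15 simulated nuclei are detected (F1 = 1 at 50 % overlap) and every
mask matches its nucleus at IoU ≥ 0.80 — on easy in-focus synthetic
data the pipeline is essentially perfect, which is what makes the
degradation under defocus, and its rescue by real augmentation,
interpretable. The other examples cover simulation, annotation,
agreement scoring, quantification/gating, and the two headline
comparisons (`examples/run_comparisons.py`).

The CLI mirrors the library:

```bash
triseg simulate --preset dense --n 20 --out data/ --seed 7
triseg segment --model ckpt --image data/dense_000_channels.tif --out mask.tif
triseg evaluate --gt data/dense_000_mask.tif --pred mask.tif --out scores.json
```

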