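"""Seedable desk-scale reproductions of the headline comparisons.

Two scripted experiments, both running entirely on simulated specimens:

* :func:`run_augmentation_comparison` — train one model per arm
  (unaugmented + rotations, Gaussian-blur augmented, real
  defocus/saturation augmented) on size-balanced sets and evaluate all
  arms on defocused test data.  The expected outcome is the real >
  Gaussian > unaugmented ordering of retained fractions under defocus.
* :func:`run_scenarios` — the A-D scenario grid: A = DNA-only training,
  in-focus test; B = DNA-only training, defocused test; C = DNA+NES
  training, defocused test; D = DNA+NES plus real augmentation, defocused
  test.  Expected ordering on defocused tests: D >= C >= B.

Within a seed every arm/scenario sees bit-identical simulated specimens,
so differences are attributable only to the training condition.  Results
aggregate as mean +/- standard error over seeds per IoU threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from triseg import simdata
from triseg.datasets import (
    AugmentationPlan,
    Patch,
    SplitConfig,
    _largest_remainder,
    assemble_real_augmented_set,
    balance_sets,
    computed_augment,
    normalize_dynamic_range,
)
from triseg.instseg import extract_instances
from triseg.metrics import DEFAULT_THRESHOLDS, InstanceScores, match_instances
from triseg.segnet import (
    TINY_TRAIN,
    TINY_UNET,
    TrainConfig,
    UNetConfig,
    build_model,
    predict_probmaps,
    train_model,
)

__all__ = [
    "ScenarioSpec",
    "ExperimentReport",
    "SCENARIOS",
    "run_augmentation_comparison",
    "run_scenarios",
]

ALL_REAL = frozenset({"defocus_plus", "defocus_minus", "saturated"})

#: Gaussian-blur sigmas (px) for computed augmentation: a range matched to
#: the spread of plausible defocus kernels at the working pixel size.
GAUSSIAN_SIGMAS = (1.5, 3.0)


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    train_channels: tuple[str, ...]
    train_real: frozenset
    test_condition: str  # "infocus" | "defocused" | "saturated"
    train_gaussian_sigmas: tuple[float, ...] = ()
    model_scale: str = "tiny"


SCENARIOS: dict[str, ScenarioSpec] = {
    "A": ScenarioSpec("A", ("dna",), frozenset(), "infocus"),
    "B": ScenarioSpec("B", ("dna",), frozenset(), "defocused"),
    "C": ScenarioSpec("C", ("dna", "nes"), frozenset(), "defocused"),
    "D": ScenarioSpec("D", ("dna", "nes"), ALL_REAL, "defocused"),
}


@dataclass
class ExperimentReport:
    """Per-arm, per-seed curves and scores + aggregate mean/SEM."""

    thresholds: tuple[float, ...]
    arms: dict[str, dict[int, dict]] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def add(self, arm: str, seed: int, fractions: np.ndarray, scores: InstanceScores):
        self.arms.setdefault(arm, {})[seed] = {
            "retained_fraction": [float(f) for f in fractions],
            "tp": scores.tp,
            "fp": scores.fp,
            "fn": scores.fn,
            "precision": scores.precision,
            "recall": scores.recall,
            "f1": scores.f1,
            "ap": scores.ap,
        }

    def fractions(self, arm: str) -> np.ndarray:
        """(n_seeds, n_thresholds) retained fractions for an arm."""
        per_seed = self.arms[arm]
        return np.array(
            [per_seed[s]["retained_fraction"] for s in sorted(per_seed)]
        )

    def mean_sem(self, arm: str) -> tuple[np.ndarray, np.ndarray]:
        f = self.fractions(arm)
        sem = f.std(axis=0, ddof=1) / np.sqrt(len(f)) if len(f) > 1 else np.zeros(f.shape[1])
        return f.mean(axis=0), sem

    def retained_at(self, arm: str, threshold: float) -> np.ndarray:
        """Per-seed retained fraction at one threshold."""
        j = int(np.argmin(np.abs(np.asarray(self.thresholds) - threshold)))
        return self.fractions(arm)[:, j]

    def to_dict(self) -> dict:
        out = {
            "thresholds": list(self.thresholds),
            "config": self.config,
            "arms": self.arms,
            "aggregate": {},
        }
        for arm in self.arms:
            mean, sem = self.mean_sem(arm)
            out["aggregate"][arm] = {
                "mean_retained_fraction": [float(x) for x in mean],
                "sem_retained_fraction": [float(x) for x in sem],
                "mean_f1": float(
                    np.mean([r["f1"] for r in self.arms[arm].values()])
                ),
            }
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# -- shared harness --------------------------------------------------------

def _specimens_from_dir(data_dir) -> list[simdata.SimulatedSpecimen]:
    """Load specimens written by ``write_specimen`` (stem_channels.tif +
    stem_mask.tif + stem.json triples)."""
    import json as _json
    from pathlib import Path

    from triseg import io

    out = []
    for sidecar in sorted(Path(data_dir).glob("*.json")):
        stem = sidecar.stem
        chan_path = sidecar.with_name(f"{stem}_channels.tif")
        mask_path = sidecar.with_name(f"{stem}_mask.tif")
        if not chan_path.exists() or not mask_path.exists():
            continue
        meta = _json.loads(sidecar.read_text())
        params = meta["params"]
        for key in ("field_shape", "elongation_ratio", "radius_range_um"):
            params[key] = tuple(params[key])
        optics = meta["optics"]
        for key in ("defocus_offsets_um", "saturation_target"):
            optics[key] = tuple(optics[key])
        out.append(
            simdata.SimulatedSpecimen(
                channels=io.read_image(chan_path),
                instances=io.read_mask(mask_path),
                params=simdata.TissueSimParams(**params),
                optics=simdata.OpticsConfig(**optics),
                seed=meta["seed"],
            )
        )
    return out


def _sub_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def _tile_params(preset_name: str, tile_px: int = 128) -> simdata.TissueSimParams:
    base = simdata.preset(preset_name)
    scale = (tile_px * tile_px) / (
        base.field_shape[0] * base.field_shape[1]
    )
    return replace(
        base,
        field_shape=(tile_px, tile_px),
        n_nuclei=max(4, int(round(base.n_nuclei * scale))),
    )


def simulate_tiles(
    preset_name: str, n_tiles: int, seed: int, tile_px: int = 128
) -> list[simdata.SimulatedSpecimen]:
    params = _tile_params(preset_name, tile_px)
    optics = simdata.OpticsConfig()
    return [
        simdata.simulate_specimen(
            replace(params, seed=_sub_seed(seed, i)), optics
        )
        for i in range(n_tiles)
    ]


def split_tiles(specimens, seed: int, ratios=(0.36, 0.24, 0.40)):
    counts = _largest_remainder(len(specimens), ratios)
    rng = np.random.default_rng(_sub_seed(seed, 977))
    order = rng.permutation(len(specimens))
    bounds = np.cumsum([0] + counts)
    parts = []
    for k in range(3):
        idx = sorted(order[bounds[k] : bounds[k + 1]])
        parts.append([specimens[i] for i in idx])
    return parts[0], parts[1], parts[2]


def _test_images(spec, condition: str, channels):
    """Image stacks for one test tile under a test condition.

    Defocused tests pool the above- and below-focus acquisitions.  The NES
    channel, when used, is the registered in-focus acquisition.
    """
    dna_names = {
        "infocus": ["dna_infocus"],
        "defocused": ["dna_plus_z", "dna_minus_z"],
        "saturated": ["dna_saturated"],
    }[condition]
    stacks = []
    for name in dna_names:
        planes = [normalize_dynamic_range(spec.channels[name])]
        if "nes" in channels:
            planes.append(normalize_dynamic_range(spec.channels["nes"]))
        stacks.append(np.stack(planes, axis=2))
    return stacks


def evaluate_on_tiles(
    model,
    test_specimens,
    condition: str,
    channels,
    thresholds=DEFAULT_THRESHOLDS,
    pixel_size_um: float = 0.65,
) -> tuple[np.ndarray, InstanceScores]:
    """Pooled sweeping-IoU fractions + instance scores over test tiles."""
    matched = np.zeros(len(thresholds), dtype=int)
    total_gt = 0
    tp = fp = fn = 0
    for spec in test_specimens:
        gt = spec.instances
        n_gt = len(np.unique(gt[gt > 0]))
        for img in _test_images(spec, condition, channels):
            pred = extract_instances(predict_probmaps(model, img))
            total_gt += n_gt
            for k, t in enumerate(thresholds):
                matched[k] += len(match_instances(gt, pred, t).pairs)
            m = match_instances(gt, pred, 0.5)
            tp += len(m.pairs)
            fp += len(m.unmatched_pred)
            fn += len(m.unmatched_gt)
    if total_gt == 0:
        raise ValueError("no ground-truth instances in the test tiles")
    return matched / total_gt, InstanceScores(tp=tp, fp=fp, fn=fn)


def _train_arm(
    patches: Sequence[Patch],
    in_channels: int,
    seed: int,
    train_cfg: TrainConfig,
) -> "TrainedModel":
    cfg = replace(TINY_UNET, in_channels=in_channels)
    model = build_model(cfg, seed=_sub_seed(seed, 31))
    n_val = max(1, len(patches) // 8)
    rng = np.random.default_rng(_sub_seed(seed, 57))
    order = rng.permutation(len(patches))
    val = [patches[i] for i in order[:n_val]]
    train = [patches[i] for i in order[n_val:]]
    return train_model(model, train, val, replace(train_cfg, seed=_sub_seed(seed, 91)))


def run_augmentation_comparison(
    sim_preset: str = "dense",
    n_tiles: int = 12,
    model_scale: str = "tiny",
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    train_cfg: TrainConfig | None = None,
    patch_px: int = 64,
) -> ExperimentReport:
    """Real vs computed augmentation, evaluated on defocused test tiles.

    Three DNA-only arms per seed, size-balanced by rotation padding:
    ``unaugmented`` (in-focus + 90/180 rotations), ``gaussian`` (in-focus
    + Gaussian-blur copies), and ``real`` (in-focus + registered
    defocused/saturated acquisitions).  All three are tested on the
    defocused split.
    """
    if n_tiles < 8:
        raise ValueError("n_tiles must be >= 8")
    seeds = list(seeds)
    if len(seeds) < 3:
        raise ValueError("need >= 3 seeds for a standard-error estimate")
    train_cfg = train_cfg or replace(TINY_TRAIN, max_steps=200)
    report = ExperimentReport(
        thresholds=DEFAULT_THRESHOLDS,
        config={
            "experiment": "augmentation_comparison",
            "sim_preset": sim_preset,
            "n_tiles": n_tiles,
            "model_scale": model_scale,
            "seeds": seeds,
            "max_steps": train_cfg.max_steps,
        },
    )
    arms_spec = {
        "unaugmented": dict(real=(), plan=AugmentationPlan(
            rotations=(90, 180), reflections=False, upscale_factor=1.0)),
        "gaussian": dict(real=(), plan=AugmentationPlan(
            rotations=(), reflections=False, upscale_factor=1.0,
            gaussian_sigmas_px=GAUSSIAN_SIGMAS)),
        "real": dict(real=tuple(sorted(ALL_REAL)), plan=None),
    }
    for seed in seeds:
        tiles = simulate_tiles(sim_preset, n_tiles, seed)
        train_t, val_t, test_t = split_tiles(tiles, seed)
        train_pool = train_t + val_t  # val split handled inside _train_arm
        arm_patches = {}
        for arm, spec_ in arms_spec.items():
            base = assemble_real_augmented_set(
                train_pool, channels=("dna",), real=spec_["real"],
                patch_size_px=patch_px,
            )
            if spec_["plan"] is not None:
                base = computed_augment(base, spec_["plan"], seed=_sub_seed(seed, 7))
            arm_patches[arm] = base
        # balance every arm to the largest arm size
        target_arm = max(arm_patches, key=lambda a: len(arm_patches[a]))
        for arm in arm_patches:
            if arm != target_arm:
                arm_patches[arm], _ = balance_sets(
                    arm_patches[arm], arm_patches[target_arm],
                    seed=_sub_seed(seed, 11),
                )
        for arm, patches in arm_patches.items():
            model = _train_arm(patches, 1, _sub_seed(seed, sum(map(ord, arm))), train_cfg)
            fracs, scores = evaluate_on_tiles(model, test_t, "defocused", ("dna",))
            report.add(arm, seed, fracs, scores)
    return report


def run_scenarios(
    scenarios: Iterable[str | ScenarioSpec] = ("A", "B", "C", "D"),
    sim_preset: str = "dense",
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    n_tiles: int = 12,
    train_cfg: TrainConfig | None = None,
    patch_px: int = 64,
) -> ExperimentReport:
    """End-to-end scenario grid: simulate -> annotate -> split -> train ->
    segment -> evaluate, with shared specimens per seed."""
    specs = [SCENARIOS[s] if isinstance(s, str) else s for s in scenarios]
    seeds = list(seeds)
    train_cfg = train_cfg or replace(TINY_TRAIN, max_steps=200)
    report = ExperimentReport(
        thresholds=DEFAULT_THRESHOLDS,
        config={
            "experiment": "scenarios",
            "scenarios": [s.name for s in specs],
            "sim_preset": sim_preset,
            "n_tiles": n_tiles,
            "seeds": seeds,
            "max_steps": train_cfg.max_steps,
        },
    )
    if not specs:
        return report
    for seed in seeds:
        tiles = simulate_tiles(sim_preset, n_tiles, seed)
        train_t, val_t, test_t = split_tiles(tiles, seed)
        train_pool = train_t + val_t
        # balance scenario training sets to a common size
        sets = {}
        for sc in specs:
            patches = assemble_real_augmented_set(
                train_pool,
                channels=sc.train_channels,
                real=sc.train_real,
                patch_size_px=patch_px,
            )
            if sc.train_gaussian_sigmas:
                patches = computed_augment(
                    patches,
                    AugmentationPlan(
                        rotations=(), reflections=False, upscale_factor=1.0,
                        gaussian_sigmas_px=sc.train_gaussian_sigmas,
                    ),
                    seed=_sub_seed(seed, 7),
                )
            sets[sc.name] = patches
        max_n = max(len(p) for p in sets.values())
        for name in sets:
            if len(sets[name]) < max_n:
                ref = next(p for p in sets.values() if len(p) == max_n)
                sets[name], _ = balance_sets(sets[name], ref, seed=_sub_seed(seed, 11))
        for sc in specs:
            model = _train_arm(
                sets[sc.name],
                len(sc.train_channels),
                _sub_seed(seed, sum(map(ord, sc.name))),
                train_cfg,
            )
            fracs, scores = evaluate_on_tiles(
                model, test_t, sc.test_condition, sc.train_channels
            )
            report.add(sc.name, seed, fracs, scores)
    return report
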