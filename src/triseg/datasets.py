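"""Training-set assembly: patches, normalization, augmentation, splits.

The data pipeline mirrors the acquisition protocol this toolkit targets:
tiles are normalized to their full dynamic range, cropped into 64x64
patches, and augmented either *computationally* (90 deg rotations,
reflections, 20% upscaling, optional Gaussian blur) or with *real*
artefact channels (defocused above/below focus, saturated) that were
acquired registered to the in-focus frame and therefore share one
annotation.  Splitting into train/validation/test uses the 0.36:0.24:0.40
ratio, at tile granularity so patches of one tile never leak across
splits, and artefact variants always travel with their in-focus tile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi

from triseg.labels import AnnotationPack, annotation_to_training_target, instance_to_annotation
from triseg.simdata import SimulatedSpecimen, gaussian_blur

__all__ = [
    "Patch",
    "SplitConfig",
    "AugmentationPlan",
    "normalize_dynamic_range",
    "extract_patches",
    "computed_augment",
    "assemble_real_augmented_set",
    "balance_sets",
    "split_dataset",
]

REAL_CHANNELS = {
    "defocus_plus": "dna_plus_z",
    "defocus_minus": "dna_minus_z",
    "saturated": "dna_saturated",
}


@dataclass
class Patch:
    """One training example: image stack + aligned three-class target."""

    image: np.ndarray  # H x W x C float
    classes: np.ndarray  # H x W int
    weights: np.ndarray  # H x W float
    provenance: str = "infocus"
    source_id: str = ""
    offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.image.ndim == 2:
            self.image = self.image[:, :, None]
        if self.image.shape[:2] != self.classes.shape:
            raise ValueError("image and target are not spatially aligned")


@dataclass(frozen=True)
class SplitConfig:
    ratios: tuple[float, float, float] = (0.36, 0.24, 0.40)
    unit: str = "tile"  # "tile" or "patch"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios):
            raise ValueError("split ratios must be positive")
        if abs(sum(self.ratios) - 1.0) > 1e-6:
            raise ValueError("split ratios must sum to 1")
        if self.unit not in ("tile", "patch"):
            raise ValueError("unit must be 'tile' or 'patch'")


@dataclass(frozen=True)
class AugmentationPlan:
    rotations: tuple[int, ...] = (90, 180)
    reflections: bool = True
    upscale_factor: float = 1.2
    gaussian_sigmas_px: tuple[float, ...] = ()
    real: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.upscale_factor < 1.0:
            raise ValueError("upscale_factor must be >= 1")
        bad = set(self.real) - set(REAL_CHANNELS)
        if bad:
            raise ValueError(f"unknown real-augmentation channels: {sorted(bad)}")


def normalize_dynamic_range(
    image: np.ndarray, low_pct: float = 0.0, high_pct: float = 100.0
) -> np.ndarray:
    """Affine rescale to [0, 1] (min -> 0, max -> 1 by default).

    Percentile clipping is available for robust scaling.  A constant image
    maps to all zeros.
    """
    image = np.asarray(image, dtype=float)
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite pixels")
    lo = np.percentile(image, low_pct)
    hi = np.percentile(image, high_pct)
    if hi <= lo:
        return np.zeros_like(image)
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def extract_patches(
    image: np.ndarray,
    classes: np.ndarray,
    weights: np.ndarray,
    size_px: int = 64,
    stride_px: int | None = None,
    source_id: str = "",
    provenance: str = "infocus",
) -> list[Patch]:
    """Row-major tiling into ``size_px`` windows; trailing partial windows
    are dropped.  Each patch records its (row, col) offset."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = image[:, :, None]
    h, w = classes.shape
    if size_px > h or size_px > w:
        raise ValueError(f"patch size {size_px} exceeds image dims {(h, w)}")
    stride = stride_px or size_px
    out = []
    for r in range(0, h - size_px + 1, stride):
        for c in range(0, w - size_px + 1, stride):
            sl = (slice(r, r + size_px), slice(c, c + size_px))
            out.append(
                Patch(
                    image=image[sl[0], sl[1], :].copy(),
                    classes=classes[sl].copy(),
                    weights=weights[sl].copy(),
                    provenance=provenance,
                    source_id=source_id,
                    offset=(r, c),
                )
            )
    return out


def _rotate_patch(p: Patch, k: int, tag: str) -> Patch:
    return Patch(
        image=np.ascontiguousarray(np.rot90(p.image, k, axes=(0, 1))),
        classes=np.ascontiguousarray(np.rot90(p.classes, k)),
        weights=np.ascontiguousarray(np.rot90(p.weights, k)),
        provenance=f"{p.provenance}+{tag}",
        source_id=p.source_id,
        offset=p.offset,
    )


def _upscale_patch(p: Patch, factor: float) -> Patch:
    """Zoom by ``factor`` then center-crop back to the original size:
    bilinear for intensities, nearest-neighbour for class/weight maps."""
    h, w = p.classes.shape
    img = ndi.zoom(p.image, (factor, factor, 1), order=1)
    cls = ndi.zoom(p.classes, factor, order=0)
    wgt = ndi.zoom(p.weights, factor, order=0)
    r0 = (img.shape[0] - h) // 2
    c0 = (img.shape[1] - w) // 2
    sl = (slice(r0, r0 + h), slice(c0, c0 + w))
    return Patch(
        image=img[sl[0], sl[1], :],
        classes=cls[sl],
        weights=wgt[sl],
        provenance=f"{p.provenance}+upscaled",
        source_id=p.source_id,
        offset=p.offset,
    )


def computed_augment(
    patches: Sequence[Patch], plan: AugmentationPlan, seed: int = 0
) -> list[Patch]:
    """Apply the computed-augmentation plan, returning originals + copies.

    Geometric transforms act identically on image and target; Gaussian
    blur acts on the image only (all intensity channels together).
    """
    out = list(patches)
    for p in patches:
        for deg in plan.rotations:
            out.append(_rotate_patch(p, deg // 90, f"rot{deg}"))
        if plan.reflections:
            out.append(
                Patch(
                    image=p.image[:, ::-1].copy(),
                    classes=p.classes[:, ::-1].copy(),
                    weights=p.weights[:, ::-1].copy(),
                    provenance=f"{p.provenance}+reflected",
                    source_id=p.source_id,
                    offset=p.offset,
                )
            )
        if plan.upscale_factor > 1.0:
            out.append(_upscale_patch(p, plan.upscale_factor))
        for s in plan.gaussian_sigmas_px:
            img = p.image if s == 0 else np.stack(
                [gaussian_blur(p.image[:, :, c], s) for c in range(p.image.shape[2])],
                axis=2,
            )
            out.append(
                Patch(
                    image=np.asarray(img, dtype=float).copy(),
                    classes=p.classes.copy(),
                    weights=p.weights.copy(),
                    provenance=f"{p.provenance}+gaussian_sigma={s}",
                    source_id=p.source_id,
                    offset=p.offset,
                )
            )
    return out


def assemble_real_augmented_set(
    specimens: Iterable[SimulatedSpecimen],
    channels: Sequence[str] = ("dna",),
    real: Iterable[str] = (),
    patch_size_px: int | None = None,
    contour_width_px: int = 2,
    gap_radius_px: int = 2,
    gap_weight: float = 3.0,
) -> list[Patch]:
    """Build a patch set from registered specimens.

    For every tile the in-focus patch is emitted plus one patch per
    requested real-artefact channel; all variants of a tile share the
    identical target, derived once from the instance map (the point of
    registered real augmentation).  ``channels`` is ``("dna",)`` or
    ``("dna", "nes")``; the NES channel, when present, is stacked as a
    second image channel.  With ``patch_size_px`` set, tiles are cropped
    into patches; otherwise whole tiles are emitted.
    """
    real = sorted(set(real))
    bad = set(real) - set(REAL_CHANNELS)
    if bad:
        raise ValueError(f"unknown real-augmentation channels: {sorted(bad)}")
    out: list[Patch] = []
    for idx, spec in enumerate(specimens):
        source_id = f"tile{idx:04d}_seed{spec.seed}"
        for r in real:
            if REAL_CHANNELS[r] not in spec.channels:
                raise ValueError(
                    f"specimen {source_id} lacks channel {REAL_CHANNELS[r]!r} "
                    f"required for real augmentation {r!r}"
                )
        pack = instance_to_annotation(
            spec.instances, contour_width_px, gap_radius_px, gap_weight
        )
        classes, weights = annotation_to_training_target(pack)

        def stack(dna_name: str) -> np.ndarray:
            planes = [normalize_dynamic_range(spec.channels[dna_name])]
            if "nes" in channels:
                planes.append(normalize_dynamic_range(spec.channels["nes"]))
            return np.stack(planes, axis=2)

        variants = [("infocus", stack("dna_infocus"))]
        variants += [(r, stack(REAL_CHANNELS[r])) for r in real]
        if patch_size_px is None:
            for prov, img in variants:
                out.append(
                    Patch(
                        image=img,
                        classes=classes,
                        weights=weights,
                        provenance=prov,
                        source_id=source_id,
                    )
                )
        else:
            # patch targets computed once, shared across variants
            base = extract_patches(
                variants[0][1], classes, weights, patch_size_px,
                source_id=source_id, provenance="infocus",
            )
            out.extend(base)
            for prov, img in variants[1:]:
                for bp in base:
                    r0, c0 = bp.offset
                    sl = (slice(r0, r0 + patch_size_px), slice(c0, c0 + patch_size_px))
                    out.append(
                        Patch(
                            image=img[sl[0], sl[1], :].copy(),
                            classes=bp.classes,
                            weights=bp.weights,
                            provenance=prov,
                            source_id=source_id,
                            offset=bp.offset,
                        )
                    )
    return out


def balance_sets(
    set_a: Sequence[Patch], set_b: Sequence[Patch], seed: int = 0
) -> tuple[list[Patch], list[Patch]]:
    """Equalize two training sets by padding the smaller with rotated
    copies of its own patches (90/180/270 deg); data are never discarded."""
    a, b = list(set_a), list(set_b)
    if len(a) == len(b):
        return a, b
    small, big = (a, b) if len(a) < len(b) else (b, a)
    if not small:
        raise ValueError("cannot balance an empty set")
    rng = np.random.default_rng(seed)
    pads: list[Patch] = []
    while len(small) + len(pads) < len(big):
        p = small[int(rng.integers(len(small)))]
        k = int(rng.integers(1, 4))
        pads.append(_rotate_patch(p, k, f"rot{90 * k}"))
    small_out = small + pads
    return (small_out, big) if len(a) < len(b) else (big, small_out)


def _largest_remainder(n: int, ratios: Sequence[float]) -> list[int]:
    quotas = [n * r for r in ratios]
    counts = [int(np.floor(q)) for q in quotas]
    rem = n - sum(counts)
    order = sorted(
        range(len(ratios)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in order[:rem]:
        counts[i] += 1
    return counts


def split_dataset(
    items: Sequence[Patch], cfg: SplitConfig = SplitConfig()
) -> tuple[list[Patch], list[Patch], list[Patch]]:
    """Disjoint, exhaustive train/validation/test split.

    With ``unit="tile"`` (default) all patches sharing a ``source_id``
    stay together — artefact variants of a tile never cross splits, the
    conservative anti-leakage choice.  Subset sizes follow the
    largest-remainder apportionment of the ratios; assignment is a
    deterministic seeded shuffle.
    """
    items = list(items)
    if cfg.unit == "patch":
        groups = [[p] for p in items]
    else:
        by_tile: dict[str, list[Patch]] = {}
        for p in items:
            by_tile.setdefault(p.source_id, []).append(p)
        groups = [by_tile[k] for k in sorted(by_tile)]
    n = len(groups)
    if n < 3:
        raise ValueError("need at least 3 units to split three ways")
    counts = _largest_remainder(n, cfg.ratios)
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(n)
    bounds = np.cumsum([0] + counts)
    out: list[list[Patch]] = []
    for k in range(3):
        sel = order[bounds[k] : bounds[k + 1]]
        out.append([p for i in sorted(sel) for p in groups[i]])
    return out[0], out[1], out[2]
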