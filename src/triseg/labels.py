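"""Three-class training annotations from instance ground truth.

The training target mirrors a manual annotation protocol: annotators draw
closed nucleus *contours*, the contours are filled to obtain nucleus
*centers*, everything else is *background*, and a fourth layer marks the
thin background gaps between clumped nuclei so a model can be penalized
extra for merging neighbours.  Here the same annotation is derived
mechanically from an instance label map:

* contour: the inner morphological boundary of each instance, thickened to
  ``contour_width_px`` (inner, so contours of touching nuclei stay
  distinct);
* center: the remaining interior of each instance;
* gap weight: a per-pixel loss weight, ``gap_weight`` on background pixels
  lying within ``gap_radius_px`` of two or more distinct instances and 1
  elsewhere (a weight map rather than a fourth class, so the semantic model
  stays three-class);
* border nuclei: instances clipped by the image border cannot carry a
  closed contour; they are annotated as center pixels only and contribute
  a centroid point to ``border_centers``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "AnnotationPack",
    "instance_to_annotation",
    "fill_contours",
    "annotation_to_training_target",
    "BACKGROUND",
    "CONTOUR",
    "CENTER",
]

BACKGROUND, CONTOUR, CENTER = 0, 1, 2

_CROSS = ndi.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass
class AnnotationPack:
    """Three-class map + gap weight map + border-nucleus centroids."""

    classmap: np.ndarray
    gapweight: np.ndarray
    border_centers: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.classmap.shape != self.gapweight.shape:
            raise ValueError("classmap and gapweight must share a shape")


def _touches_border(sl: tuple[slice, slice], shape: tuple[int, int]) -> bool:
    return (
        sl[0].start == 0
        or sl[1].start == 0
        or sl[0].stop == shape[0]
        or sl[1].stop == shape[1]
    )


def instance_to_annotation(
    instances: np.ndarray,
    contour_width_px: int = 2,
    gap_radius_px: int = 2,
    gap_weight: float = 3.0,
) -> AnnotationPack:
    """Derive the three-class annotation and gap-weight map.

    Parameters
    ----------
    instances:
        Integer label map, 0 = background; each positive label one
        4-connected nucleus.
    contour_width_px:
        Thickness of the inner-boundary contour class (>= 1).  Default 2 px
        at the 0.65 um/px working scale.
    gap_radius_px:
        Background pixels within this Euclidean distance of two or more
        distinct instances receive extra loss weight.
    gap_weight:
        The weight assigned to clumped-gap pixels; elsewhere the weight
        is 1.
    """
    if contour_width_px < 1:
        raise ValueError("contour_width_px must be >= 1")
    instances = np.asarray(instances)
    if instances.ndim != 2:
        raise ValueError("instance map must be 2-D")
    shape = instances.shape
    classmap = np.zeros(shape, dtype=np.uint8)
    gap_count = np.zeros(shape, dtype=np.int32)
    border_centers: list[tuple[float, float]] = []

    # dilation footprint: Euclidean disk of radius gap_radius_px
    g = gap_radius_px
    yy, xx = np.mgrid[-g : g + 1, -g : g + 1]
    gap_disk = (yy**2 + xx**2) <= g**2

    objects = ndi.find_objects(instances)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        pad = max(contour_width_px, g) + 1
        y0 = max(0, sl[0].start - pad)
        y1 = min(shape[0], sl[0].stop + pad)
        x0 = max(0, sl[1].start - pad)
        x1 = min(shape[1], sl[1].stop + pad)
        win = (slice(y0, y1), slice(x0, x1))
        mask = instances[win] == lab

        if _touches_border(sl, shape):
            # no closed contour possible: center-only + centroid point
            classmap[win][mask] = CENTER
            com = ndi.center_of_mass(mask)
            border_centers.append((com[0] + y0, com[1] + x0))
        else:
            interior = ndi.binary_erosion(
                mask, structure=_CROSS, iterations=contour_width_px
            )
            contour = mask & ~interior
            classmap[win][contour] = CONTOUR
            classmap[win][interior] = CENTER
        gap_count[win] += ndi.binary_dilation(mask, structure=gap_disk)

    gapweight = np.ones(shape, dtype=float)
    gap_pixels = (gap_count >= 2) & (instances == 0)
    gapweight[gap_pixels] = gap_weight
    return AnnotationPack(
        classmap=classmap, gapweight=gapweight, border_centers=border_centers
    )


def fill_contours(contours: np.ndarray) -> np.ndarray:
    """Fill closed contours: add every background region not connected to
    the image border (4-connected flood fill), as in filling hand-drawn
    nucleus outlines to obtain their centers.  Idempotent."""
    contours = np.asarray(contours).astype(bool)
    return ndi.binary_fill_holes(contours, structure=_CROSS)


def annotation_to_training_target(
    pack: AnnotationPack,
    class_balance: tuple[float, float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Flatten an annotation pack into (class indices, per-pixel weights).

    The weight map is the gap-weight map, optionally multiplied by
    per-class balancing factors.
    """
    classes = pack.classmap.astype(np.int64)
    weights = pack.gapweight.astype(np.float64).copy()
    if class_balance is not None:
        factors = np.asarray(class_balance, dtype=float)
        weights *= factors[classes]
    return classes, weights
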