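"""TIFF/mask/config readers and writers.

Channel stacks travel as multi-page TIFF with channel names stored in the
image description (JSON), instance masks as single-channel integer TIFF
(16-bit while labels fit, 32-bit beyond 65535), and configuration as
YAML/JSON validated against the package defaults with unknown keys
rejected.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

from triseg.datasets import SplitConfig
from triseg.segnet import TrainConfig, UNetConfig
from triseg.simdata import OpticsConfig, SimulatedSpecimen, TissueSimParams

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "write_specimen",
    "load_config",
    "default_config",
]


def write_image(stack: dict[str, np.ndarray], path: str | Path) -> None:
    """Write named channels as a multi-page TIFF (one page per channel)."""
    if not stack:
        raise ValueError("empty channel stack")
    names = list(stack)
    shapes = {stack[n].shape for n in names}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent channel shapes: {shapes}")
    desc = json.dumps({"channels": names})
    with tifffile.TiffWriter(path) as tif:
        for i, n in enumerate(names):
            tif.write(stack[n], description=desc if i == 0 else None)


def read_image(path: str | Path) -> dict[str, np.ndarray]:
    """Read a (multi-page) TIFF into named channels.

    Channel names come from the JSON image description when present,
    otherwise positional names ``ch0, ch1, ...``.
    """
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
        desc = tif.pages[0].description
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent page shapes in {path}: {shapes}")
    names = None
    if desc:
        try:
            meta = json.loads(desc)
            names = meta.get("channels")
        except (json.JSONDecodeError, AttributeError):
            names = None
    if not names or len(names) != len(pages):
        names = [f"ch{i}" for i in range(len(pages))]
    return dict(zip(names, pages))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write an instance label map; dtype sized to the largest label."""
    mask = np.asarray(mask)
    if np.issubdtype(mask.dtype, np.floating):
        if not np.all(mask == np.round(mask)):
            raise ValueError("float mask contains non-integer values")
        mask = mask.astype(np.int64)
    if mask.min() < 0:
        raise ValueError("mask labels must be non-negative")
    dtype = np.uint16 if mask.max() <= 65535 else np.uint32
    tifffile.imwrite(path, mask.astype(dtype))


def read_mask(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if np.issubdtype(arr.dtype, np.floating):
        if not np.all(arr == np.round(arr)):
            raise ValueError(f"{path}: float mask with non-integer values")
        arr = arr.astype(np.int64)
    return arr.astype(np.int32 if arr.max() <= 2**31 - 1 else np.int64)


def write_specimen(spec: SimulatedSpecimen, out_dir: str | Path, stem: str) -> None:
    """One specimen -> channels TIFF + mask TIFF + JSON parameter sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image(spec.channels, out / f"{stem}_channels.tif")
    write_mask(spec.instances, out / f"{stem}_mask.tif")
    sidecar = {
        "params": asdict(spec.params),
        "optics": asdict(spec.optics),
        "seed": spec.seed,
    }
    (out / f"{stem}.json").write_text(json.dumps(sidecar, indent=2, default=list))


def default_config() -> dict:
    """The fully resolved default configuration tree."""
    return {
        "simulate": {**asdict(TissueSimParams()), "optics": asdict(OpticsConfig())},
        "unet": asdict(UNetConfig()),
        "train": asdict(TrainConfig()),
        "split": asdict(SplitConfig()),
        "annotation": {
            "contour_width_px": 2,
            "gap_radius_px": 2,
            "gap_weight": 3.0,
        },
        "segment": {
            "center_thresh": 0.5,
            "fg_thresh": 0.5,
            "min_area_px": None,
            "max_area_px": None,
        },
    }


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown configuration key: {here}")
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge(defaults[key], val, here)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load YAML/JSON configuration over the package defaults.

    Unknown keys are rejected with the path to the offending field; an
    empty or missing file yields the full default tree.
    """
    defaults = default_config()
    if path is None:
        return defaults
    text = Path(path).read_text()
    if not text.strip():
        return defaults
    data = yaml.safe_load(text)  # YAML superset covers JSON
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top-level configuration must be a mapping")
    return _merge(defaults, data)
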