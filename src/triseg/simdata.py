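"""Synthetic multiplexed tissue specimens with registered optical artefacts.

Real tissue images used to train segmentation models come with "real
augmentations": the same field re-acquired with the focal plane displaced a
few micrometres above and below the specimen, and with a long exposure that
saturates most nucleus pixels.  Because the stage does not move between
acquisitions, one set of instance annotations is valid for every variant.

This module emulates that acquisition protocol.  A specimen is a noiseless
scene of elliptical nuclei (with chromatin texture) from which five
registered channels are rendered:

``dna_infocus``
    DNA stain, in focus.
``dna_plus_z`` / ``dna_minus_z``
    DNA stain with the focal plane displaced by +/- ``defocus_offsets_um``
    (default +/-3 um).  Defocus is modelled as convolution with a uniform
    disk (pillbox) kernel whose radius grows with the offset; the
    below-focus kernel is wider by ``asymmetry_factor``, since real
    out-of-focus blur differs above and below the specimen.  A pillbox is
    deliberately *not* a Gaussian, so computed Gaussian-blur augmentation
    remains a genuinely different operation.
``dna_saturated``
    DNA stain at long exposure: a gain is applied before clipping at the
    detector maximum, by default auto-tuned so 70-80% of foreground
    (nucleus) pixels saturate.
``nes``
    Nuclear envelope stain: an annulus around each nucleus boundary,
    optionally perturbed towards the irregular/diffuse envelopes seen in
    many cell types.

Poisson-Gaussian camera noise is applied after blurring and before
clipping/quantization.  All channels and the instance label map share one
geometry; artefact rendering never moves objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "OpticsConfig",
    "TissueSimParams",
    "SimulatedSpecimen",
    "simulate_specimen",
    "render_defocus",
    "render_saturation",
    "gaussian_blur",
    "disk_kernel",
    "gaussian_kernel",
    "PRESETS",
]


@dataclass(frozen=True)
class OpticsConfig:
    """Acquisition model: pixel pitch, defocus kernels, exposure, noise.

    Parameters
    ----------
    pixel_size_um:
        Physical pixel pitch in micrometres.  Default 0.65 um, the scale of
        20x images down-sampled by 2.
    defocus_offsets_um:
        Focal-plane displacements rendered for the "real augmentation"
        channels; default (+3, -3) um.
    defocus_kernel:
        ``"disk_psf"`` (uniform pillbox, the default) or ``"gaussian"``.
    defocus_radius_per_um:
        Unitless NA-like constant: the kernel radius in the image plane is
        ``defocus_radius_per_um * |offset_um| / pixel_size_um`` pixels.
    asymmetry_factor:
        Multiplier applied to the kernel radius for negative (below-focus)
        offsets; default 1.3.
    saturation_exposure:
        Gain applied before clipping for the saturated channel, or
        ``"auto"`` to tune the gain so the saturated foreground fraction
        falls inside ``saturation_target``.
    saturation_target:
        (low, high) bounds on the fraction of saturated foreground pixels
        in auto mode; default (0.70, 0.80).
    photon_scale:
        Expected photon count on a unit-intensity pixel; sets the Poisson
        shot-noise level (default 100, SNR ~ 10 on nuclei).
    read_noise_sigma:
        Additive Gaussian camera noise, in photon counts.
    bit_depth:
        Integer output depth of rendered channels (default 16).
    """

    pixel_size_um: float = 0.65
    defocus_offsets_um: tuple[float, ...] = (3.0, -3.0)
    defocus_kernel: Literal["disk_psf", "gaussian"] = "disk_psf"
    defocus_radius_per_um: float = 1.0
    asymmetry_factor: float = 1.3
    saturation_exposure: float | Literal["auto"] = "auto"
    saturation_target: tuple[float, float] = (0.70, 0.80)
    photon_scale: float = 100.0
    read_noise_sigma: float = 2.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        lo, hi = self.saturation_target
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("saturation_target bounds must lie in (0, 1)")
        if self.bit_depth not in (8, 16, 32):
            raise ValueError("bit_depth must be 8, 16 or 32")

    @property
    def dtype(self) -> np.dtype:
        return np.dtype({8: np.uint8, 16: np.uint16, 32: np.uint32}[self.bit_depth])

    @property
    def dtype_max(self) -> int:
        return int(np.iinfo(self.dtype).max)

    def defocus_radius_px(self, offset_um: float) -> float:
        r = self.defocus_radius_per_um * abs(offset_um) / self.pixel_size_um
        if offset_um < 0:
            r *= self.asymmetry_factor
        return r


@dataclass(frozen=True)
class TissueSimParams:
    """Geometry and staining parameters of a simulated field.

    ``packing`` controls nucleus placement: ``sparse`` keeps nuclei well
    separated, ``dense`` allows touching (never overlapping) instances, and
    ``clumped`` draws centers around a few cluster sites so nuclei form
    tight groups separated by thin background gaps.
    """

    field_shape: tuple[int, int] = (256, 256)
    n_nuclei: int = 60
    packing: Literal["sparse", "dense", "clumped"] = "dense"
    frac_elongated: float = 0.3
    elongation_ratio: tuple[float, float] = (1.6, 2.6)
    radius_range_um: tuple[float, float] = (3.0, 5.5)
    texture_contrast: float = 0.3
    nes_ring_width_um: float = 1.0
    nes_coverage: float = 1.0
    nes_irregularity: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        for name in ("frac_elongated", "nes_coverage", "nes_irregularity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.radius_range_um[0] <= 0 or self.radius_range_um[1] < self.radius_range_um[0]:
            raise ValueError("radius_range_um must be positive and ordered")


# Tissue-style presets: sparse fibroblast-like fields, dense epithelium-like
# fields, clumped crypt-like groups, and a pleomorphic high-variance field.
PRESETS: dict[str, TissueSimParams] = {
    "sparse": TissueSimParams(packing="sparse", n_nuclei=25, frac_elongated=0.5),
    "dense": TissueSimParams(packing="dense", n_nuclei=60, frac_elongated=0.3),
    "clumped": TissueSimParams(packing="clumped", n_nuclei=60, frac_elongated=0.2),
    "glioblastoma-like": TissueSimParams(
        packing="dense",
        n_nuclei=45,
        frac_elongated=0.5,
        elongation_ratio=(1.5, 3.2),
        radius_range_um=(2.5, 7.0),
        texture_contrast=0.5,
        nes_irregularity=0.8,
    ),
}


@dataclass
class SimulatedSpecimen:
    """Registered channel stack + instance ground truth for one field."""

    channels: dict[str, np.ndarray]
    instances: np.ndarray
    params: TissueSimParams
    optics: OpticsConfig
    seed: int

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} not present; have {sorted(self.channels)}"
            )
        return self.channels[name]


def disk_kernel(radius_px: float) -> np.ndarray:
    """Normalized uniform (pillbox) kernel of the given radius in pixels.

    Radius below 0.5 px degenerates to the identity kernel.
    """
    r = float(radius_px)
    if r < 0.5:
        return np.ones((1, 1))
    n = int(np.ceil(r))
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    k = ((yy**2 + xx**2) <= r**2).astype(float)
    return k / k.sum()


def gaussian_kernel(sigma_px: float, truncate: float = 4.0) -> np.ndarray:
    """Normalized 2-D Gaussian kernel (for kernel-shape comparisons)."""
    if sigma_px <= 0:
        return np.ones((1, 1))
    n = int(truncate * sigma_px + 0.5)
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    k = np.exp(-(yy**2 + xx**2) / (2.0 * sigma_px**2))
    return k / k.sum()


def render_defocus(
    image: np.ndarray, offset_um: float, optics: OpticsConfig
) -> np.ndarray:
    """Apply the configured defocus blur for a given z offset.

    Offset 0 returns the input unchanged.  Convolution uses reflect
    padding, so total intensity is conserved for interior-supported
    content.  Input must be finite.
    """
    image = np.asarray(image, dtype=float)
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite pixels")
    if offset_um == 0:
        return image.copy()
    r = optics.defocus_radius_px(offset_um)
    if optics.defocus_kernel == "gaussian":
        # Gaussian with matched RMS width: a pillbox of radius r has
        # radial second moment r^2/2, i.e. sigma = r/2 per axis.
        return ndi.gaussian_filter(image, sigma=r / 2.0, mode="reflect")
    k = disk_kernel(r)
    return ndi.convolve(image, k, mode="reflect")


def gaussian_blur(image: np.ndarray, sigma_px: float) -> np.ndarray:
    """Computed-augmentation blur: normalized Gaussian, reflect padding."""
    if sigma_px < 0:
        raise ValueError("sigma_px must be >= 0")
    image = np.asarray(image, dtype=float)
    if sigma_px == 0:
        return image.copy()
    return ndi.gaussian_filter(image, sigma=sigma_px, mode="reflect")


def render_saturation(
    image: np.ndarray,
    optics: OpticsConfig,
    foreground: np.ndarray,
) -> np.ndarray:
    """Long-exposure rendering: gain before clipping at the detector max.

    With ``saturation_exposure="auto"`` the gain is found by bisection so
    the fraction of *foreground* pixels at the detector maximum lands in
    ``optics.saturation_target`` (default 70-80%, the acquisition target
    for saturated training data).  Raising the gain never decreases any
    pixel.
    """
    image = np.asarray(image, dtype=float)
    foreground = np.asarray(foreground, dtype=bool)
    if foreground.shape != image.shape:
        raise ValueError("foreground mask must match image shape")
    vmax = float(optics.dtype_max)

    def sat_frac(gain: float) -> float:
        return float(np.mean(gain * image[foreground] >= vmax))

    gain = optics.saturation_exposure
    if gain == "auto":
        if not foreground.any():
            raise ValueError(
                "auto saturation undefined: foreground mask is empty"
            )
        lo_t, hi_t = optics.saturation_target
        target = 0.5 * (lo_t + hi_t)
        lo, hi = 1e-9, 1.0
        while sat_frac(hi) < target and hi < 1e12:
            hi *= 2.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            f = sat_frac(mid)
            if lo_t <= f <= hi_t:
                gain = mid
                break
            if f < target:
                lo = mid
            else:
                hi = mid
        else:  # pragma: no cover - saturable images always converge
            gain = 0.5 * (lo + hi)
    return np.clip(float(gain) * image, 0.0, vmax)


def _sample_axes(rng: np.random.Generator, params: TissueSimParams, px: float):
    r_um = rng.uniform(*params.radius_range_um)
    r_px = r_um / px
    if rng.uniform() < params.frac_elongated:
        q = rng.uniform(*params.elongation_ratio)
    else:
        q = rng.uniform(1.0, 1.2)
    # Keep the equivalent radius: a*b = r^2 with a/b = q.
    a = r_px * np.sqrt(q)
    b = r_px / np.sqrt(q)
    theta = rng.uniform(0.0, np.pi)
    return a, b, theta


def _ellipse_mask(shape, center, a, b, theta) -> np.ndarray:
    cy, cx = center
    n = int(np.ceil(max(a, b))) + 1
    y0, y1 = max(0, int(cy) - n), min(shape[0], int(cy) + n + 1)
    x0, x1 = max(0, int(cx) - n), min(shape[1], int(cx) + n + 1)
    if y0 >= y1 or x0 >= x1:
        return np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    out = np.zeros(shape, dtype=bool)
    out[y0:y1, x0:x1] = inside
    return out


def _place_nuclei(
    rng: np.random.Generator, params: TissueSimParams, optics: OpticsConfig
) -> np.ndarray:
    """Rejection-sampled placement; returns the instance label map."""
    shape = params.field_shape
    px = optics.pixel_size_um
    max_r_px = params.radius_range_um[1] / px
    if params.n_nuclei > 0 and (
        min(shape) < 2 * max_r_px + 2
        or params.n_nuclei * np.pi * (params.radius_range_um[0] / px) ** 2
        > 0.95 * shape[0] * shape[1]
    ):
        raise ValueError(
            f"field {shape} too small for n_nuclei={params.n_nuclei} "
            f"at radius_range_um={params.radius_range_um}"
        )
    labels = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    # sparse placement keeps a clearance ring; dense/clumped allow touching
    clearance = {"sparse": 4, "dense": 0, "clumped": 0}[params.packing]

    cluster_sites = None
    if params.packing == "clumped":
        n_sites = max(1, params.n_nuclei // 8)
        cluster_sites = np.column_stack(
            [
                rng.uniform(max_r_px, shape[0] - max_r_px, n_sites),
                rng.uniform(max_r_px, shape[1] - max_r_px, n_sites),
            ]
        )

    placed = 0
    attempts = 0
    max_attempts = 200 * max(1, params.n_nuclei)
    while placed < params.n_nuclei and attempts < max_attempts:
        attempts += 1
        a, b, theta = _sample_axes(rng, params, px)
        margin = max(a, b)
        if cluster_sites is not None:
            site = cluster_sites[rng.integers(len(cluster_sites))]
            cy = site[0] + rng.normal(0.0, 2.5 * max_r_px)
            cx = site[1] + rng.normal(0.0, 2.5 * max_r_px)
            if not (margin <= cy <= shape[0] - margin - 1) or not (
                margin <= cx <= shape[1] - margin - 1
            ):
                continue
        else:
            cy = rng.uniform(margin, shape[0] - margin - 1)
            cx = rng.uniform(margin, shape[1] - margin - 1)
        mask = _ellipse_mask(shape, (cy, cx), a, b, theta)
        if not mask.any():
            continue
        test = mask
        if clearance:
            test = ndi.binary_dilation(mask, iterations=clearance)
        if (occupied & test).any():
            continue
        placed += 1
        labels[mask] = placed
        occupied |= mask
    return labels


def _chromatin_texture(
    rng: np.random.Generator, shape, contrast: float
) -> np.ndarray:
    """Smooth multiplicative texture field in [1-c, 1+c]."""
    noise = rng.normal(size=shape)
    smooth = ndi.gaussian_filter(noise, sigma=1.5)
    smooth /= max(np.abs(smooth).max(), 1e-9)
    return 1.0 + contrast * smooth

def _nes_scene(
    rng: np.random.Generator,
    labels: np.ndarray,
    params: TissueSimParams,
    optics: OpticsConfig,
) -> np.ndarray:
    """Annulus of configurable width around each instance boundary."""
    half_w = max(1, int(round(0.5 * params.nes_ring_width_um / optics.pixel_size_um)))
    scene = np.zeros(labels.shape, dtype=float)
    expressing = [
        lab
        for lab in np.unique(labels)
        if lab > 0 and rng.uniform() < params.nes_coverage
    ]
    for sl, lab in zip(ndi.find_objects(labels), np.unique(labels[labels > 0])):
        if lab not in expressing or sl is None:
            continue
        pad = half_w + 2
        y0 = max(0, sl[0].start - pad)
        y1 = min(labels.shape[0], sl[0].stop + pad)
        x0 = max(0, sl[1].start - pad)
        x1 = min(labels.shape[1], sl[1].stop + pad)
        m = labels[y0:y1, x0:x1] == lab
        ring = ndi.binary_dilation(m, iterations=half_w) & ~ndi.binary_erosion(
            m, iterations=half_w
        )
        scene[y0:y1, x0:x1][ring] = 1.0
    if params.nes_irregularity > 0 and scene.any():
        # perturb ring intensity and bleed it outward: folds/invaginations
        pert = ndi.gaussian_filter(rng.normal(size=scene.shape), sigma=2.0)
        pert /= max(np.abs(pert).max(), 1e-9)
        scene = scene * (1.0 - params.nes_irregularity * 0.7 * (pert + 1) / 2)
        scene = (1 - params.nes_irregularity) * scene + params.nes_irregularity * (
            ndi.gaussian_filter(scene, sigma=1.5)
        )
    return scene


def _digitize(
    rng: np.random.Generator, scene: np.ndarray, optics: OpticsConfig
) -> np.ndarray:
    """Poisson-Gaussian camera model, then quantization to the bit depth."""
    counts = rng.poisson(np.clip(scene, 0, None) * optics.photon_scale).astype(float)
    counts += rng.normal(0.0, optics.read_noise_sigma, size=scene.shape)
    # Map the nominal full-scale (1.25 photon_scale) to ~30% of the dtype
    # range so the saturated channel has headroom before clipping.
    gain = 0.3 * optics.dtype_max / (1.25 * optics.photon_scale)
    return np.clip(counts * gain, 0, optics.dtype_max)


def simulate_specimen(
    params: TissueSimParams, optics: OpticsConfig | None = None
) -> SimulatedSpecimen:
    """Simulate one field: five registered channels + instance ground truth.

    Deterministic for fixed ``params.seed``: two calls with identical
    configurations return bit-identical channels and labels.  The defocused
    and saturated channels are rendered from the same noiseless scene as
    the in-focus channel, so the instance map is valid ground truth for all
    of them.
    """
    optics = optics or OpticsConfig()
    rng = np.random.default_rng(params.seed)
    labels = _place_nuclei(rng, params, optics)

    scene = np.full(labels.shape, 0.04)  # tissue autofluorescence floor
    if labels.any():
        texture = _chromatin_texture(rng, labels.shape, params.texture_contrast)
        body = (labels > 0).astype(float)
        # soften nucleus edges slightly: stain density falls at the rim
        soft = 0.7 * body + 0.3 * ndi.gaussian_filter(body, sigma=1.0)
        scene = scene + soft * texture
    nes_scene = _nes_scene(rng, labels, params, optics)

    plus, minus = optics.defocus_offsets_um[0], optics.defocus_offsets_um[1]
    scenes = {
        "dna_infocus": scene,
        "dna_plus_z": render_defocus(scene, plus, optics),
        "dna_minus_z": render_defocus(scene, minus, optics),
        "nes": nes_scene,
    }
    channels: dict[str, np.ndarray] = {}
    for name in ("dna_infocus", "dna_plus_z", "dna_minus_z", "nes"):
        channels[name] = _digitize(rng, scenes[name], optics)
    fg = labels > 0
    if fg.any():
        channels["dna_saturated"] = render_saturation(
            channels["dna_infocus"], optics, fg
        )
    else:
        channels["dna_saturated"] = channels["dna_infocus"].copy()
    dtype = optics.dtype
    channels = {k: np.round(v).astype(dtype) for k, v in channels.items()}
    return SimulatedSpecimen(
        channels=channels,
        instances=labels,
        params=params,
        optics=optics,
        seed=params.seed,
    )


def preset(name: str, **overrides) -> TissueSimParams:
    """Look up a tissue preset, optionally overriding fields."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)
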