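"""Shared fixtures: small simulated specimens and random instance maps."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from triseg import simdata


@pytest.fixture(scope="session")
def dense_specimen() -> simdata.SimulatedSpecimen:
    params = simdata.preset("dense", field_shape=(128, 128), n_nuclei=15, seed=11)
    return simdata.simulate_specimen(params)


@pytest.fixture(scope="session")
def sparse_specimen() -> simdata.SimulatedSpecimen:
    params = simdata.preset("sparse", field_shape=(128, 128), n_nuclei=6, seed=5)
    return simdata.simulate_specimen(params)


def make_random_instances(
    rng: np.random.Generator,
    shape: tuple[int, int] = (48, 48),
    max_objects: int = 8,
    r_range: tuple[int, int] = (3, 7),
) -> np.ndarray:
    """Random non-overlapping disk instances (>= 1 object)."""
    n = int(rng.integers(1, max_objects + 1))
    labels = np.zeros(shape, dtype=np.int32)
    lab = 0
    for _ in range(200):
        if lab >= n:
            break
        r = int(rng.integers(*r_range))
        cy = int(rng.integers(r, shape[0] - r))
        cx = int(rng.integers(r, shape[1] - r))
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        if (labels[disk] != 0).any():
            continue
        lab += 1
        labels[disk] = lab
    return labels


def perturb_instances(
    rng: np.random.Generator, labels: np.ndarray
) -> np.ndarray:
    """A plausible 'prediction': shift, relabel, drop and add objects."""
    out = np.zeros_like(labels)
    ids = np.unique(labels[labels > 0])
    next_id = 1
    for lab in ids:
        if rng.uniform() < 0.15:  # miss
            continue
        dy, dx = rng.integers(-3, 4, size=2)
        mask = labels == lab
        shifted = np.roll(np.roll(mask, dy, axis=0), dx, axis=1)
        shifted &= out == 0
        if shifted.any():
            out[shifted] = next_id
            next_id += 1
    for _ in range(int(rng.integers(0, 3))):  # spurious objects
        r = int(rng.integers(2, 5))
        cy = int(rng.integers(r, labels.shape[0] - r))
        cx = int(rng.integers(r, labels.shape[1] - r))
        yy, xx = np.mgrid[: labels.shape[0], : labels.shape[1]]
        disk = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r**2) & (out == 0)
        if disk.any():
            out[disk] = next_id
            next_id += 1
    return out


_PERM_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _perms(m: int, k: int) -> np.ndarray:
    if (m, k) not in _PERM_CACHE:
        _PERM_CACHE[(m, k)] = np.array(
            list(itertools.permutations(range(m), k)), dtype=np.int64
        ).reshape(-1, k)
    return _PERM_CACHE[(m, k)]


def brute_force_match(iou: np.ndarray, threshold: float):
    """Exhaustive one-to-one assignment oracle on an IoU matrix.

    Returns (max_total_iou, set of matched-pair counts among all optimal
    assignments).  Pairs below the threshold contribute nothing and are
    not counted.
    """
    n, m = iou.shape
    if n == 0 or m == 0:
        return 0.0, {0}
    score = np.where(iou >= threshold, iou, 0.0)
    if n <= m:
        perms = _perms(m, n)
        totals = score[np.arange(n)[None, :], perms].sum(axis=1)
        counts = (score[np.arange(n)[None, :], perms] > 0).sum(axis=1)
    else:
        perms = _perms(n, m)
        totals = score[perms, np.arange(m)[None, :]].sum(axis=1)
        counts = (score[perms, np.arange(m)[None, :]] > 0).sum(axis=1)
    best = totals.max()
    tied = counts[totals >= best - 1e-12]
    return float(best), set(int(c) for c in tied)
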