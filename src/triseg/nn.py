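"""Minimal NumPy neural-network engine for the three-class UNet.

Implements exactly the pieces the segmentation model needs — 2-D
convolution (im2col + matmul, with analytic backprop), batch
normalization, ReLU, 2x2 max-pooling, nearest-neighbour upsampling,
dropout, weighted softmax cross-entropy and the Adam optimizer with
stepwise learning-rate decay.  Everything is float32 and fully
deterministic given the seeds.

Tensors are laid out channels-last, (N, H, W, C): im2col windows and
convolution outputs are then nearly contiguous, which is what makes
CPU training at the package's "tiny" model scale practical.

Layers follow a simple protocol: ``forward(x, training)`` caches what the
backward pass needs; ``backward(grad_out)`` accumulates parameter
gradients and returns the input gradient; ``params()`` yields
``ParamSlot`` objects the optimizer updates in place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ParamSlot",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "Dropout",
    "Block",
    "Adam",
    "weighted_cross_entropy",
    "softmax",
]


@dataclass
class ParamSlot:
    name: str
    value: np.ndarray
    grad: np.ndarray
    l1_penalized: bool = False  # True for conv weights


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N*H*W, k*k*C) with same zero padding."""
    n, h, w, c = x.shape
    if k == 1:
        return x.reshape(n * h * w, c)
    p = k // 2
    x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = sliding_window_view(x, (k, k), axis=(1, 2))  # N,H,W,C,k,k
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n * h * w, k * k * c
    )


class Conv2d:
    """Same-padding k x k convolution (k odd); weights (k*k*cin, cout)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.w = (rng.standard_normal((fan_in, cout)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, h, w, _ = x.shape
        cols = _im2col(x, self.k)
        self._cols = cols if training else None
        self._shape = x.shape
        return (cols @ self.w + self.b).reshape(n, h, w, self.cout)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, h, w, _ = self._shape
        g2 = g.reshape(n * h * w, self.cout)
        self.gw += self._cols.T @ g2
        self.gb += g2.sum(axis=0)
        # input gradient = correlation of g with spatially flipped kernels
        k = self.k
        w4 = self.w.reshape(k, k, self.cin, self.cout)
        wr = np.ascontiguousarray(
            w4[::-1, ::-1].transpose(0, 1, 3, 2)
        ).reshape(k * k * self.cout, self.cin)
        dx = (_im2col(g, k) @ wr).reshape(n, h, w, self.cin)
        self._cols = None
        return dx

    def params(self):
        yield ParamSlot(f"conv{self.cin}x{self.cout}.w", self.w, self.gw, True)
        yield ParamSlot(f"conv{self.cin}x{self.cout}.b", self.b, self.gb, False)

    def state(self):
        return [self.w, self.b]


class BatchNorm2d:
    """Batch normalization over (N, H, W) per channel (channels-last)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        if training:
            self._cache = (xhat, invstd)
        return (self.gamma * xhat + self.beta).astype(np.float32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        self._cache = None
        self.ggamma += (g * xhat).sum(axis=(0, 1, 2))
        self.gbeta += g.sum(axis=(0, 1, 2))
        gxhat = g * self.gamma
        dx = (
            gxhat
            - gxhat.mean(axis=(0, 1, 2))
            - xhat * (gxhat * xhat).mean(axis=(0, 1, 2))
        ) * invstd
        return dx.astype(np.float32)

    def params(self):
        yield ParamSlot("bn.gamma", self.gamma, self.ggamma, False)
        yield ParamSlot("bn.beta", self.beta, self.gbeta, False)

    def state(self):
        return [self.gamma, self.beta, self.running_mean, self.running_var]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x, training):
        self._mask = x > 0 if training else None
        return np.maximum(x, 0)

    def backward(self, g):
        g = g * self._mask
        self._mask = None
        return g

    def params(self):
        return ()

    def state(self):
        return []


class MaxPool2:
    """2x2 max pooling, stride 2, channels-last."""

    def forward(self, x, training):
        n, h, w, c = x.shape
        xr = np.ascontiguousarray(
            x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        ).reshape(n, h // 2, w // 2, c, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, g):
        n, h, w, c = self._shape
        out = np.zeros((n, h // 2, w // 2, c, 4), dtype=g.dtype)
        np.put_along_axis(out, self._idx[..., None], g[..., None], axis=-1)
        out = out.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(out.reshape(n, h, w, c))

    def params(self):
        return ()

    def state(self):
        return []


class Upsample2:
    """Nearest-neighbour 2x upsampling, channels-last."""

    def forward(self, x, training):
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, g):
        n, h, w, c = g.shape
        return g.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))

    def params(self):
        return ()

    def state(self):
        return []


class Dropout:
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, training):
        if not training or self.p <= 0:
            return x
        self._mask = (self.rng.uniform(size=x.shape) >= self.p).astype(
            np.float32
        ) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        if self._mask is None:
            return g
        g = g * self._mask
        self._mask = None
        return g

    def params(self):
        return ()

    def state(self):
        return []


class Block:
    """A plain sequence of layers."""

    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        for layer in self.layers:
            yield from layer.params()

    def state(self):
        out = []
        for layer in self.layers:
            out.extend(layer.state())
        return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, classes: np.ndarray, weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Per-pixel weighted softmax cross-entropy, normalized by total weight.

    ``logits``: (N, H, W, K); ``classes``: (N, H, W) ints; ``weights``:
    (N, H, W).  Returns (loss, dloss/dlogits).
    """
    p = softmax(logits, axis=-1)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, classes[..., None], 1.0, axis=-1)
    wsum = float(weights.sum())
    py = np.take_along_axis(p, classes[..., None], axis=-1)[..., 0]
    loss = float((weights * -np.log(np.clip(py, 1e-12, None))).sum() / wsum)
    dlogits = (p - onehot) * weights[..., None] / wsum
    return loss, dlogits.astype(np.float32)


class Adam:
    """Adam with stepwise exponential learning-rate decay."""

    def __init__(
        self,
        slots,
        lr: float,
        decay: float = 0.98,
        decay_every: int = 5000,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.slots = list(slots)
        self.lr0, self.decay, self.decay_every = lr, decay, decay_every
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(s.value) for s in self.slots]
        self.v = [np.zeros_like(s.value) for s in self.slots]
        self.t = 0

    @property
    def lr(self) -> float:
        return self.lr0 * self.decay ** (self.t // self.decay_every)

    def step(self) -> None:
        self.t += 1
        lr = self.lr
        b1, b2 = self.beta1, self.beta2
        for slot, m, v in zip(self.slots, self.m, self.v):
            g = slot.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            slot.value -= lr * mhat / (np.sqrt(vhat) + self.eps)
            slot.grad[...] = 0.0
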