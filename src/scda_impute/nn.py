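"""Minimal 1-D convolutional network primitives with reverse-mode gradients.

Everything operates on arrays shaped ``(batch, length, channels)`` in
float32. Convolutions are evaluated as an im2col matrix product so the
heavy lifting runs through BLAS; backward passes reuse the cached column
matrix. The only consumers are the genotype autoencoder in
:mod:`scda_impute.model` and its tests, so the layer zoo is deliberately
small: same-padded conv, ReLU/sigmoid, max-pool and nearest-neighbour
upsample of width 2, inverted dropout, and Adam.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv1d_same",
    "Conv1D",
    "ReLU",
    "Sigmoid",
    "MaxPool1D",
    "Upsample1D",
    "Dropout",
    "Adam",
]


def conv1d_same(
    x: np.ndarray,
    filters: np.ndarray,
    biases: np.ndarray,
    activation=None,
) -> np.ndarray:
    """Same-padded multi-channel discrete convolution.

    ``out[..., i, m] = act(sum_{u,d} filters[m, d, u] *
    x_padded[..., i + u - k//2, d] + biases[m])`` with zero padding, so the
    output length equals the input length. ``filters`` has shape
    ``(n_filters, in_channels, k)`` with odd ``k``.

    Accepts ``(length, channels)`` or ``(batch, length, channels)`` input
    and returns the matching shape with ``n_filters`` channels.
    """
    x = np.asarray(x)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    n_filters, in_ch, k = np.asarray(filters).shape
    if k % 2 == 0:
        raise ValueError(f"filter size must be odd, got {k}")
    if x.shape[2] != in_ch:
        raise ValueError("input channel count does not match filters")
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    # windows: (B, L, in_ch, k); flatten to (B*L, in_ch*k)
    win = sliding_window_view(xp, k, axis=1)
    B, L = x.shape[0], x.shape[1]
    cols = win.reshape(B * L, in_ch * k)
    wmat = np.asarray(filters).reshape(n_filters, in_ch * k).T
    out = (cols @ wmat).reshape(B, L, n_filters) + np.asarray(biases)
    if activation is not None:
        out = activation(out)
    return out[0] if squeeze else out


class Layer:
    """Forward/backward pair with optional parameters."""

    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Same-padded 1-D convolution, weights ``(out_ch, in_ch, k)``.

    He-uniform initialisation; ``k`` must be odd.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        if k % 2 == 0 or k < 1:
            raise ValueError(f"filter size must be odd and >= 1, got {k}")
        limit = np.sqrt(6.0 / (in_ch * k))
        self.W = rng.uniform(-limit, limit, size=(out_ch, in_ch, k)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.k = k
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, int] | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, L, _ = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        win = sliding_window_view(xp, self.k, axis=1)
        cols = np.ascontiguousarray(win).reshape(B * L, self.in_ch * self.k)
        wmat = self.W.reshape(self.out_ch, -1).T
        out = (cols @ wmat).reshape(B, L, self.out_ch) + self.b
        if training:
            self._cols = cols
            self._shape = (B, L)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._cols is not None and self._shape is not None
        B, L = self._shape
        dflat = dout.reshape(B * L, self.out_ch)
        self.grads[0][...] = (self._cols.T @ dflat).T.reshape(self.W.shape)
        self.grads[1][...] = dflat.sum(axis=0)
        dcols = (dflat @ self.W.reshape(self.out_ch, -1)).reshape(
            B, L, self.in_ch, self.k
        )
        pad = self.k // 2
        dxp = np.zeros((B, L + 2 * pad, self.in_ch), dtype=dout.dtype)
        for u in range(self.k):
            dxp[:, u : u + L, :] += dcols[:, :, :, u]
        self._cols = None
        return dxp[:, pad : pad + L, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x))
        if training:
            self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._out * (1.0 - self._out)


class MaxPool1D(Layer):
    """Non-overlapping max filter of width ``size`` along the length axis.

    Input length must be divisible by ``size``; ties take the first
    (leftmost) maximum.
    """

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, L, C = x.shape
        if L % self.size:
            raise ValueError(f"length {L} not divisible by pool size {self.size}")
        xr = x.reshape(B, L // self.size, self.size, C)
        if training:
            self._argmax = xr.argmax(axis=2)
            self._shape = (B, L, C)
        return xr.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, L, C = self._shape
        dxr = np.zeros((B, L // self.size, self.size, C), dtype=dout.dtype)
        bi, li, ci = np.ogrid[: B, : L // self.size, : C]
        dxr[bi, li, self._argmax, ci] = dout
        return dxr.reshape(B, L, C)


class Upsample1D(Layer):
    """Nearest-neighbour upsampling: repeats each position ``size`` times."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return np.repeat(x, self.size, axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, L, C = dout.shape
        return dout.reshape(B, L // self.size, self.size, C).sum(axis=2)


class Dropout(Layer):
    """Inverted dropout: active only during training, identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Adam:
    """Adam optimiser over a flat list of parameter/gradient pairs."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Channel-wise softmax over the last axis, numerically stabilised."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
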