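"""Minimal neural-network engine used by the Hyper3DNetReg model.

Implements exactly the layer types the architecture needs — 3-D convolution,
depthwise-separable 2-D convolution, plain 2-D convolution, batch
normalization, ReLU, dropout and a fully connected layer — with explicit
forward/backward passes over numpy arrays, plus the Adadelta optimizer.

Conventions
-----------
* Tensors are channels-last: 2-D tensors are ``(B, H, W, C)``; 3-D tensors
  are ``(B, D, H, W, C)`` where ``D`` is the covariate (spectral) axis of
  the input data cube. Channels-last keeps the im2col gather/scatter
  copies contiguous, which dominates the runtime of the small-window
  convolutions this model uses.
* Every layer caches what its backward pass needs during ``forward`` with
  ``train=True``; ``backward`` consumes the cache and fills ``layer.grads``.
* Trainable parameters live in ``layer.params`` (dict of name -> ndarray);
  gradients appear under the same keys in ``layer.grads``.

All gradients are validated against central finite differences in the test
suite, which is the engine's correctness oracle.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv3D",
    "Conv2D",
    "SepConv2D",
    "BatchNorm",
    "ReLU",
    "Dropout",
    "Dense",
    "Adadelta",
    "glorot_uniform",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int,
                   dtype=np.float32) -> np.ndarray:
    """Glorot/Xavier uniform initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base class: named container of parameters and gradients."""

    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))


# ---------------------------------------------------------------------------
# convolutions

def _offsets(k: int, ndim: int):
    """All kernel offsets of a ``k**ndim`` window, kernel-major order."""
    if ndim == 2:
        return [(dy, dx) for dy in range(k) for dx in range(k)]
    return [(dz, dy, dx) for dz in range(k) for dy in range(k)
            for dx in range(k)]


def _off_slice(off, out_spatial):
    return (slice(None),) + tuple(slice(o, o + n) for o, n in
                                  zip(off, out_spatial)) + (slice(None),)


class _ConvND(Layer):
    """Shared machinery of the 2-D and 3-D convolutions (stride 1, symmetric
    zero padding).

    The convolution is evaluated as a sum of ``k**s`` shifted channel
    matmuls — one GEMM per kernel offset against the matching row block of
    the kernel-major weight matrix ``(k**s * C_in, C_out)`` — instead of a
    materialized im2col buffer; for the tiny 5 x 5 x n volumes this model
    convolves, the shifted contiguous copies are far cheaper than the
    strided im2col gather.
    """

    spatial_ndim: int

    def __init__(self, name, in_ch, out_ch, k, pad, rng, dtype):
        super().__init__(name)
        rng = rng or np.random.default_rng()
        fan_in = k ** self.spatial_ndim * in_ch
        self.k, self.pad, self.in_ch, self.out_ch = k, pad, in_ch, out_ch
        self.params["w"] = glorot_uniform(rng, (fan_in, out_ch), fan_in,
                                          out_ch, dtype)
        self.params["b"] = np.zeros(out_ch, dtype=dtype)

    def forward(self, x, train=False):
        if x.shape[-1] != self.in_ch:
            raise ValueError(f"{self.name}: expected {self.in_ch} input "
                             f"channels, got {x.shape[-1]}")
        p, k, s, C = self.pad, self.k, self.spatial_ndim, self.in_ch
        spatial = x.shape[1:1 + s]
        out_spatial = tuple(n + 2 * p - k + 1 for n in spatial)
        pw = ((0, 0),) + ((p, p),) * s + ((0, 0),)
        xp = np.pad(x, pw) if p else x
        w = self.params["w"]
        out = np.tile(self.params["b"],
                      (x.shape[0] * int(np.prod(out_spatial)), 1))
        for idx, off in enumerate(_offsets(k, s)):
            xs = np.ascontiguousarray(xp[_off_slice(off, out_spatial)])
            out += xs.reshape(-1, C) @ w[idx * C:(idx + 1) * C]
        if train:
            self._cache = (xp, out_spatial)
        return out.reshape(x.shape[0], *out_spatial, self.out_ch)

    def backward(self, dout):
        xp, out_spatial = self._cache
        p, k, s, C = self.pad, self.k, self.spatial_ndim, self.in_ch
        w = self.params["w"]
        d2 = np.ascontiguousarray(dout.reshape(-1, self.out_ch))
        dw = np.empty_like(w)
        dxp = np.zeros_like(xp)
        block = dout.shape[:1] + tuple(out_spatial) + (C,)
        for idx, off in enumerate(_offsets(k, s)):
            sl = _off_slice(off, out_spatial)
            xs = np.ascontiguousarray(xp[sl])
            dw[idx * C:(idx + 1) * C] = xs.reshape(-1, C).T @ d2
            dxp[sl] += (d2 @ w[idx * C:(idx + 1) * C].T).reshape(block)
        self.grads["w"] = dw
        self.grads["b"] = d2.sum(axis=0)
        if p:
            sl = (slice(None),) + (slice(p, -p),) * s + (slice(None),)
            dxp = dxp[sl]
        return dxp


class Conv2D(_ConvND):
    """2-D convolution, kernel ``k x k``, stride 1, symmetric zero padding."""

    spatial_ndim = 2

    def __init__(self, name: str, in_ch: int, out_ch: int, k: int = 3,
                 pad: int = 1, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__(name, in_ch, out_ch, k, pad, rng, dtype)


class Conv3D(_ConvND):
    """3-D convolution over a ``(D, H, W)`` volume, kernel 3x3x3, padding 1.

    Input/output are ``(B, D, H, W, C)``; padding keeps all three volume
    dimensions unchanged so the spatial footprint never shrinks.
    """

    spatial_ndim = 3

    def __init__(self, name: str, in_ch: int, out_ch: int, k: int = 3,
                 pad: int = 1, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__(name, in_ch, out_ch, k, pad, rng, dtype)


class SepConv2D(Layer):
    """Depthwise-separable 2-D convolution: per-channel ``k x k`` depthwise
    convolution followed by a 1x1 pointwise convolution, each with a bias."""

    def __init__(self, name: str, in_ch: int, out_ch: int, k: int = 3,
                 pad: int = 1, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__(name)
        rng = rng or np.random.default_rng()
        self.k, self.pad, self.in_ch, self.out_ch = k, pad, in_ch, out_ch
        self.params["dw"] = glorot_uniform(rng, (k * k, in_ch), k * k, 1, dtype)
        self.params["db"] = np.zeros(in_ch, dtype=dtype)
        self.params["pw"] = glorot_uniform(rng, (in_ch, out_ch), in_ch,
                                           out_ch, dtype)
        self.params["pb"] = np.zeros(out_ch, dtype=dtype)

    def forward(self, x, train=False):
        B, H, W, C = x.shape
        if C != self.in_ch:
            raise ValueError(f"{self.name}: expected {self.in_ch} input "
                             f"channels, got {C}")
        p, k = self.pad, self.k
        out_spatial = (H + 2 * p - k + 1, W + 2 * p - k + 1)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        mid = np.tile(self.params["db"], (B, *out_spatial, 1))
        for idx, off in enumerate(_offsets(k, 2)):
            mid += xp[_off_slice(off, out_spatial)] * self.params["dw"][idx]
        out = mid.reshape(-1, C) @ self.params["pw"] + self.params["pb"]
        if train:
            self._cache = (xp, mid, out_spatial)
        return out.reshape(B, *out_spatial, self.out_ch)

    def backward(self, dout):
        xp, mid, out_spatial = self._cache
        B = dout.shape[0]
        C, p, k = self.in_ch, self.pad, self.k
        d2 = dout.reshape(-1, self.out_ch)
        self.grads["pw"] = mid.reshape(-1, C).T @ d2
        self.grads["pb"] = d2.sum(axis=0)
        dmid = (d2 @ self.params["pw"].T).reshape(B, *out_spatial, C)
        self.grads["db"] = dmid.sum(axis=(0, 1, 2))
        ddw = np.empty_like(self.params["dw"])
        dxp = np.zeros_like(xp)
        for idx, off in enumerate(_offsets(k, 2)):
            sl = _off_slice(off, out_spatial)
            ddw[idx] = (xp[sl] * dmid).sum(axis=(0, 1, 2))
            dxp[sl] += dmid * self.params["dw"][idx]
        self.grads["dw"] = ddw
        return dxp[:, p:-p or None, p:-p or None, :] if p else dxp


# ---------------------------------------------------------------------------
# pointwise / normalization layers


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        super().__init__(name)

    def forward(self, x, train=False):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, name: str, p: float, rng: np.random.Generator):
        super().__init__(name)
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel axis (last).

    Normalizes with the biased batch variance during training and tracks
    running statistics (keep rate ``momentum``) for evaluation mode.
    """

    def __init__(self, name: str, channels: int, momentum: float = 0.9,
                 eps: float = 1e-5, dtype=np.float32):
        super().__init__(name)
        self.eps = eps
        self.momentum = momentum
        self.channels = channels
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + \
                (1 - self.momentum) * mean.astype(np.float64)
            self.running_var = self.momentum * self.running_var + \
                (1 - self.momentum) * var.astype(np.float64)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv
            self._cache = (xhat, inv, axes)
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = ((x - self.running_mean) * inv).astype(x.dtype)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        xhat, inv, axes = self._cache
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"]
        # standard batch-norm backward with biased variance
        return (dxhat - dxhat.mean(axis=axes)
                - xhat * (dxhat * xhat).mean(axis=axes)) * inv


class Dense(Layer):
    """Fully connected layer on ``(B, in_features)`` input."""

    def __init__(self, name: str, in_features: int, out_features: int,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__(name)
        rng = rng or np.random.default_rng()
        self.in_features, self.out_features = in_features, out_features
        self.params["w"] = glorot_uniform(rng, (in_features, out_features),
                                          in_features, out_features, dtype)
        if bias:
            self.params["b"] = np.zeros(out_features, dtype=dtype)

    def forward(self, x, train=False):
        if train:
            self._x = x
        out = x @ self.params["w"]
        if "b" in self.params:
            out = out + self.params["b"]
        return out

    def backward(self, dout):
        self.grads["w"] = self._x.T @ dout
        if "b" in self.params:
            self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["w"].T


# ---------------------------------------------------------------------------
# optimizer


class Adadelta:
    """Adadelta (Zeiler 2012): adaptive per-parameter step sizes that need no
    hand-tuned learning rate.

    Defaults rho=0.95, eps=1e-6 follow the original method; ``lr`` is a plain
    multiplier on the computed update (1.0 = the published rule).
    """

    def __init__(self, layers, rho: float = 0.95, eps: float = 1e-6,
                 lr: float = 1.0):
        self.layers = [ly for ly in layers if ly.params]
        self.rho, self.eps, self.lr = rho, eps, lr
        self._eg = [{k: np.zeros_like(v, dtype=np.float64)
                     for k, v in ly.params.items()} for ly in self.layers]
        self._ed = [{k: np.zeros_like(v, dtype=np.float64)
                     for k, v in ly.params.items()} for ly in self.layers]

    def step(self):
        r, e = self.rho, self.eps
        for ly, eg, ed in zip(self.layers, self._eg, self._ed):
            for k, p in ly.params.items():
                g = ly.grads[k].astype(np.float64)
                eg[k] = r * eg[k] + (1 - r) * g * g
                delta = -np.sqrt((ed[k] + e) / (eg[k] + e)) * g
                ed[k] = r * ed[k] + (1 - r) * delta * delta
                p += (self.lr * delta).astype(p.dtype)
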