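"""Minimal CPU building blocks for the 3D segmentation network.

Plain-numpy layers with explicit forward/backward passes: 3D convolutions
via im2col matrix multiplication, 2x max pooling, nearest-neighbour
upsampling, ReLU, and an Adam optimizer.  Tensors are laid out
channel-first with the batch axis second, ``(C, B, D, H, W)``, so that the
im2col buffers are filled by plain strided slice copies and every matrix
product runs over ``B * D * H * W`` columns at once.  Each layer caches
its last forward pass; ``backward`` must follow the matching ``forward``.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Conv3d:
    """Stride-1, same-padding 3D convolution (kernel 3 or 1).

    Weight layout is ``(cout, k^3 * cin)`` with column blocks ordered by
    kernel offset then input channel, matching the im2col buffer laid out
    as ``(k^3, cin, n_voxels)`` — all gather/scatter transfers are plain
    strided slice copies.
    """

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.cin, self.cout, self.k = cin, cout, ksize
        fan_in = cin * ksize ** 3
        std = np.sqrt(2.0 / fan_in)
        self.W = Param(rng.normal(0.0, std, size=(cout, fan_in)).astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def _offsets(self):
        k = self.k
        return [(dz, dy, dx) for dz in range(k) for dy in range(k) for dx in range(k)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, b, d, h, w = x.shape
        k, pad = self.k, self.k // 2
        n = b * d * h * w
        if k == 1:
            cols = np.ascontiguousarray(x).reshape(c, n)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
            cols5 = np.empty((k ** 3, c, b, d, h, w), dtype=x.dtype)
            for j, (dz, dy, dx) in enumerate(self._offsets()):
                cols5[j] = xp[:, :, dz:dz + d, dy:dy + h, dx:dx + w]
            cols = cols5.reshape(k ** 3 * c, n)
        out = self.W.value @ cols + self.b.value[:, None]
        self._cache = (cols, (c, b, d, h, w))
        return out.reshape(self.cout, b, d, h, w)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, (c, b, d, h, w) = self._cache
        k, pad = self.k, self.k // 2
        g = gy.reshape(self.cout, b * d * h * w)
        self.W.grad += g @ cols.T
        self.b.grad += g.sum(axis=1)
        if k == 1:
            return (self.W.value.T @ g).reshape(c, b, d, h, w)
        # col2im fused per kernel offset: small (cin, cout) @ (cout, n)
        # products avoid the skinny-inner-dimension GEMM that BLAS hates
        wr = self.W.value.reshape(self.cout, k ** 3, c)
        dxp = np.zeros((c, b, d + 2 * pad, h + 2 * pad, w + 2 * pad), dtype=gy.dtype)
        for j, (dz, dy, dx) in enumerate(self._offsets()):
            dxp[:, :, dz:dz + d, dy:dy + h, dx:dx + w] += (
                wr[:, j, :].T @ g).reshape(c, b, d, h, w)
        return dxp[:, :, pad:-pad, pad:-pad, pad:-pad]


class InstanceNorm3d:
    """Per-channel, per-sample normalization over the spatial axes.

    Stabilizes the Dice-loss optimization of the small U-Net, which has no
    other normalization and otherwise drifts into dead-ReLU collapse.
    """

    def __init__(self, channels: int, dtype=np.float32, eps: float = 1e-5):
        self.gamma = Param(np.ones((channels, 1, 1, 1, 1), dtype=dtype))
        self.beta = Param(np.zeros((channels, 1, 1, 1, 1), dtype=dtype))
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3, 4), keepdims=True)
        var = x.var(axis=(2, 3, 4), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=(1, 2, 3, 4), keepdims=True).reshape(
            self.gamma.value.shape)
        self.beta.grad += gy.sum(axis=(1, 2, 3, 4), keepdims=True).reshape(
            self.beta.value.shape)
        dxhat = gy * self.gamma.value
        m1 = dxhat.mean(axis=(2, 3, 4), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3, 4), keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class ReLU:
    """Leaky rectifier (slope 0.1 for negative inputs).

    The small negative slope keeps gradient flowing to channels that the
    Dice loss has temporarily suppressed, which matters for the scarce
    vessel classes.
    """

    def __init__(self, slope: float = 0.1):
        self.slope = slope
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, self.slope * gy)


class MaxPool3d:
    """2x2x2 max pooling; spatial dims must be even."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, b, d, h, w = x.shape
        xr = x.reshape(c, b, d // 2, 2, h // 2, 2, w // 2, 2)
        xr = np.ascontiguousarray(xr.transpose(0, 1, 2, 4, 6, 3, 5, 7)).reshape(
            c, b, d // 2, h // 2, w // 2, 8)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (c, b, d, h, w))
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        idx, (c, b, d, h, w) = self._cache
        dxr = np.zeros((c, b, d // 2, h // 2, w // 2, 8), dtype=gy.dtype)
        np.put_along_axis(dxr, idx[..., None], gy[..., None], axis=-1)
        dxr = dxr.reshape(c, b, d // 2, h // 2, w // 2, 2, 2, 2)
        return np.ascontiguousarray(dxr.transpose(0, 1, 2, 5, 3, 6, 4, 7)).reshape(
            c, b, d, h, w)


class Upsample3d:
    """Nearest-neighbour 2x upsampling."""

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        c, b, d, h, w = gy.shape
        return gy.reshape(c, b, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


class Adam:
    """Adaptive-moment gradient descent over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, grad_scale: float = 1.0) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad * grad_scale
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def clip_grad_norm(self, max_norm: float) -> float:
        total = float(np.sqrt(sum(float((p.grad * p.grad).sum()) for p in self.params)))
        if total > max_norm:
            scale = max_norm / (total + 1e-12)
            for p in self.params:
                p.grad *= scale
        return total
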