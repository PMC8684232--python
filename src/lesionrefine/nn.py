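"""Minimal CPU neural-network primitives used by the segmentation networks.

Everything operates on ``(N, C, H, W)`` arrays.  Each layer caches what its
backward pass needs; gradients accumulate into ``Param.grad`` and are consumed
by :class:`SGDMomentum`.  Spatially linear operators (bilinear resize,
adaptive average pooling) are expressed as sparse matrices so that forward and
backward are a single sparse product each — exact, fast, and trivially
transposable.

The stack is deliberately small: convolutions (with stride and dilation),
ReLU, bilinear resize, adaptive pooling, momentum SGD with weight decay, and a
binary cross-entropy-with-logits loss are all the segmentation heads need.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Param",
    "Conv2d",
    "ReLU",
    "BilinearResize",
    "AdaptiveAvgPool",
    "GlobalAvgPool",
    "Sequential",
    "SGDMomentum",
    "bce_with_logits",
    "sigmoid",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy on sigmoid(logits); returns (loss, dloss/dlogits)."""
    z = np.asarray(logits, dtype=float)
    t = np.asarray(targets, dtype=float)
    # log(1 + exp(-|z|)) formulation, numerically stable
    loss = np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))
    grad = (sigmoid(z) - t) / z.size
    return float(loss), grad.astype(z.dtype)


class Layer:
    def params(self) -> list:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Conv2d(Layer):
    """2-D convolution via k*k shifted views (im2col without the big copy)."""

    def __init__(
        self,
        rng: np.random.Generator,
        cin: int,
        cout: int,
        k: int = 3,
        stride: int = 1,
        dilation: int = 1,
        pad: int | None = None,
        dtype=np.float32,
    ):
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.dilation = stride, dilation
        self.pad = dilation * (k - 1) // 2 if pad is None else pad
        std = np.sqrt(2.0 / (cin * k * k))  # He initialization (ReLU nets)
        self.w = Param((rng.standard_normal((cout, cin * k * k)) * std).astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))
        self._cache = None

    def params(self) -> list:
        return [self.w, self.b]

    def _out_hw(self, h: int, w: int) -> tuple:
        span = self.dilation * (self.k - 1) + 1
        ho = (h + 2 * self.pad - span) // self.stride + 1
        wo = (w + 2 * self.pad - span) // self.stride + 1
        return ho, wo

    def _im2col(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        n, c = xp.shape[:2]
        s, d, k = self.stride, self.dilation, self.k
        cols = np.empty((n, c, k * k, ho, wo), dtype=xp.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, i * k + j] = xp[
                    :, :, i * d : i * d + ho * s : s, j * d : j * d + wo * s : s
                ]
        return cols.reshape(n, c * k * k, ho * wo)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = self._out_hw(h, w)
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = self._im2col(xp, ho, wo)
        y = self.w.value @ cols  # (N, cout, L)
        y += self.b.value[None, :, None]
        self._cache = (cols, xp.shape, (h, w), (ho, wo))
        return y.reshape(n, self.cout, ho, wo)

    def backward(self, dy: np.ndarray, need_input_grad: bool = True):
        cols, xp_shape, (h, w), (ho, wo) = self._cache
        n = dy.shape[0]
        dyf = dy.reshape(n, self.cout, ho * wo)
        self.w.grad += np.tensordot(dyf, cols, axes=([0, 2], [0, 2]))
        self.b.grad += dyf.sum(axis=(0, 2))
        if not need_input_grad:
            return None
        dcols = (self.w.value.T @ dyf).reshape(n, self.cin, self.k * self.k, ho, wo)
        dxp = np.zeros(xp_shape, dtype=dy.dtype)
        s, d, k, p = self.stride, self.dilation, self.k, self.pad
        for i in range(k):
            for j in range(k):
                dxp[:, :, i * d : i * d + ho * s : s, j * d : j * d + wo * s : s] += dcols[
                    :, :, i * k + j
                ]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class _SpatialLinear(Layer):
    """y = M @ x over the flattened spatial axis; backward is M^T."""

    def __init__(self, matrix: sp.spmatrix, in_hw: tuple, out_hw: tuple):
        self.m = matrix.tocsr()
        self.mt = self.m.T.tocsr()
        self.in_hw, self.out_hw = in_hw, out_hw

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c = x.shape[:2]
        xf = x.reshape(n * c, -1)
        yf = (self.m @ xf.T).T
        return np.ascontiguousarray(yf, dtype=x.dtype).reshape(n, c, *self.out_hw)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c = dy.shape[:2]
        dyf = dy.reshape(n * c, -1)
        dxf = (self.mt @ dyf.T).T
        return np.ascontiguousarray(dxf, dtype=dy.dtype).reshape(n, c, *self.in_hw)


_MATRIX_CACHE: dict = {}


def bilinear_matrix(in_hw: tuple, out_hw: tuple) -> sp.csr_matrix:
    """Sparse bilinear interpolation matrix, half-pixel-centred (like image resize)."""
    key = ("bilinear", in_hw, out_hw)
    if key in _MATRIX_CACHE:
        return _MATRIX_CACHE[key]
    (hi, wi), (ho, wo) = in_hw, out_hw

    def axis_weights(n_in, n_out):
        src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        src = np.clip(src, 0, n_in - 1)
        lo = np.floor(src).astype(int)
        hi_ = np.minimum(lo + 1, n_in - 1)
        frac = src - lo
        return lo, hi_, frac

    r0, r1, fr = axis_weights(hi, ho)
    c0, c1, fc = axis_weights(wi, wo)
    rows, cols, vals = [], [], []
    out_idx = np.arange(ho * wo)
    for ri, wr in ((r0, 1 - fr), (r1, fr)):
        for ci, wc in ((c0, 1 - fc), (c1, fc)):
            rows.append(out_idx)
            cols.append((ri[:, None] * wi + ci[None, :]).ravel())
            vals.append((wr[:, None] * wc[None, :]).ravel())
    m = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ho * wo, hi * wi),
    )
    m.sum_duplicates()
    _MATRIX_CACHE[key] = m
    return m


def avgpool_matrix(in_hw: tuple, grid: tuple) -> sp.csr_matrix:
    """Adaptive average pooling to a grid; regions use floor/ceil boundaries."""
    key = ("avgpool", in_hw, grid)
    if key in _MATRIX_CACHE:
        return _MATRIX_CACHE[key]
    (hi, wi), (gh, gw) = in_hw, grid
    rows, cols, vals = [], [], []
    for a in range(gh):
        r0, r1 = (a * hi) // gh, -(-((a + 1) * hi) // gh)
        for b in range(gw):
            c0, c1 = (b * wi) // gw, -(-((b + 1) * wi) // gw)
            region = (np.arange(r0, r1)[:, None] * wi + np.arange(c0, c1)[None, :]).ravel()
            rows.extend([a * gw + b] * region.size)
            cols.extend(region.tolist())
            vals.extend([1.0 / region.size] * region.size)
    m = sp.csr_matrix((vals, (rows, cols)), shape=(gh * gw, hi * wi))
    _MATRIX_CACHE[key] = m
    return m


class BilinearResize(_SpatialLinear):
    def __init__(self, in_hw: tuple, out_hw: tuple):
        super().__init__(bilinear_matrix(in_hw, out_hw), in_hw, out_hw)


class AdaptiveAvgPool(_SpatialLinear):
    def __init__(self, in_hw: tuple, grid: tuple):
        super().__init__(avgpool_matrix(in_hw, grid), in_hw, grid)


class GlobalAvgPool(AdaptiveAvgPool):
    def __init__(self, in_hw: tuple):
        super().__init__(in_hw, (1, 1))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class SGDMomentum:
    """SGD with classical momentum and decoupled-from-schedule weight decay.

    update: v <- mu * v + (g + wd * w);  w <- w - lr * v
    """

    def __init__(self, params: list, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = params
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self.velocity):
            g = p.grad + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value -= (lr * v).astype(p.value.dtype)
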