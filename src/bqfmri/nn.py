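"""Minimal 3D convolutional neural-net engine on NumPy.

Provides exactly the pieces the volumetric autoencoder needs: 3x3x3
convolutions (stride 1 or 2, zero padding 1), stride-2 transpose
convolutions (implemented as the exact adjoint of the strided convolution,
so spatial size doubles), ReLU, mean-squared-error loss, and Adam.

Layout is channels-last: activations are (batch, D, H, W, C) arrays,
float32 in the training loop.  Convolutions materialize an im2col matrix
once per call (``sliding_window_view`` + reshape) and run plain 2D
matmuls against it; the transpose convolution scatters columns back
(col2im).  Everything is deterministic given the seeded
``numpy.random.Generator`` used for initialization and batch shuffling.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_K = 3  # kernel size, fixed
_P = 1  # zero padding per side


def _pad_spatial(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((0, 0), (_P, _P), (_P, _P), (_P, _P), (0, 0)))


def _im2col(x_padded: np.ndarray, stride: int) -> np.ndarray:
    """(B, Dp, Hp, Wp, C) -> window view (B, Do, Ho, Wo, C, 3, 3, 3)."""
    win = sliding_window_view(x_padded, (_K, _K, _K), axis=(1, 2, 3))
    return win[:, ::stride, ::stride, ::stride]


def _col2im(cols: np.ndarray, spatial_padded: tuple[int, int, int],
            stride: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add (B, Do, Ho, Wo, C, 3, 3, 3) columns."""
    b, do, ho, wo, c = cols.shape[:5]
    out = np.zeros((b, *spatial_padded, c), dtype=cols.dtype)
    for i, j, k in product(range(_K), repeat=3):
        out[:, i:i + stride * do:stride,
            j:j + stride * ho:stride,
            k:k + stride * wo:stride, :] += cols[..., i, j, k]
    return out


class Layer:
    params: dict
    grads: dict

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv3D(Layer):
    """3x3x3 convolution, zero padding 1, stride 1 (same size) or 2 (halves)."""

    def __init__(self, c_in: int, c_out: int, stride: int,
                 rng: np.random.Generator) -> None:
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        self.stride = stride
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / (_K**3 * c_in))
        w = rng.standard_normal((c_in, _K, _K, _K, c_out)) * scale
        self.params = {"w": w.astype(np.float32),
                       "b": np.zeros(c_out, dtype=np.float32)}
        self.grads = {}
        self._cols2d: np.ndarray | None = None
        self._in_spatial: tuple[int, int, int] | None = None
        self._out_spatial: tuple[int, int, int] | None = None

    def _w2d(self) -> np.ndarray:
        return self.params["w"].reshape(self.c_in * _K**3, self.c_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_spatial = x.shape[1:4]
        cols = _im2col(_pad_spatial(x), self.stride)
        b = cols.shape[0]
        self._out_spatial = cols.shape[1:4]
        self._cols2d = cols.reshape(-1, self.c_in * _K**3)  # single copy
        y = self._cols2d @ self._w2d() + self.params["b"]
        return y.reshape(b, *self._out_spatial, self.c_out)

    def backward(self, g: np.ndarray) -> np.ndarray:
        b = g.shape[0]
        g2d = g.reshape(-1, self.c_out)
        self.grads["w"] = (self._cols2d.T @ g2d).reshape(self.params["w"].shape)
        self.grads["b"] = g2d.sum(axis=0)
        gcols = (g2d @ self._w2d().T).reshape(
            b, *self._out_spatial, self.c_in, _K, _K, _K)
        padded = tuple(s + 2 * _P for s in self._in_spatial)
        gx = _col2im(gcols, padded, self.stride)
        return gx[:, _P:-_P, _P:-_P, _P:-_P, :]


class ConvTranspose3D(Layer):
    """Stride-2 transpose convolution (kernel 3): doubles each spatial dim.

    Forward is the exact adjoint of ``Conv3D(stride=2)``'s forward, so its
    backward pass is that convolution's forward.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        self.stride = 2
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / (_K**3 * c_in))
        w = rng.standard_normal((c_in, c_out, _K, _K, _K)) * scale
        self.params = {"w": w.astype(np.float32),
                       "b": np.zeros(c_out, dtype=np.float32)}
        self.grads = {}
        self._x2d: np.ndarray | None = None
        self._in_spatial: tuple[int, int, int] | None = None

    def _w2d(self) -> np.ndarray:
        return self.params["w"].reshape(self.c_in, self.c_out * _K**3)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b = x.shape[0]
        self._in_spatial = x.shape[1:4]
        self._x2d = x.reshape(-1, self.c_in)
        cols = (self._x2d @ self._w2d()).reshape(
            b, *self._in_spatial, self.c_out, _K, _K, _K)
        out_spatial = tuple(2 * s for s in self._in_spatial)
        padded = tuple(s + 2 * _P for s in out_spatial)
        y = _col2im(cols, padded, self.stride)[:, _P:-_P, _P:-_P, _P:-_P, :]
        return y + self.params["b"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        gcols2d = _im2col(_pad_spatial(g), self.stride).reshape(
            -1, self.c_out * _K**3)
        self.grads["w"] = (self._x2d.T @ gcols2d).reshape(self.params["w"].shape)
        self.grads["b"] = g.reshape(-1, self.c_out).sum(axis=0)
        gx = gcols2d @ self._w2d().T
        return gx.reshape(g.shape[0], *self._in_spatial, self.c_in)


class ReLU(Layer):
    def __init__(self) -> None:
        self.params, self.grads = {}, {}
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, 0.0)


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class Adam:
    """Adam with the standard bias-corrected first/second moments."""

    def __init__(self, layers: list[Layer], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.slots = [(layer, name,
                       np.zeros_like(layer.params[name]),
                       np.zeros_like(layer.params[name]))
                      for layer in layers for name in layer.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, name, m, v in self.slots:
            g = layer.grads[name].astype(m.dtype, copy=False)
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            layer.params[name] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements and its gradient wrt pred."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    return loss, (2.0 / diff.size) * diff
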