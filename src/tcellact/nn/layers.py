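"""Layers for the NumPy neural-network engine.

Every layer implements ``forward(x)`` (caching what backward needs),
``backward(grad)`` (returning the gradient with respect to the layer input
and storing parameter gradients), and exposes ``params`` /``grads`` lists of
arrays sharing order.  Convolutions use im2col; shapes are NCHW.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Layer", "Dense", "ReLU", "Flatten", "Conv2D", "MaxPool2D",
           "AvgPool2D", "GlobalAvgPool"]


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]
    trainable: bool = True

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    """Affine layer y = xW + b with He-style random init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class ReLU(Layer):
    """Rectifier.  In guided mode the backward pass additionally zeroes
    negative upstream gradients (guided backpropagation)."""

    guided = False

    def __init__(self) -> None:
        super().__init__()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._gate = x > 0
        return np.where(self._gate, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = np.where(self._gate, grad, 0.0)
        if self.guided:
            out = np.where(grad > 0, out, 0.0)
        return out


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int):
    n, c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, shape=(n, c, oh, ow, kh, kw),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3))
    return windows.reshape(n, c, oh * ow, kh * kw), oh, ow


class Conv2D(Layer):
    """Valid-mode convolution (cross-correlation), stride 1, NCHW."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, padding: int = 0):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel))
        self.b = np.zeros(c_out)
        self.kernel = kernel
        self.padding = padding
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.padding:
            p = self.padding
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._x = x
        k = self.kernel
        cols, oh, ow = _im2col(x, k, k, 1)  # (n, c, oh*ow, k*k)
        n, c = x.shape[:2]
        cols2 = cols.transpose(0, 2, 1, 3).reshape(n, oh * ow, c * k * k)
        self._cols2 = cols2
        Wmat = self.W.reshape(self.W.shape[0], -1)  # (c_out, c*k*k)
        out = cols2 @ Wmat.T + self.b
        self._oh, self._ow = oh, ow
        return out.transpose(0, 2, 1).reshape(n, -1, oh, ow)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c_out, oh, ow = grad.shape
        g2 = grad.reshape(n, c_out, oh * ow).transpose(0, 2, 1)  # (n,ohw,co)
        Wmat = self.W.reshape(c_out, -1)
        gW = np.einsum("npo,npk->ok", g2, self._cols2)
        self.grads[0][...] = gW.reshape(self.W.shape)
        self.grads[1][...] = grad.sum(axis=(0, 2, 3))
        gcols2 = g2 @ Wmat  # (n, oh*ow, c*k*k)
        # col2im accumulate
        k = self.kernel
        c = self._x.shape[1]
        gx = np.zeros_like(self._x)
        gcols = gcols2.reshape(n, oh, ow, c, k, k)
        for di in range(k):
            for dj in range(k):
                gx[:, :, di : di + oh, dj : dj + ow] += \
                    gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        if self.padding:
            p = self.padding
            gx = gx[:, :, p:-p, p:-p]
        return gx


class MaxPool2D(Layer):
    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        s = self.size
        oh, ow = h // s, w // s
        self._inshape = x.shape
        x = x[:, :, : oh * s, : ow * s]
        self._xshape = x.shape
        xr = x.reshape(n, c, oh, s, ow, s)
        out = xr.max(axis=(3, 5))
        self._argmask = (xr == out[:, :, :, None, :, None])
        # break ties deterministically: keep only first max per window
        flat = self._argmask.reshape(n, c, oh, ow, s * s)
        first = np.argmax(
            self._argmask.transpose(0, 1, 2, 4, 3, 5).reshape(
                n, c, oh, ow, s * s), axis=-1)
        m = np.zeros((n, c, oh, ow, s * s), dtype=bool)
        np.put_along_axis(m, first[..., None], True, axis=-1)
        self._mask = m.reshape(n, c, oh, ow, s, s).transpose(0, 1, 2, 4, 3, 5)
        del flat
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        s = self.size
        g = (self._mask * grad[:, :, :, None, :, None]).reshape(self._xshape)
        if self._xshape != self._inshape:
            full = np.zeros(self._inshape)
            full[:, :, : self._xshape[2], : self._xshape[3]] = g
            return full
        return g


class AvgPool2D(Layer):
    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        s = self.size
        oh, ow = h // s, w // s
        self._inshape = x.shape
        x = x[:, :, : oh * s, : ow * s]
        self._xshape = x.shape
        return x.reshape(n, c, oh, s, ow, s).mean(axis=(3, 5))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        s = self.size
        gb = grad[:, :, :, None, :, None] / (s * s)
        g = np.broadcast_to(
            gb, grad.shape[:3] + (s, grad.shape[3], s)).reshape(self._xshape)
        if self._xshape != self._inshape:
            full = np.zeros(self._inshape)
            full[:, :, : self._xshape[2], : self._xshape[3]] = g
            return full
        return np.ascontiguousarray(g)


class GlobalAvgPool(Layer):
    """Average over all spatial positions: (n, c, h, w) -> (n, c)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        return np.broadcast_to(
            grad[:, :, None, None] / (h * w), self._xshape).copy()
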