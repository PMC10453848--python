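"""Layer primitives with explicit forward/backward passes.

Array layout is NCHW throughout. Convolutions use im2col backed by
``numpy.lib.stride_tricks.sliding_window_view``; ``padding="same"`` follows
the ceil-mode convention (output size ``ceil(n / stride)``) with asymmetric
zero padding when the total pad is odd.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor plus its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, *, train: bool = False, rng=None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError

    def __call__(self, x, **kw):
        return self.forward(x, **kw)


class Identity(Layer):
    def forward(self, x, *, train=False, rng=None):
        return x

    def backward(self, dy):
        return dy


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with stride and same/valid padding."""

    def __init__(self, cin, cout, k=3, stride=1, padding="same", *, rng, bias=True):
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        self.k = int(k)
        self.stride = int(stride)
        self.padding = padding
        self.W = Param(he_normal(rng, (cout, cin, self.k, self.k), cin * self.k * self.k))
        self.b = Param(np.zeros(cout)) if bias else None
        self._cache = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def _pads(self, h, w):
        if self.padding == "valid":
            return 0, 0, 0, 0
        s, k = self.stride, self.k
        th = max((-(-h // s) - 1) * s + k - h, 0)
        tw = max((-(-w // s) - 1) * s + k - w, 0)
        return th // 2, th - th // 2, tw // 2, tw - tw // 2

    def forward(self, x, *, train=False, rng=None):
        n, c, h, w = x.shape
        p0, p1, p2, p3 = pads = self._pads(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (p0, p1), (p2, p3)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, :: self.stride, :: self.stride]
        oh, ow = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(
            n, c * self.k * self.k, oh * ow
        )
        wmat = self.W.value.reshape(self.W.value.shape[0], -1)
        y = np.einsum("ok,nkl->nol", wmat, cols, optimize=True)
        if self.b is not None:
            y = y + self.b.value[None, :, None]
        self._cache = (x.shape, pads, cols, oh, ow)
        return y.reshape(n, -1, oh, ow)

    def backward(self, dy):
        (n, c, h, w), (p0, p1, p2, p3), cols, oh, ow = self._cache
        o = dy.shape[1]
        dyf = dy.reshape(n, o, oh * ow)
        self.W.grad += np.einsum("nol,nkl->ok", dyf, cols, optimize=True).reshape(
            self.W.value.shape
        )
        if self.b is not None:
            self.b.grad += dyf.sum(axis=(0, 2))
        wmat = self.W.value.reshape(o, -1)
        dcols = np.einsum("ok,nol->nkl", wmat, dyf, optimize=True)
        dcols = dcols.reshape(n, c, self.k, self.k, oh, ow)
        s = self.stride
        dxp = np.zeros((n, c, h + p0 + p1, w + p2 + p3))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[:, :, i, j]
        return dxp[:, :, p0 : p0 + h, p2 : p2 + w]


class ReLU(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/cols are dropped.

    Gradient at ties is split evenly among the tied positions.
    """

    def forward(self, x, *, train=False, rng=None):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
        y = xc.max(axis=(3, 5))
        mask = (xc == y[:, :, :, None, :, None]).astype(np.float64)
        mask /= mask.sum(axis=(3, 5), keepdims=True)
        self._cache = (x.shape, mask)
        return y

    def backward(self, dy):
        (n, c, h, w), mask = self._cache
        h2, w2 = mask.shape[2], mask.shape[4]
        dxc = mask * dy[:, :, :, None, :, None]
        dx = np.zeros((n, c, h, w))
        dx[:, :, : 2 * h2, : 2 * w2] = dxc.reshape(n, c, 2 * h2, 2 * w2)
        return dx


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x, *, train=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Dense(Layer):
    def __init__(self, nin, nout, *, rng, bias=True):
        self.W = Param(he_normal(rng, (nout, nin), nin))
        self.b = Param(np.zeros(nout)) if bias else None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        y = x @ self.W.value.T
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dy):
        self.W.grad += dy.T @ self._x
        if self.b is not None:
            self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, p=0.2):
        self.p = float(p)

    def forward(self, x, *, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        out = []
        for lay in self.layers:
            out.extend(lay.params())
        return out

    def forward(self, x, *, train=False, rng=None):
        for lay in self.layers:
            x = lay.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


class Parallel(Layer):
    """Apply branches to the same input and concatenate along channels."""

    def __init__(self, *branches):
        self.branches = list(branches)

    def params(self):
        out = []
        for br in self.branches:
            out.extend(br.params())
        return out

    def forward(self, x, *, train=False, rng=None):
        ys = [br.forward(x, train=train, rng=rng) for br in self.branches]
        self._splits = [y.shape[1] for y in ys]
        return np.concatenate(ys, axis=1)

    def backward(self, dy):
        dx = None
        start = 0
        for br, width in zip(self.branches, self._splits):
            d = br.backward(dy[:, start : start + width])
            dx = d if dx is None else dx + d
            start += width
        return dx


class Residual(Layer):
    """y = x + scale * inner(x); the channel counts must match."""

    def __init__(self, inner: Layer, scale: float = 0.2):
        self.inner = inner
        self.scale = float(scale)

    def params(self):
        return self.inner.params()

    def forward(self, x, *, train=False, rng=None):
        return x + self.scale * self.inner.forward(x, train=train, rng=rng)

    def backward(self, dy):
        # Scale the gradient entering the branch so its parameter grads
        # carry the residual scaling too.
        return dy + self.inner.backward(self.scale * dy)
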