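"""Minimal convolutional network stack with explicit reverse-mode gradients.

Implements exactly the pieces the emulator needs — 2-D convolutions (via
im2col), instance normalization, ReLU family, global average pooling, a
dense head, and Adam — with hand-written backward passes over float64 numpy
arrays.  Tensors are laid out (N, C, H, W).

The implementation favours clarity and testability over generality: layers
cache what their backward pass needs, a gradient check against central
finite differences lives in the test suite, and all randomness flows through
an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def params(self) -> list:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, 'same'-style zero padding, optional stride."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, name: str = "conv"):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        w = rng.standard_normal((cout, fan_in)) * np.sqrt(2.0 / fan_in)
        self.W = Param(w, f"{name}.W")
        self.b = Param(np.zeros(cout), f"{name}.b")
        self.k, self.stride, self.pad = k, stride, k // 2
        self.cin, self.cout = cin, cout
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        n, c, h, w = x.shape
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        patches = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
        y = patches @ self.W.value.T + self.b.value
        self._cache = (patches, (n, c, h, w), (ho, wo))
        return y.transpose(0, 2, 1).reshape(n, self.cout, ho, wo)

    def backward(self, dy):
        patches, (n, c, h, w), (ho, wo) = self._cache
        p, k, s = self.pad, self.k, self.stride
        dyf = dy.reshape(n, self.cout, ho * wo).transpose(0, 2, 1)
        self.W.grad += dyf.reshape(-1, self.cout).T @ patches.reshape(-1, c * k * k)
        self.b.grad += dyf.sum(axis=(0, 1))
        dpatch = (dyf @ self.W.value).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + s * ho:s, dj:dj + s * wo:s] += \
                    dpatch[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w]


class InstanceNorm(Layer):
    """Per-sample, per-channel normalization over the spatial axes."""

    EPS = 1e-5

    def __init__(self, c: int, name: str = "inorm"):
        self.gamma = Param(np.ones(c), f"{name}.gamma")
        self.beta = Param(np.zeros(c), f"{name}.beta")
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.EPS)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat + \
            self.beta.value[None, :, None, None]

    def backward(self, dy):
        xhat, inv = self._cache
        m = xhat.shape[2] * xhat.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        s1 = dxhat.sum(axis=(2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(2, 3), keepdims=True)
        return (inv / m) * (m * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


class ResBlock(Layer):
    """conv - norm - act - conv - norm with identity skip."""

    def __init__(self, c: int, rng: np.random.Generator, name: str = "res"):
        self.body = Sequential(
            Conv2d(c, c, rng=rng, name=f"{name}.c1"),
            InstanceNorm(c, name=f"{name}.n1"),
            ReLU(),
            Conv2d(c, c, rng=rng, name=f"{name}.c2"),
            InstanceNorm(c, name=f"{name}.n2"),
        )

    def params(self):
        return self.body.params()

    def forward(self, x):
        return x + self.body.forward(x)

    def backward(self, dy):
        return dy + self.body.backward(dy)


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None,
                 name: str = "fc"):
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.standard_normal((cout, cin)) * np.sqrt(1.0 / cin),
                       f"{name}.W")
        self.b = Param(np.zeros(cout), f"{name}.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy):
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value


class Adam:
    """Adam with externally supplied per-step learning rate."""

    def __init__(self, params: list, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite-difference gradient of scalar f at x (test oracle)."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        old = x[idx]
        x[idx] = old + eps
        fp = f()
        x[idx] = old - eps
        fm = f()
        x[idx] = old
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
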