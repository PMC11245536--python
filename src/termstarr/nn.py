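"""Minimal 1-D convolutional network engine.

A compact numpy implementation of the layers needed for the densely connected
strength regressor: same-padded 1-D convolution, batch normalization, ReLU,
average pooling, channel concatenation (dense blocks), and a fully connected
head, with hand-derived backward passes and an Adam optimizer.  Everything is
deterministic given a seed and single-threaded execution.

Shapes follow the (batch, channels, length) convention.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: computation dtype; single precision keeps the conv matmuls in cache
DTYPE = np.float32


class Layer:
    def params(self):
        return []

    def buffers(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded 1-D convolution (odd kernels), valid for kernel 1."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("only odd kernel sizes are supported")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        self.pad = (kernel - 1) // 2
        fan_in = in_channels * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(out_channels, fan_in)).astype(DTYPE)
        self.b = np.zeros(out_channels, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def forward(self, x, train):
        n, c, L = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} channels, got {c}")
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad))) if self.pad else x
        win = sliding_window_view(xp, self.k, axis=2)  # (n, c, L, k)
        cols = np.ascontiguousarray(
            win.transpose(0, 2, 1, 3).reshape(n, L, c * self.k))
        self._cols = cols if train else None
        self._L = L
        y = cols.reshape(n * L, -1) @ self.W.T + self.b
        return np.ascontiguousarray(
            y.reshape(n, L, self.cout).transpose(0, 2, 1))

    def backward(self, grad):
        n, _, L = grad.shape
        g = np.ascontiguousarray(grad.transpose(0, 2, 1)).reshape(n * L, self.cout)
        cols = self._cols.reshape(n * L, -1)
        self.gW += g.T @ cols
        self.gb += g.sum(axis=0)
        gcols = (g @ self.W).reshape(n, L, self.cin, self.k).transpose(0, 2, 1, 3)
        Lp = L + 2 * self.pad
        gxp = np.zeros((n, self.cin, Lp), dtype=DTYPE)
        for j in range(self.k):
            gxp[:, :, j:j + L] += gcols[:, :, :, j]
        self._cols = None
        return gxp[:, :, self.pad:Lp - self.pad] if self.pad else gxp


class BatchNorm1d(Layer):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.ggamma = np.zeros(channels, dtype=DTYPE)
        self.gbeta = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2), dtype=np.float64).astype(DTYPE)
            var = x.var(axis=(0, 2), dtype=np.float64).astype(DTYPE)
            self.running_mean[...] = (self.momentum * self.running_mean
                                      + (1 - self.momentum) * mean)
            self.running_var[...] = (self.momentum * self.running_var
                                     + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * ivar[None, :, None]
        if train:
            self._xhat, self._ivar, self._nt = xhat, ivar, x.shape[0] * x.shape[2]
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, grad):
        xhat, ivar, nt = self._xhat, self._ivar, self._nt
        self.ggamma += (grad * xhat).sum(axis=(0, 2))
        self.gbeta += grad.sum(axis=(0, 2))
        gxhat = grad * self.gamma[None, :, None]
        term = (gxhat - gxhat.mean(axis=(0, 2), keepdims=True)
                - xhat * (gxhat * xhat).mean(axis=(0, 2), keepdims=True))
        self._xhat = None
        return term * ivar[None, :, None]


class ReLU(Layer):
    def forward(self, x, train):
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, grad):
        g = grad * self._mask
        self._mask = None
        return g


class AvgPool1d(Layer):
    def __init__(self, kernel: int = 2):
        self.k = kernel

    def forward(self, x, train):
        n, c, L = x.shape
        m = L // self.k
        if m < 1:
            raise ValueError("feature map shorter than pooling kernel")
        self._L = L
        return x[:, :, :m * self.k].reshape(n, c, m, self.k).mean(axis=3)

    def backward(self, grad):
        n, c, m = grad.shape
        g = np.repeat(grad, self.k, axis=2) / self.k
        if m * self.k < self._L:
            g = np.pad(g, ((0, 0), (0, 0), (0, self._L - m * self.k)))
        return g


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def buffers(self):
        return [b for l in self.layers for b in l.buffers()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class DenseBlock(Layer):
    """Densely connected block: each composite layer (BN -> ReLU -> Conv)
    produces ``growth`` channels appended to its input."""

    def __init__(self, in_channels: int, n_layers: int, growth: int, kernel: int,
                 rng: np.random.Generator):
        self.sublayers = []
        c = in_channels
        for _ in range(n_layers):
            self.sublayers.append(Sequential([
                BatchNorm1d(c), ReLU(), Conv1d(c, growth, kernel, rng)
            ]))
            c += growth
        self.out_channels = c
        self.growth = growth

    def params(self):
        return [p for l in self.sublayers for p in l.params()]

    def buffers(self):
        return [b for l in self.sublayers for b in l.buffers()]

    def forward(self, x, train):
        self._in_channels = []
        for l in self.sublayers:
            self._in_channels.append(x.shape[1])
            h = l.forward(x, train)
            x = np.concatenate([x, h], axis=1)
        return x

    def backward(self, grad):
        for l, cin in zip(reversed(self.sublayers), reversed(self._in_channels)):
            g_in, g_h = grad[:, :cin], grad[:, cin:]
            grad = g_in + l.backward(g_h)
        return grad


class GlobalAvgPool(Layer):
    """Mean over the length axis: (n, c, L) -> (n, c)."""

    def forward(self, x, train):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad):
        return np.repeat(grad[:, :, None], self._L, axis=2) / self._L


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(1.0 / d_in),
                            size=(d_out, d_in)).astype(DTYPE)
        self.b = np.zeros(d_out, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad):
        self.gW += grad.T @ self._x
        self.gb += grad.sum(axis=0)
        g = grad @ self.W
        self._x = None
        return g


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0


def get_weights(layer: Layer) -> list[np.ndarray]:
    """Snapshot of all parameters and buffers (batch-norm running stats)."""
    return [p.copy() for p, _ in layer.params()] + [b.copy() for b in layer.buffers()]


def set_weights(layer: Layer, weights) -> None:
    n = len(layer.params())
    for (p, _), w in zip(layer.params(), weights[:n]):
        p[...] = w
    for b, w in zip(layer.buffers(), weights[n:]):
        b[...] = w
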