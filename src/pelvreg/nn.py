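"""Minimal convolutional-network layers with hand-written backprop.

The registration regressor needs only a fixed, small layer vocabulary —
3 x 3 same-padded convolutions, batch normalization, ELU, 2 x 2 average
pooling — so each layer implements an explicit ``forward``/``backward``
pair on ``(B, C, H, W)`` float64 arrays, and ``Sequential`` chains them.
Convolutions are computed as nine shifted batched GEMMs, which keeps the
arithmetic inside BLAS.

``Adam`` implements the standard optimizer (beta1 = 0.9, beta2 = 0.999).
All parameter initialization is driven by an explicit Generator, so
training is deterministic under a seed.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class; layers expose params() / grads() as flat lists."""

    training = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv2d(Layer):
    """3 x 3 (or k x k) convolution, stride 1, zero 'same' padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int = 3,
                 rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        k = kernel_size
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.k = k
        if zero_init:
            self.W = np.zeros((out_ch, in_ch, k, k))
        else:
            rng = rng or np.random.default_rng(0)
            fan_in = in_ch * k * k
            self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                size=(out_ch, in_ch, k, k))
        self.b = np.zeros(out_ch)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._xpad = None

    def forward(self, x):
        B, C, H, W = x.shape
        p = self.k // 2
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xpad = xpad
        self._in_shape = x.shape
        out_ch = self.W.shape[0]
        out = np.broadcast_to(self.b[None, :, None, None],
                              (B, out_ch, H, W)).copy()
        out_flat = out.reshape(B, out_ch, H * W)
        for di in range(self.k):
            for dj in range(self.k):
                xs = xpad[:, :, di:di + H, dj:dj + W].reshape(B, C, H * W)
                out_flat += np.matmul(self.W[:, :, di, dj], xs)
        return out

    def backward(self, grad):
        B, C, H, W = self._in_shape
        p = self.k // 2
        out_ch = self.W.shape[0]
        g = grad.reshape(B, out_ch, H * W)
        self.gb += grad.sum(axis=(0, 2, 3))
        gxpad = np.zeros_like(self._xpad)
        for di in range(self.k):
            for dj in range(self.k):
                xs = self._xpad[:, :, di:di + H, dj:dj + W] \
                    .reshape(B, C, H * W)
                self.gW[:, :, di, dj] += np.matmul(
                    g, xs.transpose(0, 2, 1)).sum(axis=0)
                gxpad[:, :, di:di + H, dj:dj + W] += np.matmul(
                    self.W[:, :, di, dj].T, g).reshape(B, C, H, W)
        self._xpad = None
        return gxpad[:, :, p:p + H, p:p + W]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics.

    ``momentum`` follows the convention ``running = m * running +
    (1 - m) * batch`` (the paper-style momentum of 0.9).  Evaluation mode
    uses the running statistics, making inference deterministic.
    """

    def __init__(self, n_ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_ch)
        self.beta = np.zeros(n_ch)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean \
                + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var \
                + (1 - self.momentum) * var
        else:
            mean = self.running_mean
            var = self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) \
            / self._std[None, :, None, None]
        return self.gamma[None, :, None, None] * self._xhat \
            + self.beta[None, :, None, None]

    def backward(self, grad):
        xhat = self._xhat
        self.ggamma += (grad * xhat).sum(axis=(0, 2, 3))
        self.gbeta += grad.sum(axis=(0, 2, 3))
        gx = grad * self.gamma[None, :, None, None] \
            / self._std[None, :, None, None]
        if self.training:
            n = grad.shape[0] * grad.shape[2] * grad.shape[3]
            gsum = gx.sum(axis=(0, 2, 3), keepdims=True)
            gxhat = (gx * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = gx - gsum / n - xhat * gxhat / n
        self._xhat = None
        return gx

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.ggamma, self.gbeta]


class ELU(Layer):
    """Exponential linear unit, alpha = 1."""

    def forward(self, x):
        self._neg_exp = np.where(x < 0, np.exp(np.minimum(x, 0.0)), 1.0)
        return np.where(x >= 0, x, self._neg_exp - 1.0)

    def backward(self, grad):
        g = grad * self._neg_exp
        self._neg_exp = None
        return g


class AvgPool2d(Layer):
    """2 x 2 average pooling, stride 2 (even spatial dims required)."""

    def forward(self, x):
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"AvgPool2d needs even dims, got {(H, W)}")
        self._in_shape = x.shape
        return x.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(self, grad):
        B, C, H, W = self._in_shape
        g = np.repeat(np.repeat(grad, 2, axis=2), 2, axis=3) / 4.0
        return g


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    @property
    def training(self):
        return all(getattr(l, "training", True) for l in self.layers)

    def train(self, mode: bool = True):
        for layer in self.layers:
            layer.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for g in self.grads():
            g[...] = 0.0

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params()))


class Adam:
    """Standard Adam optimizer over a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
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
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
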