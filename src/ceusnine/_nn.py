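"""Minimal CPU neural-network primitives (conv/pool/dense, Adam).

Just enough machinery for the desk-scale CNN backbones: explicit
forward/backward passes on float64 numpy arrays, 3x3 same-padding
convolutions via im2col, and an Adam optimizer.  No autograd, no GPU.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 convolution, stride 1, same padding, on (N, C, H, W) input.

    Implemented as nine shifted tensor contractions, which keeps the large
    intermediate gathers of a classic im2col off the hot path.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        fan_in = c_in * 9
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  size=(c_out, c_in, 3, 3)).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self.c_in, self.c_out = c_in, c_out

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        out = np.zeros((self.c_out, n, h, w), dtype=self.w.value.dtype)
        for di in range(3):
            for dj in range(3):
                out += np.tensordot(self.w.value[:, :, di, dj],
                                    xp[:, :, di:di + h, dj:dj + w], axes=([1], [1]))
        out += self.b.value[:, None, None, None]
        self._cache = (xp, (n, c, h, w))
        return np.ascontiguousarray(out.transpose(1, 0, 2, 3))

    def backward(self, grad):
        xp, (n, c, h, w) = self._cache
        dxp = np.zeros_like(xp)
        for di in range(3):
            for dj in range(3):
                window = xp[:, :, di:di + h, dj:dj + w]
                self.w.grad[:, :, di, dj] += np.tensordot(
                    grad, window, axes=([0, 2, 3], [0, 2, 3]))
                dxp[:, :, di:di + h, dj:dj + w] += np.tensordot(
                    self.w.value[:, :, di, dj], grad, axes=([0], [1])
                ).transpose(1, 0, 2, 3)
        self.b.grad += grad.sum(axis=(0, 2, 3))
        return dxp[:, :, 1:h + 1, 1:w + 1]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2(Layer):
    """2x2 max pooling; an odd trailing row/column is dropped."""

    def forward(self, x):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, :2 * h2, :2 * w2]
        windows = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h2, w2, 4)
        self._idx = windows.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(windows, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, c, h, w = self._shape
        h2, w2 = h // 2, w // 2
        dwin = np.zeros((n, c, h2, w2, 4), dtype=grad.dtype)
        np.put_along_axis(dwin, self._idx[..., None], grad[..., None], axis=-1)
        dx = np.zeros((n, c, h, w), dtype=grad.dtype)
        dx[:, :, :2 * h2, :2 * w2] = dwin.reshape(n, c, h2, w2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(n, c, 2 * h2, 2 * w2)
        return dx


class AvgPool2(Layer):
    """2x2 mean pooling; an odd trailing row/column is dropped."""

    def forward(self, x):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        self._shape = (n, c, h, w)
        xc = x[:, :, :2 * h2, :2 * w2]
        return xc.reshape(n, c, h2, 2, w2, 2).mean(axis=(3, 5))

    def backward(self, grad):
        n, c, h, w = self._shape
        h2, w2 = h // 2, w // 2
        dx = np.zeros((n, c, h, w), dtype=grad.dtype)
        dx[:, :, :2 * h2, :2 * w2] = np.repeat(
            np.repeat(grad, 2, axis=2), 2, axis=3) / 4.0
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], (n, c, h, w)) / (h * w)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / n_in),
                                  size=(n_in, n_out)).astype(dtype))
        self.b = Param(np.zeros(n_out, dtype=dtype))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    loss = -np.log(np.maximum(probs[np.arange(n), y], 1e-300)).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
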