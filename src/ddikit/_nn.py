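"""Minimal NumPy neural-network kernel: layers, manual backprop, AdamW.

Everything is deliberately small and deterministic: layers cache what their
backward pass needs, parameters are plain arrays, and all randomness
(initialization, dropout) flows from explicit ``numpy.random.Generator``
objects so training runs are bit-reproducible under a seed.

Shapes: sequence tensors are (batch, length, channels); dense tensors are
(batch, features).
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Embedding(Layer):
    """Token-id lookup table: (B, L) int -> (B, L, D)."""

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        self.W = Param(rng.normal(0.0, 0.1, size=(vocab_size, dim)))

    def params(self):
        return [self.W]

    def forward(self, x, train):
        self._ids = x
        return self.W.value[x]

    def backward(self, dout):
        np.add.at(self.W.grad, self._ids, dout)
        return None  # token ids take no gradient


class Conv1d(Layer):
    """Same-padded 1D convolution over the length axis via im2col."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError("kernel must be odd and >= 1")
        self.kernel = kernel
        self.in_ch = in_ch
        fan_in = in_ch * kernel
        self.W = Param(rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(fan_in, out_ch)))
        self.b = Param(np.zeros(out_ch))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        B, L, C = x.shape
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        # (B, L, kernel, C) windows over the padded length axis
        cols = sliding_window_view(xp, self.kernel, axis=1).transpose(0, 1, 3, 2)
        self._cols = cols.reshape(B * L, self.kernel * C)
        self._shape = (B, L, C)
        out = self._cols @ self.W.value + self.b.value
        return out.reshape(B, L, -1)

    def backward(self, dout):
        B, L, C = self._shape
        d2 = dout.reshape(B * L, -1)
        self.W.grad += self._cols.T @ d2
        self.b.grad += d2.sum(axis=0)
        dcols = (d2 @ self.W.value.T).reshape(B, L, self.kernel, C)
        p = self.kernel // 2
        dxp = np.zeros((B, L + 2 * p, C))
        for k in range(self.kernel):
            dxp[:, k : k + L, :] += dcols[:, :, k, :]
        return dxp[:, p : p + L, :]


class BatchNorm(Layer):
    """Batch normalization over all leading axes, per channel."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        flat = x.reshape(-1, x.shape[-1])
        if train:
            mu = flat.mean(axis=0)
            var = flat.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (flat - mu) * self._inv_std
        self._shape = x.shape
        self._train = train
        out = self.gamma.value * self._xhat + self.beta.value
        return out.reshape(x.shape)

    def backward(self, dout):
        d = dout.reshape(-1, dout.shape[-1])
        self.gamma.grad += (d * self._xhat).sum(axis=0)
        self.beta.grad += d.sum(axis=0)
        if self._train:
            n = d.shape[0]
            dx = (self.gamma.value * self._inv_std / n) * (
                n * d - d.sum(axis=0) - self._xhat * (d * self._xhat).sum(axis=0)
            )
        else:
            dx = d * self.gamma.value * self._inv_std
        return dx.reshape(self._shape)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class GlobalMaxPool(Layer):
    """(B, L, C) -> (B, C), max over the length axis."""

    def forward(self, x, train):
        self._arg = x.argmax(axis=1)
        self._shape = x.shape
        return np.take_along_axis(x, self._arg[:, None, :], axis=1)[:, 0, :]

    def backward(self, dout):
        dx = np.zeros(self._shape)
        np.put_along_axis(dx, self._arg[:, None, :], dout[:, None, :], axis=1)
        return dx


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def zero_grads(params: list[Param]) -> None:
    for p in params:
        p.grad[...] = 0.0


def get_state(params: list[Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def set_state(params: list[Param], state: list[np.ndarray]) -> None:
    for p, v in zip(params, state, strict=True):
        p.value[...] = v


class AdamW:
    """Adam with decoupled weight decay; learning rate supplied per step."""

    def __init__(
        self,
        params: list[Param],
        weight_decay: float = 1e-6,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.wd = weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            p.value -= lr * ((m / bc1) / (np.sqrt(v / bc2) + self.eps) + self.wd * p.value)


def cosine_annealed_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    """Cosine annealing from ``base_lr`` down to 0 over ``total_epochs``."""
    if total_epochs <= 1:
        return base_lr
    return 0.5 * base_lr * (1.0 + math.cos(math.pi * epoch / (total_epochs - 1)))
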