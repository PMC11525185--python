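"""A small reverse-mode neural-network engine on numpy.

Provides exactly the layers the activity model needs (1-D convolution,
batch normalization, max pooling, linear maps, ReLU, dropout, branched
output heads) with explicit ``forward``/``backward`` passes.  ``backward``
returns the gradient with respect to the layer input, so gradients flow all
the way back to the one-hot sequence — which is what gradient-based
sequence design and integrated-gradients attribution require.

Arrays are float32 throughout; convolution is im2col + matrix products.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    train_mode = False

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """Valid-mode cross-correlation over (N, C, L) inputs."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        std = math.sqrt(2.0 / (c_in * kernel))
        self.w = Param(rng.normal(0.0, std, (c_out, c_in, kernel)))
        self.b = Param(np.zeros(c_out))
        self.kernel = kernel

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x_shape = x.shape
        n, c, l = x.shape
        k = self.kernel
        l_out = l - k + 1
        windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)
        # im2col: (N*Lout, C*K) so both passes are single GEMMs
        col = np.ascontiguousarray(windows.transpose(0, 2, 1, 3)).reshape(n * l_out, c * k)
        self._col = col
        w2 = self.w.value.reshape(self.w.value.shape[0], c * k)
        out = (col @ w2.T).reshape(n, l_out, -1).transpose(0, 2, 1)
        out = out + self.b.value[None, :, None]
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, dout):
        n, c, l = self._x_shape
        k = self.kernel
        c_out, l_out = dout.shape[1], dout.shape[2]
        dout_r = np.ascontiguousarray(dout.transpose(0, 2, 1)).reshape(n * l_out, c_out)
        self.w.grad += (dout_r.T @ self._col).reshape(c_out, c, k)
        self.b.grad += dout.sum(axis=(0, 2))
        dcol = (dout_r @ self.w.value.reshape(c_out, c * k)).reshape(n, l_out, c, k)
        dx = np.zeros(self._x_shape, dtype=np.float32)
        for t in range(k):  # col2im scatter-add
            dx[:, :, t:t + l_out] += dcol[:, :, :, t].transpose(0, 2, 1)
        return dx


class BatchNorm1d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        self.train_mode = train
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        self._invstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        self._xhat = (x - mean[None, :, None]) * self._invstd[None, :, None]
        return (self.gamma.value[None, :, None] * self._xhat
                + self.beta.value[None, :, None]).astype(np.float32, copy=False)

    def backward(self, dout):
        xhat = self._xhat
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2))
        self.beta.grad += dout.sum(axis=(0, 2))
        scale = (self.gamma.value * self._invstd)[None, :, None]
        if not self.train_mode:
            return (dout * scale).astype(np.float32, copy=False)
        dmean = dout.mean(axis=(0, 2))[None, :, None]
        dproj = (dout * xhat).mean(axis=(0, 2))[None, :, None]
        return (scale * (dout - dmean - xhat * dproj)).astype(np.float32, copy=False)


class MaxPool1d(Layer):
    """Non-overlapping max pooling; trailing remainder positions dropped."""

    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x, train=False):
        n, c, l = x.shape
        lp = l // self.pool
        self._in_shape = x.shape
        xr = x[:, :, :lp * self.pool].reshape(n, c, lp, self.pool)
        self._xr = xr
        out = xr.max(axis=3)
        self._out = out
        return out

    def backward(self, dout):
        n, c, l = self._in_shape
        lp = dout.shape[2]
        # route gradient to the first maximal element of each pool window
        mask = self._xr == self._out[..., None]
        first = mask.cumsum(axis=3) == 1
        dxr = (mask & first) * dout[..., None]
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[:, :, :lp * self.pool] = dxr.reshape(n, c, lp * self.pool)
        return dx


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(Layer):
    """Leaky rectifier; the small negative slope keeps gradient flowing
    through narrow layers that plain ReLU can leave permanently dead."""

    def __init__(self, alpha: float = 0.1):
        self.alpha = alpha

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        std = math.sqrt(2.0 / d_in)
        self.w = Param(rng.normal(0.0, std, (d_in, d_out)))
        self.b = Param(np.zeros(d_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(np.float32, copy=False)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return (dout * self._mask).astype(np.float32, copy=False)


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class BranchedHeads(Layer):
    """Independent per-output branches applied to a shared hidden state;
    outputs concatenated into (N, n_branches)."""

    def __init__(self, branches: Sequence[Sequential]):
        self.branches = list(branches)

    def params(self):
        return [p for b in self.branches for p in b.params()]

    def forward(self, x, train=False):
        outs = [b.forward(x, train=train) for b in self.branches]
        return np.concatenate(outs, axis=1)

    def backward(self, dout):
        dx = None
        for i, b in enumerate(self.branches):
            g = b.backward(np.ascontiguousarray(dout[:, i:i + 1]))
            dx = g if dx is None else dx + g
        return dx


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad ** 2
            p.value -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def cosine_lr(step: int, total: int, lr_max: float, lr_min: float,
              flat_frac: float = 0.0) -> float:
    """Cosine-annealed learning rate from lr_max down to lr_min, optionally
    holding lr_max flat for the first ``flat_frac`` of the steps."""
    hold = int(total * flat_frac)
    if step < hold:
        return lr_max
    step, total = step - hold, total - hold
    if total <= 1:
        return lr_min
    frac = min(step, total - 1) / (total - 1)
    return lr_min + 0.5 * (lr_max - lr_min) * (1 + math.cos(math.pi * frac))


def get_state(net: Layer) -> list[np.ndarray]:
    return [p.value.copy() for p in net.params()]


def set_state(net: Layer, state: list[np.ndarray]) -> None:
    for p, s in zip(net.params(), state):
        p.value[...] = s


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray, axis: int = -1) -> np.ndarray:
    """Jacobian-vector product of softmax at ``probs``."""
    inner = (dprobs * probs).sum(axis=axis, keepdims=True)
    return probs * (dprobs - inner)
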