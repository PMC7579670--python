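"""Minimal CPU neural-network engine (numpy, float32).

Only what the package needs: dense / 2-D convolution / ReLU / dropout /
flatten / global-average-pool / softmax layers, a ``Sequential`` container
with explicit backward passes, and Adam / RAdam optimizers with an optional
reduce-on-plateau learning-rate schedule.  Everything is deterministic given
the ``numpy.random.Generator`` supplied at construction / training time.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Scale",
    "Dense",
    "Conv2D",
    "ReLU",
    "Dropout",
    "Flatten",
    "GlobalAvgPool",
    "Softmax",
    "Sequential",
    "Adam",
    "RAdam",
    "ReduceLROnPlateau",
]

_F = np.float32


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=_F)
        self.grad = np.zeros_like(self.value)


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Scale(Layer):
    """Multiply inputs by a constant (e.g. 1/255 pixel scaling)."""

    def __init__(self, factor: float):
        self.factor = _F(factor)

    def forward(self, x, train):
        return x.astype(_F) * self.factor

    def backward(self, grad):
        return grad * self.factor


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def forward(self, x, train):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T

    def params(self):
        return [self.w, self.b]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(B,H,W,C) -> (B*OH*OW, k*k*C) patch matrix plus output spatial dims."""
    b, h, w, c = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(b, oh, ow, k, k, c),
        strides=(s0, s1 * stride, s2 * stride, s1, s2, s3),
        writeable=False,
    )
    return np.ascontiguousarray(windows).reshape(b * oh * ow, k * k * c), oh, ow


class Conv2D(Layer):
    """3-D input (H, W, C) convolution, NHWC layout, stride >= 1, zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0):
        self.k, self.stride, self.pad = kernel, stride, padding
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / (kernel * kernel * c_in))
        self.w = Param(rng.normal(0.0, scale, size=(kernel * kernel * c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x, train):
        x = x.astype(_F, copy=False)
        self._in_shape = x.shape
        cols, oh, ow = _im2col(x, self.k, self.stride, self.pad)
        self._cols = cols
        out = cols @ self.w.value + self.b.value
        return out.reshape(x.shape[0], oh, ow, self.c_out)

    def backward(self, grad):
        b, oh, ow, _ = grad.shape
        g2 = grad.reshape(b * oh * ow, self.c_out)
        self.w.grad += self._cols.T @ g2
        self.b.grad += g2.sum(axis=0)
        gcols = g2 @ self.w.value.T  # (B*OH*OW, k*k*C)
        # scatter columns back to the (padded) input
        _, h, w, c = self._in_shape
        hp, wp = h + 2 * self.pad, w + 2 * self.pad
        gx = np.zeros((b, hp, wp, c), dtype=_F)
        gcols = gcols.reshape(b, oh, ow, self.k, self.k, c)
        for ki in range(self.k):
            for kj in range(self.k):
                gx[:, ki:ki + oh * self.stride:self.stride,
                   kj:kj + ow * self.stride:self.stride, :] += gcols[:, :, :, ki, kj, :]
        if self.pad:
            gx = gx[:, self.pad:-self.pad, self.pad:-self.pad, :]
        return gx

    def params(self):
        return [self.w, self.b]

    @property
    def n_params(self) -> int:
        return self.w.value.size + self.b.value.size


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, _F(0.0))

    def backward(self, grad):
        return np.where(self._mask, grad, _F(0.0))


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            return x
        keep = _F(1.0 - self.rate)
        self._mask = (self.rng.random(x.shape) >= self.rate).astype(_F) / keep
        return x * self._mask

    def backward(self, grad):
        if self.rate == 0.0:
            return grad
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class GlobalAvgPool(Layer):
    """(B,H,W,C) -> (B,C) spatial mean."""

    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        b, h, w, c = self._shape
        g = np.broadcast_to(grad[:, None, None, :] / _F(h * w), self._shape)
        return np.ascontiguousarray(g)


class Softmax(Layer):
    def forward(self, x, train):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=-1, keepdims=True)
        return self._p

    def backward(self, grad):
        p = self._p
        return p * (grad - (grad * p).sum(axis=-1, keepdims=True))


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    @property
    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    # plain-array (de)serialization; callers own the container format
    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.value.shape} vs {w.shape}")
            p.value[...] = w


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RAdam(Adam):
    """Rectified Adam: warms up the adaptive term via the variance rectifier."""

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        rho_inf = 2.0 / (1.0 - b2) - 1.0
        b2t = b2 ** self.t
        rho = rho_inf - 2.0 * self.t * b2t / (1.0 - b2t)
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            if rho > 4.0:
                r = np.sqrt(((rho - 4) * (rho - 2) * rho_inf)
                            / ((rho_inf - 4) * (rho_inf - 2) * rho))
                vhat = np.sqrt(v / (1 - b2t)) + self.eps
                p.value -= self.lr * r * mhat / vhat
            else:
                p.value -= self.lr * mhat


class ReduceLROnPlateau:
    """Halve the optimizer learning rate when the monitored loss stalls."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 3,
                 min_lr: float = 1e-6, min_delta: float = 1e-4):
        self.opt = optimizer
        self.factor, self.patience = factor, patience
        self.min_lr, self.min_delta = min_lr, min_delta
        self.best = np.inf
        self.wait = 0

    def step(self, loss: float) -> None:
        if loss < self.best - self.min_delta:
            self.best = loss
            self.wait = 0
            return
        self.wait += 1
        if self.wait >= self.patience:
            self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
            self.wait = 0
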