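"""Minimal self-contained neural-network kernels (numpy, NHWC, float32).

Implements exactly the pieces the Max-Feature-Map classifier needs —
same-padded stride-1 convolution, MFM, batch normalization, 2x2 max
pooling, global average pooling, dropout, dense layers, softmax
cross-entropy and Adam — with hand-derived gradients.  Convolution forward
and backward reduce to one BLAS matrix product per kernel offset, so
training speed is set by BLAS.
"""
from __future__ import annotations

import numpy as np

from .errors import ConfigurationError


class Layer:
    """Base layer; parameters and gradients are parallel lists of arrays."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padded stride-1 convolution; weights (k, k, in, out), He init.

    Implemented as a sum over the k*k kernel offsets of one BLAS matrix
    product per offset (shifted-view strategy), which avoids the large
    strided im2col gather in both directions.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.pad = k // 2
        fan_in = k * k * in_ch
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, in_ch, out_ch))
        self.params = [w.astype(np.float32), np.zeros(out_ch, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training):
        n, h, w, _ = x.shape
        self._shape = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        W = self.params[0]
        out = np.broadcast_to(self.params[1], (n * h * w, self.out_ch)).copy()
        self._slices = []
        for di in range(self.k):
            for dj in range(self.k):
                xs = np.ascontiguousarray(
                    xp[:, di:di + h, dj:dj + w, :]
                ).reshape(n * h * w, self.in_ch)
                self._slices.append(xs)
                out += xs @ W[di, dj]
        return out.reshape(n, h, w, self.out_ch)

    def backward(self, g):
        n, h, w, _ = self._shape
        p = self.pad
        g2 = np.ascontiguousarray(g).reshape(n * h * w, self.out_ch)
        W = self.params[0]
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.in_ch), dtype=g.dtype)
        for di in range(self.k):
            for dj in range(self.k):
                xs = self._slices[di * self.k + dj]
                self.grads[0][di, dj] = xs.T @ g2
                dxp[:, di:di + h, dj:dj + w, :] += (g2 @ W[di, dj].T).reshape(
                    n, h, w, self.in_ch
                )
        self.grads[1][...] = g2.sum(axis=0)
        return dxp[:, p:p + h, p:p + w, :]


class MFM(Layer):
    """Max-Feature-Map: elementwise max of the two channel halves."""

    def forward(self, x, training):
        c2 = x.shape[-1]
        if c2 % 2:
            raise ConfigurationError(f"MFM needs an even channel count, got {c2}")
        c = c2 // 2
        a, b = x[..., :c], x[..., c:]
        self._mask = a >= b
        return np.where(self._mask, a, b)

    def backward(self, g):
        return np.concatenate(
            [np.where(self._mask, g, 0.0), np.where(self._mask, 0.0, g)], axis=-1
        )


class BatchNorm(Layer):
    """Per-channel batch normalization (over all but the last axis)."""

    def __init__(self, n_ch: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = [np.ones(n_ch, dtype=np.float32), np.zeros(n_ch, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        self._m = int(np.prod([x.shape[a] for a in axes]))
        return self.params[0] * self._xhat + self.params[1]

    def backward(self, g):
        axes = tuple(range(g.ndim - 1))
        self.grads[0][...] = (g * self._xhat).sum(axis=axes)
        self.grads[1][...] = g.sum(axis=axes)
        gx = self.params[0] * g
        m = self._m
        return self._inv_std * (
            gx
            - gx.mean(axis=axes)
            - self._xhat * (gx * self._xhat).sum(axis=axes) / m
        )


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (spatial dims must be even)."""

    def forward(self, x, training):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ConfigurationError(f"max-pool needs even spatial dims, got {h}x{w}")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xr = np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, 4, c)
        self._idx = xr.argmax(axis=3)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, g):
        n, h, w, c = self._shape
        out = np.zeros((n, h // 2, w // 2, 4, c), dtype=g.dtype)
        np.put_along_axis(out, self._idx[:, :, :, None, :], g[:, :, :, None, :], axis=3)
        out = out.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return out.reshape(n, h, w, c)


class GlobalAvgPool(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, g):
        n, h, w, c = self._shape
        return np.broadcast_to(g[:, None, None, :] / (h * w), self._shape).copy()


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Dense(Layer):
    """Affine layer; ``init_scale`` < 1 damps the output layer so an
    untrained classifier starts near the uniform prediction."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init_scale: float = 1.0):
        super().__init__()
        w = init_scale * rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params = [w.astype(np.float32), np.zeros(n_out, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.params[0].T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for p in self.params]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                state += [layer.running_mean.copy(), layer.running_var.copy()]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        n = len(self.params)
        for p, s in zip(self.params, state[:n]):
            p[...] = s
        it = iter(state[n:])
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean = next(it).copy()
                layer.running_var = next(it).copy()


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_with_grad(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = len(labels)
    loss = -float(np.mean(np.log(p[np.arange(n), labels] + 1e-12)))
    g = p
    g[np.arange(n), labels] -= 1.0
    return loss, (g / n).astype(np.float32)


class Adam:
    """Adaptive-moment optimizer over a parameter/gradient list pair."""

    def __init__(self, params, grads, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
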