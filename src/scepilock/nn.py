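"""Minimal NumPy neural-network engine for 1-D sequence models.

Implements exactly the pieces the accessibility classifier needs: valid
(cross-correlation) 1-D convolution via im2col + BLAS matmul, ReLU,
non-overlapping max pooling with floor division, inverted dropout, dense
layers, a numerically stable binary cross-entropy on logits, and Adam.
Every layer exposes an explicit backward pass, which is also what powers the
Grad-CAM gradients. float32 throughout.

Shapes: convolutional activations are (batch, channels, length); dense
activations are (batch, features).

`forward` takes two independent switches: `train` turns stochastic
regularization (dropout) on, `cache` stores whatever `backward` needs.
Training uses both; gradient-only passes (saliency) cache without training
noise.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

DTYPE = np.float32


def _uniform_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """U(-1/sqrt(fan_in), +1/sqrt(fan_in)) — the classic uniform fan-in scheme."""
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Layer:
    """Base layer: stateless unless it has parameters."""

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None,
                cache: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}


class Conv1D(Layer):
    """Valid-mode 1-D convolution (cross-correlation), stride 1."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        self.in_channels, self.out_channels, self.kernel = in_channels, out_channels, kernel
        fan_in = in_channels * kernel
        self.W = _uniform_init(rng, (out_channels, in_channels, kernel), fan_in)
        self.b = _uniform_init(rng, (out_channels,), fan_in)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None

    def out_length(self, length: int) -> int:
        return length - (self.kernel - 1)

    def forward(self, x, train=False, rng=None, cache=False):
        # cols: (N, Cin, Lout, k) strided view over the input
        cols = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=2)
        self._cols = cols if cache else None
        self._in_shape = x.shape
        y = np.tensordot(cols, self.W, axes=([1, 3], [1, 2]))  # (N, Lout, Cout)
        y += self.b
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, dy):
        cols = self._cols
        if cols is None:
            raise RuntimeError("backward called without a cached forward pass")
        self.dW = np.tensordot(dy, cols, axes=([0, 2], [0, 2]))  # (Cout, Cin, k)
        self.db = dy.sum(axis=(0, 2))
        lout = dy.shape[2]
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        for t in range(self.kernel):
            # dy (N, Cout, Lout) x W[:, :, t] (Cout, Cin) -> (N, Lout, Cin)
            contrib = np.tensordot(dy, self.W[:, :, t], axes=([1], [0]))
            dx[:, :, t : t + lout] += contrib.transpose(0, 2, 1)
        self._cols = None
        return dx

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class ReLU(Layer):
    def forward(self, x, train=False, rng=None, cache=False):
        mask = x > 0
        self._mask = mask if cache else None
        return np.where(mask, x, 0).astype(DTYPE, copy=False)

    def backward(self, dy):
        return np.where(self._mask, dy, 0).astype(DTYPE, copy=False)


class MaxPool1D(Layer):
    """Non-overlapping max pooling; trailing remainder positions are dropped
    (floor division of the spatial length)."""

    def __init__(self, width: int):
        self.width = width

    def out_length(self, length: int) -> int:
        return length // self.width

    def forward(self, x, train=False, rng=None, cache=False):
        n, c, length = x.shape
        lout = length // self.width
        xt = x[:, :, : lout * self.width].reshape(n, c, lout, self.width)
        if cache:
            self._argmax = xt.argmax(axis=3)
            self._in_length = length
        return xt.max(axis=3)

    def backward(self, dy):
        n, c, lout = dy.shape
        dx = np.zeros((n, c, self._in_length), dtype=DTYPE)
        dxt = dx[:, :, : lout * self.width].reshape(n, c, lout, self.width)
        np.put_along_axis(dxt, self._argmax[..., None], dy[..., None], axis=3)
        return dx


class Dropout(Layer):
    """Inverted dropout: active only in training mode, identity otherwise."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask = None

    def forward(self, x, train=False, rng=None, cache=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(DTYPE) / DTYPE(keep)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None, cache=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _uniform_init(rng, (n_out, n_in), n_in)
        self.b = _uniform_init(rng, (n_out,), n_in)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x, train=False, rng=None, cache=False):
        self._x = x if cache else None
        return x @ self.W.T + self.b

    def backward(self, dy):
        if self._x is None:
            raise RuntimeError("backward called without a cached forward pass")
        self.dW = dy.T @ self._x
        self.db = dy.sum(axis=0)
        dx = dy @ self.W
        self._x = None
        return dx

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False, rng=None, cache=False):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng, cache=cache)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def named_param_layers(self) -> Iterator[tuple[str, Layer]]:
        for i, layer in enumerate(self.layers):
            if layer.params():
                yield f"layer{i}", layer


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy over batch x classes, with d(loss)/d(logits).

    Stable form: loss = max(z, 0) - z*y + log(1 + exp(-|z|)).
    """
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    p = sigmoid(z)
    dz = ((p - y) / z.size).astype(DTYPE)
    return float(loss.mean()), dz


class Adam:
    """Adaptive moment estimation over a flat dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
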