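"""Minimal numpy neural-network layers with hand-written backpropagation.

Exactly the pieces the three classifiers need: a valid-mode 3D convolution,
batch normalization, ReLU, optional 2x max pooling, dense layers, softmax
cross-entropy and Adam. Layout conventions: images are (B, D, H, W, C)
channels-last; vectors are (B, F).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv3D",
    "BatchNorm",
    "ReLU",
    "MaxPool3D",
    "Flatten",
    "Dense",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


class Layer:
    """Base layer: parameters exposed as (name, array) for the optimizer."""

    def params(self) -> list[tuple[str, np.ndarray]]:
        return []

    def grads(self) -> list[tuple[str, np.ndarray]]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(int(p.size) for _, p in self.params())


class Conv3D(Layer):
    """Valid 3D convolution, stride 1, isotropic cubic kernel.

    Parameter count is ``out_ch * (k^3 * in_ch) + out_ch`` (weights+biases);
    with 1 input channel and 16 5x5x5 filters that is 2016.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = kernel**3 * in_ch
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_ch))
        self.b = np.zeros(out_ch)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols = None

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def grads(self):
        return [("w", self.dw), ("b", self.db)]

    def out_shape(self, in_shape: tuple[int, int, int]) -> tuple[int, int, int]:
        k = self.kernel
        out = tuple(s - k + 1 for s in in_shape)
        if any(s < 1 for s in out):
            raise ValueError(f"image shape {in_shape} too small for kernel {k}")
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, d, h, w, c = x.shape
        k = self.kernel
        win = sliding_window_view(x, (k, k, k), axis=(1, 2, 3))  # (B,D',H',W',C,k,k,k)
        od, oh, ow = win.shape[1:4]
        cols = win.transpose(0, 1, 2, 3, 5, 6, 7, 4).reshape(b * od * oh * ow, k**3 * c)
        out = cols @ self.w + self.b
        if train:
            self._cols = cols
        self._out_spatial = (b, od, oh, ow)
        return out.reshape(b, od, oh, ow, self.out_ch)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        flat = dout.reshape(-1, self.out_ch)
        self.dw[...] = self._cols.T @ flat
        self.db[...] = flat.sum(axis=0)
        return None  # first layer: no input gradient needed


class BatchNorm(Layer):
    """Per-channel batch normalization over batch and spatial axes."""

    def __init__(self, n_ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_ch)
        self.beta = np.zeros(n_ch)
        self.dgamma = np.zeros(n_ch)
        self.dbeta = np.zeros(n_ch)
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def grads(self):
        return [("gamma", self.dgamma), ("beta", self.dbeta)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._axes = axes
        self._m = x.size // x.shape[-1]
        return self.gamma * self._xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = self._axes
        self.dgamma[...] = (dout * self._xhat).sum(axis=axes)
        self.dbeta[...] = dout.sum(axis=axes)
        m = self._m
        dxhat = dout * self.gamma
        return (
            dxhat - dxhat.mean(axis=axes) - self._xhat * (dxhat * self._xhat).mean(axis=axes)
        ) / self._std


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool3D(Layer):
    """Non-overlapping 2x2x2 max pooling (trailing odd voxels cropped)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, d, h, w, c = x.shape
        dd, hh, ww = d // 2, h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, : dd * 2, : hh * 2, : ww * 2, :]
        r = xc.reshape(b, dd, 2, hh, 2, ww, 2, c)
        out = r.max(axis=(2, 4, 6))
        self._argmask = r == out[:, :, None, :, None, :, None, :]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, d, h, w, c = self._in_shape
        dd, hh, ww = d // 2, h // 2, w // 2
        expanded = self._argmask * dout[:, :, None, :, None, :, None, :]
        dx = np.zeros(self._in_shape)
        dx[:, : dd * 2, : hh * 2, : ww * 2, :] = expanded.reshape(b, dd * 2, hh * 2, ww * 2, c)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def grads(self):
        return [("w", self.dw), ("b", self.db)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.w.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and the gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean())
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Adam:
    """Standard Adam over the (layer, param) pairs of a network."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for li, layer in enumerate(layers):
            for name, p in layer.params():
                self.m[(li, name)] = np.zeros_like(p)
                self.v[(li, name)] = np.zeros_like(p)

    def step(self) -> None:
        self.t += 1
        for li, layer in enumerate(self.layers):
            grads = dict(layer.grads())
            for name, p in layer.params():
                g = grads[name]
                key = (li, name)
                self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
                self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
                mhat = self.m[key] / (1 - self.b1**self.t)
                vhat = self.v[key] / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
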