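"""Minimal NumPy neural-network layer library with hand-written backprop.

Implements exactly the pieces the parallel-path gesture classifiers need:
1-D and 2-D convolutions (including depthwise), batch normalization, max and
average pooling, dense layers, ReLU/ReLU6, softmax cross-entropy, and Adam
with early stopping.  Layers are functional: ``forward`` returns an output
plus an opaque cache and ``backward`` consumes that cache, so a single layer
object (e.g. a shared image backbone) can be applied to several inputs per
step before its gradients are accumulated.

All randomness flows through an explicit ``numpy.random.Generator``; with a
fixed seed and one CPU thread, training histories are bit-reproducible.

Gradient correctness for every layer is pinned by numerical-derivative tests.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Dense",
    "Conv1D",
    "Conv2D",
    "DepthwiseConv2D",
    "BatchNorm",
    "MaxPool1D",
    "AvgPool2D",
    "GlobalAvgPool2D",
    "ReLU",
    "ReLU6",
    "Flatten",
    "Sequential",
    "InvertedResidual",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
    "collect_parameters",
]


class Layer:
    """Base layer: parameter dict, gradient dict, functional forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool):
        raise NotImplementedError

    def backward(self, dy: np.ndarray, cache):
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    def sublayers(self):
        return []


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["w"] = _he_init(rng, (n_in, n_out), n_in)
        self.params["b"] = np.zeros(n_out)
        self.zero_grads()

    def forward(self, x, train):
        return x @ self.params["w"] + self.params["b"], x

    def backward(self, dy, cache):
        x = cache
        self.grads["w"] += x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["w"].T


class Conv1D(Layer):
    """1-D convolution over (batch, channels, length); stride 1, zero padding."""

    def __init__(self, c_in, c_out, rng, kernel: int = 3, padding: int = 1):
        super().__init__()
        self.kernel = kernel
        self.padding = padding
        self.params["w"] = _he_init(rng, (c_out, c_in, kernel), c_in * kernel)
        self.params["b"] = np.zeros(c_out)
        self.zero_grads()

    def forward(self, x, train):
        k, p = self.kernel, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        cols = sliding_window_view(xp, k, axis=2)  # (B, C, L', k)
        y = np.einsum("bclk,ock->bol", cols, self.params["w"], optimize=True)
        y += self.params["b"][None, :, None]
        return y, (cols, xp.shape)

    def backward(self, dy, cache):
        cols, xp_shape = cache
        k, p = self.kernel, self.padding
        self.grads["w"] += np.einsum("bclk,bol->ock", cols, dy, optimize=True)
        self.grads["b"] += dy.sum(axis=(0, 2))
        dxp = np.zeros(xp_shape)
        g = np.einsum("bol,ock->bclk", dy, self.params["w"], optimize=True)
        l_out = dy.shape[2]
        for i in range(k):
            dxp[:, :, i : i + l_out] += g[:, :, :, i]
        if p:
            return dxp[:, :, p:-p]
        return dxp


class Conv2D(Layer):
    """2-D convolution over (batch, channels, H, W) with stride and padding."""

    def __init__(self, c_in, c_out, rng, kernel: int = 3, stride: int = 1,
                 padding: int = 1, bias: bool = True):
        super().__init__()
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self.use_bias = bias
        self.params["w"] = _he_init(
            rng, (c_out, c_in, kernel, kernel), c_in * kernel * kernel
        )
        if bias:
            self.params["b"] = np.zeros(c_out)
        self.zero_grads()

    def forward(self, x, train):
        k, s, p = self.kernel, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # cols: (B, C, H', W', k, k)
        y = np.einsum("bchwij,ocij->bohw", cols, self.params["w"], optimize=True)
        if self.use_bias:
            y += self.params["b"][None, :, None, None]
        return y, (cols, xp.shape)

    def backward(self, dy, cache):
        cols, xp_shape = cache
        k, s, p = self.kernel, self.stride, self.padding
        self.grads["w"] += np.einsum(
            "bchwij,bohw->ocij", cols, dy, optimize=True
        )
        if self.use_bias:
            self.grads["b"] += dy.sum(axis=(0, 2, 3))
        g = np.einsum("bohw,ocij->bchwij", dy, self.params["w"], optimize=True)
        dxp = np.zeros(xp_shape)
        h_out, w_out = dy.shape[2], dy.shape[3]
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * h_out : s, j : j + s * w_out : s] += (
                    g[:, :, :, :, i, j]
                )
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class DepthwiseConv2D(Layer):
    """Per-channel 3x3 convolution (the depthwise half of a separable conv)."""

    def __init__(self, channels, rng, kernel: int = 3, stride: int = 1,
                 padding: int = 1):
        super().__init__()
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self.params["w"] = _he_init(
            rng, (channels, kernel, kernel), kernel * kernel
        )
        self.params["b"] = np.zeros(channels)
        self.zero_grads()

    def forward(self, x, train):
        k, s, p = self.kernel, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        y = np.einsum("bchwij,cij->bchw", cols, self.params["w"], optimize=True)
        y += self.params["b"][None, :, None, None]
        return y, (cols, xp.shape)

    def backward(self, dy, cache):
        cols, xp_shape = cache
        k, s, p = self.kernel, self.stride, self.padding
        self.grads["w"] += np.einsum(
            "bchwij,bchw->cij", cols, dy, optimize=True
        )
        self.grads["b"] += dy.sum(axis=(0, 2, 3))
        g = np.einsum("bchw,cij->bchwij", dy, self.params["w"], optimize=True)
        dxp = np.zeros(xp_shape)
        h_out, w_out = dy.shape[2], dy.shape[3]
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * h_out : s, j : j + s * w_out : s] += (
                    g[:, :, :, :, i, j]
                )
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel axis (axis 1)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.zero_grads()

    def _shape(self, x):
        # broadcast shape putting channels on axis 1
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train):
        axes = (0,) + tuple(range(2, x.ndim))
        shp = self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shp)) * inv_std.reshape(shp)
        y = self.params["gamma"].reshape(shp) * xhat + self.params["beta"].reshape(shp)
        return y, (xhat, inv_std, axes, shp, train)

    def backward(self, dy, cache):
        xhat, inv_std, axes, shp, train = cache
        self.grads["gamma"] += (dy * xhat).sum(axis=axes)
        self.grads["beta"] += dy.sum(axis=axes)
        g = self.params["gamma"].reshape(shp)
        if not train:
            return dy * g * inv_std.reshape(shp)
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shp)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(shp)
        ) * inv_std.reshape(shp)
        return dx


class MaxPool1D(Layer):
    """Non-overlapping max pooling over the length axis; odd tail truncated."""

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, train):
        b, c, l = x.shape
        l2 = l // self.pool
        xr = x[:, :, : l2 * self.pool].reshape(b, c, l2, self.pool)
        idx = xr.argmax(axis=3)
        y = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]
        return y, (idx, x.shape)

    def backward(self, dy, cache):
        idx, x_shape = cache
        b, c, l = x_shape
        l2 = dy.shape[2]
        dxr = np.zeros((b, c, l2, self.pool))
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=3)
        dx = np.zeros(x_shape)
        dx[:, :, : l2 * self.pool] = dxr.reshape(b, c, l2 * self.pool)
        return dx


class AvgPool2D(Layer):
    """Non-overlapping average pooling (used to downsample images on entry)."""

    def __init__(self, pool: int):
        super().__init__()
        self.pool = pool

    def forward(self, x, train):
        if self.pool == 1:
            return x, x.shape
        b, c, h, w = x.shape
        p = self.pool
        h2, w2 = h // p, w // p
        y = x[:, :, : h2 * p, : w2 * p].reshape(b, c, h2, p, w2, p).mean(axis=(3, 5))
        return y, x.shape

    def backward(self, dy, cache):
        x_shape = cache
        if self.pool == 1:
            return dy
        b, c, h, w = x_shape
        p = self.pool
        h2, w2 = dy.shape[2], dy.shape[3]
        dx = np.zeros(x_shape)
        dx[:, :, : h2 * p, : w2 * p] = np.repeat(
            np.repeat(dy, p, axis=2), p, axis=3
        ) / (p * p)
        return dx


class GlobalAvgPool2D(Layer):
    def forward(self, x, train):
        return x.mean(axis=(2, 3)), x.shape

    def backward(self, dy, cache):
        x_shape = cache
        b, c, h, w = x_shape
        return np.broadcast_to(dy[:, :, None, None], x_shape) / (h * w)


class ReLU(Layer):
    def forward(self, x, train):
        return np.maximum(x, 0.0), x > 0

    def backward(self, dy, cache):
        return dy * cache


class ReLU6(Layer):
    """min(max(x, 0), 6) — the activation of the efficient 2-D backbone."""

    def forward(self, x, train):
        return np.clip(x, 0.0, 6.0), (x > 0) & (x < 6)

    def backward(self, dy, cache):
        return dy * cache


class Flatten(Layer):
    def forward(self, x, train):
        return x.reshape(x.shape[0], -1), x.shape

    def backward(self, dy, cache):
        return dy.reshape(cache)


class Sequential(Layer):
    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train):
        caches = []
        for layer in self.layers:
            x, cache = layer.forward(x, train)
            caches.append(cache)
        return x, caches

    def backward(self, dy, caches):
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            dy = layer.backward(dy, cache)
        return dy

    def zero_grads(self):
        for layer in self.layers:
            layer.zero_grads()

    def sublayers(self):
        return self.layers


class InvertedResidual(Layer):
    """Expansion -> depthwise -> linear projection, with a skip connection
    when stride is 1 and channel count is preserved."""

    def __init__(self, c_in, c_out, rng, stride: int = 1, expand: int = 6):
        super().__init__()
        hidden = c_in * expand
        layers = []
        if expand != 1:
            layers += [
                Conv2D(c_in, hidden, rng, kernel=1, padding=0, bias=False),
                BatchNorm(hidden),
                ReLU6(),
            ]
        layers += [
            DepthwiseConv2D(hidden, rng, stride=stride),
            BatchNorm(hidden),
            ReLU6(),
            Conv2D(hidden, c_out, rng, kernel=1, padding=0, bias=False),
            BatchNorm(c_out),
        ]
        self.body = Sequential(layers)
        self.skip = stride == 1 and c_in == c_out

    def forward(self, x, train):
        y, cache = self.body.forward(x, train)
        if self.skip:
            y = y + x
        return y, cache

    def backward(self, dy, cache):
        dx = self.body.backward(dy, cache)
        if self.skip:
            dx = dx + dy
        return dx

    def zero_grads(self):
        self.body.zero_grads()

    def sublayers(self):
        return [self.body]


def collect_parameters(layers) -> list[tuple[Layer, str]]:
    """Walk a layer tree and list unique (layer, param-name) pairs.

    Deduplicated by object identity so a backbone shared between several
    input paths contributes its weights once.
    """
    out: list[tuple[Layer, str]] = []
    seen: set[int] = set()

    def visit(layer: Layer):
        if id(layer) in seen:
            return
        seen.add(id(layer))
        for name in layer.params:
            out.append((layer, name))
        for sub in layer.sublayers():
            visit(sub)

    for layer in layers:
        visit(layer)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean sparse categorical cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-12))
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adam optimizer over a fixed list of (layer, param-name) slots."""

    def __init__(self, slots, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.slots = list(slots)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[name]) for layer, name in self.slots]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.slots]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for i, (layer, name) in enumerate(self.slots):
            g = layer.grads[name]
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
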