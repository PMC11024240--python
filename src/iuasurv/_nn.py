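"""Minimal NumPy layer engine with reverse-mode gradients.

Supports exactly what the survival models in this package need: stride-1
'same' convolutions (im2col), 2x2 max pooling, batch normalization, SELU,
inverted dropout, global average pooling and dense layers, plus Nadam and
Nesterov-SGD optimizers with global-norm gradient clipping.  Data layout is
NHWC.  Every source of randomness (init, dropout) flows from a single
``numpy.random.Generator`` so runs are reproducible bit-for-bit.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

_SELU_SCALE = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


class Layer:
    """Base layer: ``params`` is a list of [name, value, grad, is_weight]."""

    def __init__(self):
        self.params: List[list] = []

    def forward(self, x, train: bool):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError

    def zero_grad(self):
        for p in self.params:
            p[2][...] = 0.0


class Conv2D(Layer):
    """Stride-1 'same' convolution via im2col; NHWC."""

    def __init__(self, in_ch, out_ch, k, rng, bias=True):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        fan_in = k * k * in_ch
        W = rng.normal(0.0, np.sqrt(1.0 / fan_in), size=(k, k, in_ch, out_ch))
        self.params = [["kernel", W, np.zeros_like(W), True]]
        self.bias = bias
        if bias:
            b = np.zeros(out_ch)
            self.params.append(["bias", b, np.zeros_like(b), False])

    def _im2col(self, x):
        n, h, w, c = x.shape
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = np.empty((n, h, w, k * k * c), dtype=x.dtype)
        idx = 0
        for di in range(k):
            for dj in range(k):
                cols[..., idx * c : (idx + 1) * c] = xp[:, di : di + h, dj : dj + w, :]
                idx += 1
        return cols

    def forward(self, x, train):
        self.x_shape = x.shape
        self.cols = self._im2col(x)
        W = self.params[0][1].reshape(-1, self.out_ch)
        out = self.cols @ W
        if self.bias:
            out += self.params[1][1]
        return out

    def backward(self, dout):
        n, h, w, _ = self.x_shape
        k, c = self.k, self.in_ch
        W = self.params[0][1].reshape(-1, self.out_ch)
        cols2d = self.cols.reshape(-1, k * k * c)
        dout2d = dout.reshape(-1, self.out_ch)
        self.params[0][2] += (cols2d.T @ dout2d).reshape(self.params[0][1].shape)
        if self.bias:
            self.params[1][2] += dout2d.sum(axis=0)
        dcols = (dout2d @ W.T).reshape(n, h, w, k * k * c)
        p = k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c))
        idx = 0
        for di in range(k):
            for dj in range(k):
                dxp[:, di : di + h, dj : dj + w, :] += dcols[
                    ..., idx * c : (idx + 1) * c
                ]
                idx += 1
        return dxp[:, p : p + h, p : p + w, :]


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2; input sides must be even."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        self.x_shape = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        self.xr = xr
        out = xr.max(axis=(2, 4))
        self.mask = xr == out[:, :, None, :, None, :]
        return out

    def backward(self, dout):
        n, h, w, c = self.x_shape
        # split gradient equally among tied maxima for determinism
        counts = self.mask.sum(axis=(2, 4), keepdims=True)
        d = self.mask * (dout[:, :, None, :, None, :] / counts)
        return d.reshape(n, h, w, c)


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel axis (last)."""

    def __init__(self, n_features, momentum=0.9, eps=1e-5):
        super().__init__()
        g = np.ones(n_features)
        b = np.zeros(n_features)
        self.params = [
            ["gamma", g, np.zeros_like(g), False],
            ["beta", b, np.zeros_like(b), False],
        ]
        self.moving_mean = np.zeros(n_features)
        self.moving_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    @property
    def n_stat_params(self) -> int:
        """Moving mean and variance, counted as non-trainable parameters."""
        return self.moving_mean.size + self.moving_var.size

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.moving_mean = self.momentum * self.moving_mean + (1 - self.momentum) * mean
            self.moving_var = self.momentum * self.moving_var + (1 - self.momentum) * var
        else:
            mean, var = self.moving_mean, self.moving_var
        self.inv_std = 1.0 / np.sqrt(var + self.eps)
        self.xhat = (x - mean) * self.inv_std
        self.train_mode = train
        self.axes = axes
        self.m = x.size // x.shape[-1]
        return self.params[0][1] * self.xhat + self.params[1][1]

    def backward(self, dout):
        gamma = self.params[0][1]
        self.params[0][2] += (dout * self.xhat).sum(axis=self.axes)
        self.params[1][2] += dout.sum(axis=self.axes)
        dxhat = dout * gamma
        if not self.train_mode:
            return dxhat * self.inv_std
        m = self.m
        return (
            self.inv_std
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=self.axes)
                - self.xhat * (dxhat * self.xhat).sum(axis=self.axes)
            )
        )


class SELU(Layer):
    def forward(self, x, train):
        self.x = x
        return _SELU_SCALE * np.where(x > 0, x, _SELU_ALPHA * (np.exp(x) - 1))

    def backward(self, dout):
        return dout * _SELU_SCALE * np.where(
            self.x > 0, 1.0, _SELU_ALPHA * np.exp(self.x)
        )


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate, rng):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self.mask = None
            return x
        self.mask = (self.rng.uniform(size=x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self.mask

    def backward(self, dout):
        return dout if self.mask is None else dout * self.mask


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self.x_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self.x_shape
        return np.broadcast_to(dout[:, None, None, :], (n, h, w, c)) / (h * w)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng, init="lecun"):
        super().__init__()
        std = np.sqrt(1.0 / n_in)
        W = rng.normal(0.0, std, size=(n_in, n_out))
        b = np.zeros(n_out)
        self.params = [
            ["kernel", W, np.zeros_like(W), True],
            ["bias", b, np.zeros_like(b), False],
        ]

    def forward(self, x, train):
        self.x = x
        return x @ self.params[0][1] + self.params[1][1]

    def backward(self, dout):
        self.params[0][2] += self.x.T @ dout
        self.params[1][2] += dout.sum(axis=0)
        return dout @ self.params[0][1].T


class Sequential:
    """Ordered layer stack with activation capture for Grad-CAM."""

    def __init__(self, layers: List[Layer]):
        self.layers = layers

    def forward(self, x, train: bool = False, keep_activations: bool = False):
        acts = []
        for layer in self.layers:
            x = layer.forward(x, train)
            if keep_activations:
                acts.append(x)
        if keep_activations:
            self.activations = acts
        return x

    def backward(self, dout, stop_at: Optional[int] = None):
        """Backpropagate; if ``stop_at`` is given, return the gradient flowing
        into the *output* of layer index ``stop_at`` (without updating the
        gradients of earlier layers)."""
        for i in range(len(self.layers) - 1, -1, -1):
            if stop_at is not None and i == stop_at:
                return dout
            dout = self.layers[i].backward(dout)
        return dout

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def parameters(self):
        for layer in self.layers:
            for p in layer.params:
                yield p

    def weight_sq_norm(self) -> float:
        return float(sum(np.sum(p[1] ** 2) for p in self.parameters() if p[3]))

    def n_parameters(self) -> int:
        n = sum(p[1].size for p in self.parameters())
        n += sum(
            layer.n_stat_params for layer in self.layers if isinstance(layer, BatchNorm)
        )
        return n

    def get_weights(self):
        flat = [p[1].copy() for p in self.parameters()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                flat.append(layer.moving_mean.copy())
                flat.append(layer.moving_var.copy())
        return flat

    def set_weights(self, flat):
        flat = list(flat)
        k = 0
        for p in self.parameters():
            p[1][...] = flat[k]
            k += 1
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.moving_mean[...] = flat[k]
                layer.moving_var[...] = flat[k + 1]
                k += 2


def clip_gradients(model: Sequential, max_norm: float) -> float:
    """Scale all gradients so the global L2 norm is at most ``max_norm``."""
    total = np.sqrt(sum(np.sum(p[2] ** 2) for p in model.parameters()))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in model.parameters():
            p[2] *= scale
    return float(total)


class Nadam:
    """Nesterov-momentum Adam (Dozat 2016), the common formulation."""

    def __init__(self, model, lr=0.002, beta1=0.9, beta2=0.999, eps=1e-7):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p[1]) for p in model.parameters()]
        self.v = [np.zeros_like(p[1]) for p in model.parameters()]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.model.parameters()):
            g = p[2]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** (self.t + 1))
            v_hat = self.v[i] / (1 - b2 ** self.t)
            update = b1 * m_hat + (1 - b1) * g / (1 - b1 ** self.t)
            p[1] -= self.lr * update / (np.sqrt(v_hat) + self.eps)


class SGDNesterov:
    def __init__(self, model, lr=0.01, momentum=0.9):
        self.model = model
        self.lr, self.mu = lr, momentum
        self.vel = [np.zeros_like(p[1]) for p in model.parameters()]

    def step(self):
        for i, p in enumerate(self.model.parameters()):
            g = p[2]
            self.vel[i] = self.mu * self.vel[i] - self.lr * g
            p[1] += self.mu * self.vel[i] - self.lr * g
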