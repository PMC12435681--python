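"""Layer ops (forward + backward) for the NHWC numpy engine.

Convolutions use an im2col/col2im pair; TensorFlow-style padding semantics
are used so the architecture shape calculus matches the executed model:
``same`` convolutions produce ``ceil(in/stride)`` and may pad
asymmetrically, ``valid`` pooling produces ``floor((in-k)/stride)+1``.
"""

from __future__ import annotations

import numpy as np

from .core import DTYPE, Layer, Parameter, variance_scaling


def _same_pad(in_size: int, k: int, s: int) -> tuple[int, int]:
    out = -(-in_size // s)
    total = max((out - 1) * s + k - in_size, 0)
    return total // 2, total - total // 2


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _im2col(xp: np.ndarray, k: int, s: int) -> np.ndarray:
    v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    v = v[:, ::s, ::s]  # (N, Ho, Wo, C, k, k)
    return np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3))  # (N, Ho, Wo, k, k, C)


def _col2im(dcols: np.ndarray, xp_shape: tuple, s: int) -> np.ndarray:
    n, ho, wo, k, _, c = dcols.shape
    dxp = np.zeros(xp_shape, dtype=DTYPE)
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + s * ho : s, j : j + s * wo : s, :] += dcols[:, :, :, i, j, :]
    return dxp


class Conv2D(Layer):
    def __init__(self, in_channels, out_channels, kernel, stride=1, padding="same",
                 use_bias=True, regularized=True, rng=None, name="conv"):
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be positive")
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        self.cin, self.cout, self.k, self.s, self.padding = (
            in_channels, out_channels, kernel, stride, padding)
        rng = rng or np.random.default_rng(0)
        fan_in = kernel * kernel * in_channels
        self.w = Parameter(variance_scaling(rng, (kernel, kernel, in_channels, out_channels), fan_in),
                           regularized=regularized, name=f"{name}/kernel")
        self.b = Parameter(np.zeros(out_channels), name=f"{name}/bias") if use_bias else None

    def parameters(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, inputs, training, rng):
        (x,) = inputs
        if x.shape[-1] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[-1]}")
        if self.padding == "same":
            pt, pb = _same_pad(x.shape[1], self.k, self.s)
            pl, pr = _same_pad(x.shape[2], self.k, self.s)
            xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        else:
            if x.shape[1] < self.k or x.shape[2] < self.k:
                raise ValueError("input smaller than kernel under valid padding")
            pt = pl = 0
            xp = x
        cols = _im2col(xp, self.k, self.s)
        n, ho, wo = cols.shape[:3]
        flat = cols.reshape(n * ho * wo, -1)
        out = flat @ self.w.value.reshape(-1, self.cout)
        if self.b is not None:
            out += self.b.value
        out = out.reshape(n, ho, wo, self.cout)
        return out, (cols, xp.shape, x.shape, (pt, pl))

    def backward(self, grad, cache):
        cols, xp_shape, x_shape, (pt, pl) = cache
        n, ho, wo = grad.shape[:3]
        gflat = grad.reshape(n * ho * wo, self.cout)
        flat = cols.reshape(n * ho * wo, -1)
        self.w.grad += (flat.T @ gflat).reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += gflat.sum(axis=0)
        dcols = (gflat @ self.w.value.reshape(-1, self.cout).T).reshape(cols.shape)
        dxp = _col2im(dcols, xp_shape, self.s)
        dx = dxp[:, pt : pt + x_shape[1], pl : pl + x_shape[2], :]
        return [dx]


class DepthwiseConv2D(Layer):
    def __init__(self, channels, kernel, stride=1, padding="same", use_bias=False,
                 rng=None, name="dwconv"):
        self.c, self.k, self.s, self.padding = channels, kernel, stride, padding
        rng = rng or np.random.default_rng(0)
        self.w = Parameter(variance_scaling(rng, (kernel, kernel, channels), kernel * kernel),
                           regularized=True, name=f"{name}/depthwise_kernel")
        self.b = Parameter(np.zeros(channels), name=f"{name}/bias") if use_bias else None

    def parameters(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, inputs, training, rng):
        (x,) = inputs
        if self.padding == "same":
            pt, pb = _same_pad(x.shape[1], self.k, self.s)
            pl, pr = _same_pad(x.shape[2], self.k, self.s)
            xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        else:
            pt = pl = 0
            xp = x
        cols = _im2col(xp, self.k, self.s)  # (N, Ho, Wo, k, k, C)
        out = np.einsum("nhwijc,ijc->nhwc", cols, self.w.value)
        if self.b is not None:
            out = out + self.b.value
        return out, (cols, xp.shape, x.shape, (pt, pl))

    def backward(self, grad, cache):
        cols, xp_shape, x_shape, (pt, pl) = cache
        self.w.grad += np.einsum("nhwijc,nhwc->ijc", cols, grad)
        if self.b is not None:
            self.b.grad += grad.sum(axis=(0, 1, 2))
        dcols = grad[:, :, :, None, None, :] * self.w.value[None, None, None]
        dxp = _col2im(dcols, xp_shape, self.s)
        dx = dxp[:, pt : pt + x_shape[1], pl : pl + x_shape[2], :]
        return [dx]


class MaxPool2D(Layer):
    """Valid-padding max pooling (the convention forced by the layer table)."""

    def __init__(self, kernel, stride):
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be positive")
        self.k, self.s = kernel, stride

    def forward(self, inputs, training, rng):
        (x,) = inputs
        n, h, w, c = x.shape
        if h < self.k or w < self.k:
            raise ValueError(f"pool kernel {self.k} exceeds spatial dims {(h, w)}")
        ho = (h - self.k) // self.s + 1
        wo = (w - self.k) // self.s + 1
        best = np.full((n, ho, wo, c), -np.inf, dtype=DTYPE)
        idx = np.zeros((n, ho, wo, c), dtype=np.int16)
        for i in range(self.k):
            for j in range(self.k):
                cand = x[:, i : i + self.s * ho : self.s, j : j + self.s * wo : self.s, :]
                sel = cand > best
                best = np.where(sel, cand, best)
                idx = np.where(sel, np.int16(i * self.k + j), idx)
        return best, (idx, x.shape)

    def backward(self, grad, cache):
        idx, x_shape = cache
        n, ho, wo, c = grad.shape
        dx = np.zeros(x_shape, dtype=DTYPE)
        ni, hi, wi, ci = np.ogrid[:n, :ho, :wo, :c]
        rows = hi * self.s + idx // self.k
        cols = wi * self.s + idx % self.k
        np.add.at(dx, (ni, rows, cols, ci), grad)
        return [dx]


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (channel) axis."""

    # momentum 0.9: moving statistics converge within the few hundred steps
    # of a desk-scale schedule (0.99 leaves them near their initial values)
    def __init__(self, channels, momentum=0.9, eps=1e-3, name="bn"):
        self.momentum, self.eps = momentum, eps
        self.gamma = Parameter(np.ones(channels), name=f"{name}/gamma")
        self.beta = Parameter(np.zeros(channels), name=f"{name}/beta")
        self.moving_mean = Parameter(np.zeros(channels), trainable=False, name=f"{name}/moving_mean")
        self.moving_var = Parameter(np.ones(channels), trainable=False, name=f"{name}/moving_variance")

    def parameters(self):
        return [self.gamma, self.beta, self.moving_mean, self.moving_var]

    def forward(self, inputs, training, rng):
        (x,) = inputs
        axes = tuple(range(x.ndim - 1))
        # A frozen batch-norm layer behaves as at inference: statistics stop
        # updating, so freezing leaves every stored value bit-identical.
        training = training and self.gamma.trainable
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.moving_mean.value[...] = m * self.moving_mean.value + (1 - m) * mean
            self.moving_var.value[...] = m * self.moving_var.value + (1 - m) * var
        else:
            mean, var = self.moving_mean.value, self.moving_var.value
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        out = self.gamma.value * xhat + self.beta.value
        return out, (xhat, inv_std, axes, training)

    def backward(self, grad, cache):
        xhat, inv_std, axes, training = cache
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        if not training:
            return [grad * self.gamma.value * inv_std]
        m = np.prod([xhat.shape[a] for a in axes])
        g = grad * self.gamma.value
        dx = inv_std * (g - g.mean(axis=axes) - xhat * (g * xhat).sum(axis=axes) / m)
        return [dx]


class Dense(Layer):
    def __init__(self, in_features, out_features, use_bias=True, regularized=True,
                 rng=None, name="dense"):
        rng = rng or np.random.default_rng(0)
        self.w = Parameter(variance_scaling(rng, (in_features, out_features), in_features, scale=1.0),
                           regularized=regularized, name=f"{name}/kernel")
        self.b = Parameter(np.zeros(out_features), name=f"{name}/bias") if use_bias else None

    def parameters(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, inputs, training, rng):
        (x,) = inputs
        out = x @ self.w.value
        if self.b is not None:
            out = out + self.b.value
        return out, x

    def backward(self, grad, cache):
        x = cache
        self.w.grad += x.T @ grad
        if self.b is not None:
            self.b.grad += grad.sum(axis=0)
        return [grad @ self.w.value.T]


class LeakyReLU(Layer):
    def __init__(self, alpha=0.3):
        self.alpha = alpha

    def forward(self, inputs, training, rng):
        (x,) = inputs
        return np.where(x >= 0, x, self.alpha * x), x >= 0

    def backward(self, grad, cache):
        return [np.where(cache, grad, self.alpha * grad)]


class ReLU(Layer):
    def forward(self, inputs, training, rng):
        (x,) = inputs
        return np.maximum(x, 0), x > 0

    def backward(self, grad, cache):
        return [grad * cache]


class SiLU(Layer):
    """x * sigmoid(x) (the EfficientNet family's activation)."""

    def forward(self, inputs, training, rng):
        (x,) = inputs
        s = 1.0 / (1.0 + np.exp(-x))
        return x * s, (x, s)

    def backward(self, grad, cache):
        x, s = cache
        return [grad * (s + x * s * (1 - s))]


class Sigmoid(Layer):
    def forward(self, inputs, training, rng):
        (x,) = inputs
        # numerically stable form: exp of a non-positive argument only
        p = np.where(x >= 0,
                     1.0 / (1.0 + np.exp(-np.maximum(x, 0))),
                     np.exp(np.minimum(x, 0)) / (1.0 + np.exp(np.minimum(x, 0))))
        return p, p

    def backward(self, grad, cache):
        p = cache
        return [grad * p * (1 - p)]


class Softmax(Layer):
    def forward(self, inputs, training, rng):
        (x,) = inputs
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        return p, p

    def backward(self, grad, cache):
        p = cache
        return [p * (grad - (grad * p).sum(axis=-1, keepdims=True))]


class GlobalAvgPool2D(Layer):
    def forward(self, inputs, training, rng):
        (x,) = inputs
        return x.mean(axis=(1, 2)), x.shape

    def backward(self, grad, cache):
        n, h, w, c = cache
        return [np.broadcast_to(grad[:, None, None, :] / (h * w), cache).astype(DTYPE)]


class GlobalMaxPool2D(Layer):
    def forward(self, inputs, training, rng):
        (x,) = inputs
        n, h, w, c = x.shape
        flat = x.reshape(n, h * w, c)
        idx = flat.argmax(axis=1)
        out = np.take_along_axis(flat, idx[:, None, :], axis=1)[:, 0, :]
        return out, (idx, x.shape)

    def backward(self, grad, cache):
        idx, shape = cache
        n, h, w, c = shape
        dflat = np.zeros((n, h * w, c), dtype=DTYPE)
        np.put_along_axis(dflat, idx[:, None, :], grad[:, None, :], axis=1)
        return [dflat.reshape(shape)]


class Dropout(Layer):
    def __init__(self, rate):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, inputs, training, rng):
        (x,) = inputs
        if not training or self.rate == 0:
            return x, None
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        mask = (rng.random(x.shape) >= self.rate).astype(DTYPE) / (1 - self.rate)
        return x * mask, mask

    def backward(self, grad, cache):
        return [grad if cache is None else grad * cache]


class Add(Layer):
    def forward(self, inputs, training, rng):
        out = inputs[0]
        for x in inputs[1:]:
            out = out + x
        return out, len(inputs)

    def backward(self, grad, cache):
        return [grad] * cache


class Multiply(Layer):
    """Elementwise product of two inputs with numpy broadcasting."""

    def forward(self, inputs, training, rng):
        a, b = inputs
        return a * b, (a, b)

    def backward(self, grad, cache):
        a, b = cache
        return [_unbroadcast(grad * b, a.shape), _unbroadcast(grad * a, b.shape)]


class Concat(Layer):
    def forward(self, inputs, training, rng):
        return np.concatenate(inputs, axis=-1), [x.shape[-1] for x in inputs]

    def backward(self, grad, cache):
        splits = np.cumsum(cache)[:-1]
        return list(np.split(grad, splits, axis=-1))


class ExpandSpatial(Layer):
    """(N, C) -> (N, 1, 1, C), so channel vectors broadcast over space."""

    def forward(self, inputs, training, rng):
        (x,) = inputs
        return x[:, None, None, :], None

    def backward(self, grad, cache):
        return [grad[:, 0, 0, :]]


class ChannelAvgMax(Layer):
    """Stack channel-mean and channel-max maps: (N,H,W,C) -> (N,H,W,2)."""

    def forward(self, inputs, training, rng):
        (x,) = inputs
        avg = x.mean(axis=-1, keepdims=True)
        idx = x.argmax(axis=-1)
        mx = np.take_along_axis(x, idx[..., None], axis=-1)
        return np.concatenate([avg, mx], axis=-1), (idx, x.shape)

    def backward(self, grad, cache):
        idx, shape = cache
        dx = np.broadcast_to(grad[..., 0:1] / shape[-1], shape).astype(DTYPE).copy()
        np.put_along_axis(dx, idx[..., None],
                          np.take_along_axis(dx, idx[..., None], axis=-1) + grad[..., 1:2],
                          axis=-1)
        return [dx]


class Identity(Layer):
    def forward(self, inputs, training, rng):
        return inputs[0], None

    def backward(self, grad, cache):
        return [grad]
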