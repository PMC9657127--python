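"""Standard CNN layers: convolution, batch normalisation, activations,
pooling and the linear classifier head."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import functional as F
from .module import Module, Parameter

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "Linear",
    "MaxPool2d",
    "GlobalAvgPool",
]


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


class Conv2d(Module):
    """2-D convolution (cross-correlation) with stride, zero padding and
    channel groups. Bias defaults off: every convolution in the backbones
    is followed by a normalisation that subsumes it."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=1, padding=0,
                 groups=1, bias=False, rng: np.random.Generator | None = None):
        super().__init__()
        kh, kw = _pair(kernel_size)
        if in_channels % groups or out_channels % groups:
            raise ValueError("groups must divide both channel counts")
        rng = rng or np.random.default_rng()
        fan_in = in_channels // groups * kh * kw
        std = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU-family nets
        self.weight = Parameter(rng.normal(0.0, std, (out_channels, in_channels // groups, kh, kw)).astype(np.float32))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self.stride = _pair(stride)
        self.padding = _pair(padding)
        self.groups = groups
        self._cache = None

    def forward(self, x):
        out, self._cache = F.conv2d_forward(
            x, self.weight.data, self.stride, self.padding, self.groups,
            None if self.bias is None else self.bias.data)
        return out

    def backward(self, grad_out):
        grad_x, grad_w, grad_b = F.conv2d_backward(grad_out, self._cache)
        self.weight.grad = self.weight.grad + grad_w
        if self.bias is not None:
            self.bias.grad = self.bias.grad + grad_b
        return grad_x


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x):
        out, self._cache = F.batchnorm_forward(
            x, self.weight.data, self.bias.data, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps)
        return out

    def backward(self, grad_out):
        grad_x, grad_scale, grad_shift = F.batchnorm_backward(grad_out, self._cache)
        self.weight.grad = self.weight.grad + grad_scale
        self.bias.grad = self.bias.grad + grad_shift
        return grad_x


class ReLU(Module):
    """Scalar rectifier: f(x) = max(x, 0)."""

    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, np.zeros((), dtype=x.dtype))

    def backward(self, grad_out):
        return grad_out * self._mask


class Sigmoid(Module):
    def __init__(self):
        super().__init__()
        self._out = None

    def forward(self, x):
        with np.errstate(over="ignore"):
            self._out = 1.0 / (1.0 + np.exp(-x))
        return self._out

    def backward(self, grad_out):
        return grad_out * self._out * (1.0 - self._out)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, std, (out_features, in_features)).astype(np.float32))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None
        self._x = None

    def forward(self, x):
        self._x = x
        out = x @ self.weight.data.T
        if self.bias is not None:
            out = out + self.bias.data
        return out

    def backward(self, grad_out):
        self.weight.grad = self.weight.grad + grad_out.T @ self._x
        if self.bias is not None:
            self.bias.grad = self.bias.grad + grad_out.sum(axis=0)
        return grad_out @ self.weight.data


class MaxPool2d(Module):
    def __init__(self, kernel_size, stride=None, padding=0):
        super().__init__()
        self.k = _pair(kernel_size)
        self.stride = _pair(stride) if stride is not None else self.k
        self.padding = _pair(padding)
        self._cache = None

    def forward(self, x):
        kh, kw = self.k
        sh, sw = self.stride
        ph, pw = self.padding
        neg = np.finfo(x.dtype).min if np.issubdtype(x.dtype, np.floating) else np.iinfo(x.dtype).min
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)), constant_values=neg)
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
        n, c, ho, wo = win.shape[:4]
        flat = win.reshape(n, c, ho, wo, kh * kw)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        self._cache = (arg, x.shape, xp.shape)
        return out

    def backward(self, grad_out):
        arg, x_shape, xp_shape = self._cache
        kh, kw = self.k
        sh, sw = self.stride
        ph, pw = self.padding
        n, c, ho, wo = grad_out.shape
        grad_xp = np.zeros((n, c, xp_shape[2], xp_shape[3]), dtype=grad_out.dtype)
        ki, kj = np.unravel_index(arg, (kh, kw))
        rows = (np.arange(ho)[None, None, :, None] * sh + ki)
        cols = (np.arange(wo)[None, None, None, :] * sw + kj)
        nn_idx = np.arange(n)[:, None, None, None]
        cc_idx = np.arange(c)[None, :, None, None]
        np.add.at(grad_xp, (nn_idx, cc_idx, rows, cols), grad_out)
        return grad_xp[:, :, ph : ph + x_shape[2], pw : pw + x_shape[3]]


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C) spatial mean; the squeeze step and the
    classifier-head pooling."""

    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad_out):
        n, c, h, w = self._shape
        return np.broadcast_to(grad_out[:, :, None, None] / (h * w), self._shape).astype(grad_out.dtype, copy=False)
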