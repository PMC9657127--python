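"""The cross-shaped spatially conditioned activation (CroReLU).

ReLU activates each scalar against the constant condition 0:
``f(x) = max(x, 0)``. CroReLU replaces the constant by a learned *spatial
condition* ``L(x)`` computed from a cross-shaped window centred on the same
pixel, so the activation of a feature-map scalar sees its vertical and
horizontal context:

    f(x[c,i,j]) = max(x[c,i,j], L(x)[c,i,j])
    L(x)[c]     = x[c] * P1[c] + x[c] * P2[c]

where ``P1[c]`` is a per-channel ``kh x 1`` kernel, ``P2[c]`` a per-channel
``1 x kw`` kernel (``*`` is 2-D cross-correlation with zero padding and
stride 1). By linearity of convolution the two 1-D branches are exactly
equivalent to a single 2-D kernel supported on a cross — the vertical and
horizontal kernels zero-padded to ``kh x kw`` and summed, with the centre
coefficient counted by both branches. The summed condition is passed
through a per-channel batch normalisation with a learnable affine so it
stays on the scale of the identity path; with all-zero condition weights
and an identity normalisation the operator degenerates to ReLU exactly.

The cross window targets elongated, tubular/papillary structures: a thin
bright ridge running through a pixel raises the condition along its axis,
letting the activation pass contextual evidence that a scalar threshold
cannot see.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import functional as F
from .nn.module import Module, Parameter

__all__ = [
    "CrossWindowSpec",
    "relu",
    "cross_condition",
    "crorelu",
    "compose_cross_kernel",
    "condition_param_count",
    "CroReLU",
]


def _validate_tensor(x: np.ndarray, name: str = "x") -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 4:
        raise ValueError(f"{name} must be 4-D (batch, channel, height, width); got ndim={x.ndim}")
    if any(d < 1 for d in x.shape):
        raise ValueError(f"{name} must have positive dimensions; got shape {x.shape}")
    if not np.isfinite(x).all():
        raise ValueError(f"{name} contains non-finite values")
    return x


@dataclass
class CrossWindowSpec:
    """Weights and normalisation state of one cross-shaped condition.

    ``w_vertical[c]`` is the ``kh x 1`` branch of channel ``c`` (row
    direction), ``w_horizontal[c]`` the ``1 x kw`` branch. ``normalize``
    switches the per-channel normalisation of the summed condition; with it
    off the affine/running fields are ignored.
    """

    kh: int
    kw: int
    w_vertical: np.ndarray
    w_horizontal: np.ndarray
    norm_scale: np.ndarray | None = None
    norm_shift: np.ndarray | None = None
    norm_running_mean: np.ndarray | None = None
    norm_running_var: np.ndarray | None = None
    normalize: bool = True
    eps: float = 1e-5
    channels: int = field(init=False)

    def __post_init__(self):
        if self.kh < 1 or self.kh % 2 == 0 or self.kw < 1 or self.kw % 2 == 0:
            raise ValueError(f"window extents must be odd and >= 1; got kh={self.kh}, kw={self.kw}")
        self.w_vertical = np.asarray(self.w_vertical)
        self.w_horizontal = np.asarray(self.w_horizontal)
        if self.w_vertical.ndim != 2 or self.w_vertical.shape[1] != self.kh:
            raise ValueError(f"w_vertical must be (channels, {self.kh}); got {self.w_vertical.shape}")
        if self.w_horizontal.ndim != 2 or self.w_horizontal.shape[1] != self.kw:
            raise ValueError(f"w_horizontal must be (channels, {self.kw}); got {self.w_horizontal.shape}")
        if self.w_vertical.shape[0] != self.w_horizontal.shape[0]:
            raise ValueError("branch weight arrays disagree on channel count")
        self.channels = int(self.w_vertical.shape[0])
        c = self.channels
        if self.norm_scale is None:
            self.norm_scale = np.ones(c)
        if self.norm_shift is None:
            self.norm_shift = np.zeros(c)
        if self.norm_running_mean is None:
            self.norm_running_mean = np.zeros(c)
        if self.norm_running_var is None:
            self.norm_running_var = np.ones(c)
        for name in ("norm_scale", "norm_shift", "norm_running_mean", "norm_running_var"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (c,):
                raise ValueError(f"{name} must have shape ({c},); got {arr.shape}")
            setattr(self, name, arr)
        if (self.norm_running_var < 0).any():
            raise ValueError("norm_running_var entries must be >= 0")

    @classmethod
    def initialize(cls, channels: int, kh: int = 3, kw: int = 3, *, normalize: bool = True,
                   init_std: float = 0.01, rng: np.random.Generator | None = None,
                   dtype=np.float32) -> "CrossWindowSpec":
        """Near-ReLU start: small zero-mean branch weights, identity affine."""
        rng = rng or np.random.default_rng()
        return cls(
            kh=kh,
            kw=kw,
            w_vertical=rng.normal(0.0, init_std, (channels, kh)).astype(dtype),
            w_horizontal=rng.normal(0.0, init_std, (channels, kw)).astype(dtype),
            norm_scale=np.ones(channels, dtype=dtype),
            norm_shift=np.zeros(channels, dtype=dtype),
            norm_running_mean=np.zeros(channels, dtype=dtype),
            norm_running_var=np.ones(channels, dtype=dtype),
            normalize=normalize,
        )


def relu(x: np.ndarray) -> np.ndarray:
    """Scalar rectifier max(x, 0) on a validated 4-D activation array."""
    x = _validate_tensor(x)
    return np.maximum(x, 0)


def _raw_condition(x: np.ndarray, spec: CrossWindowSpec) -> np.ndarray:
    """Sum of the depthwise vertical and horizontal branches, un-normalised."""
    c = x.shape[1]
    wv = spec.w_vertical.reshape(c, 1, spec.kh, 1)
    wh = spec.w_horizontal.reshape(c, 1, 1, spec.kw)
    v, _ = F.conv2d_forward(x, wv, stride=(1, 1), pad=((spec.kh - 1) // 2, 0), groups=c)
    h, _ = F.conv2d_forward(x, wh, stride=(1, 1), pad=(0, (spec.kw - 1) // 2), groups=c)
    return v + h


def cross_condition(x: np.ndarray, spec: CrossWindowSpec, training: bool = False) -> np.ndarray:
    """The crossover condition L(x): depthwise vertical + horizontal 1-D
    convolutions (zero padding, stride 1), then per-channel normalisation.

    ``training`` selects batch statistics for the normalisation; inference
    uses the spec's running statistics. Shape is preserved. This functional
    form never mutates the spec's running statistics (the :class:`CroReLU`
    layer owns that bookkeeping).
    """
    x = _validate_tensor(x)
    if x.shape[1] != spec.channels:
        raise ValueError(f"channel mismatch: input has {x.shape[1]} channels, spec has {spec.channels}")
    cond = _raw_condition(x, spec)
    if not spec.normalize:
        return cond
    mean = spec.norm_running_mean.copy()
    var = spec.norm_running_var.copy()
    out, _ = F.batchnorm_forward(cond, spec.norm_scale, spec.norm_shift, mean, var,
                                 training=training, eps=spec.eps)
    return out


def crorelu(x: np.ndarray, spec: CrossWindowSpec, training: bool = False) -> np.ndarray:
    """f(x) = max(x, L(x)) elementwise; shape preserved."""
    x = _validate_tensor(x)
    return np.maximum(x, cross_condition(x, spec, training=training))


def compose_cross_kernel(spec: CrossWindowSpec) -> np.ndarray:
    """The single 2-D kernel equivalent to the two 1-D branches.

    Convolution is linear in the kernel, so summing the ``kh x 1`` and
    ``1 x kw`` kernels zero-padded to ``kh x kw`` gives a kernel supported
    on a cross whose response equals the sum of the branch responses; the
    centre coefficient is the sum of both centre weights.
    """
    c, kh, kw = spec.channels, spec.kh, spec.kw
    kernel = np.zeros((c, kh, kw), dtype=np.result_type(spec.w_vertical, spec.w_horizontal))
    kernel[:, :, kw // 2] += spec.w_vertical
    kernel[:, kh // 2, :] += spec.w_horizontal
    return kernel


def condition_param_count(channels: int, kh: int, kw: int, *, normalize: bool = True,
                          bias: bool = False) -> int:
    """Trainable parameters added by one CroReLU site.

    Default convention: depthwise branches without bias plus one
    normalisation affine on the summed condition — ``C * (kh + kw + 2)``.
    """
    if channels < 1:
        raise ValueError("channels must be >= 1")
    per_channel = kh + kw + (2 if normalize else 0) + (2 if bias else 0)
    return int(channels) * per_channel


class CroReLU(Module):
    """CroReLU as a drop-in activation layer.

    Subgradient convention: where ``x == L(x)`` the gradient routes to the
    identity branch (as ReLU routes its tie at 0 to the zero side), so a
    zero-initialised condition trains from an exact ReLU start.
    """

    def __init__(self, channels: int, kh: int = 3, kw: int = 3, *, normalize: bool = True,
                 init_std: float = 0.01, momentum: float = 0.1, eps: float = 1e-5,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if kh < 1 or kh % 2 == 0 or kw < 1 or kw % 2 == 0:
            raise ValueError(f"window extents must be odd and >= 1; got kh={kh}, kw={kw}")
        rng = rng or np.random.default_rng()
        self.channels = channels
        self.kh, self.kw = kh, kw
        self.normalize = normalize
        self.momentum, self.eps = momentum, eps
        self.w_vertical = Parameter(rng.normal(0.0, init_std, (channels, kh)).astype(np.float32))
        self.w_horizontal = Parameter(rng.normal(0.0, init_std, (channels, kw)).astype(np.float32))
        if normalize:
            self.norm_scale = Parameter(np.ones(channels, dtype=np.float32))
            self.norm_shift = Parameter(np.zeros(channels, dtype=np.float32))
            self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
            self.register_buffer("running_var", np.ones(channels, dtype=np.float32))
        self._cache = None

    @property
    def spec(self) -> CrossWindowSpec:
        """A snapshot of the layer's current weights as a plain spec."""
        kw_args = dict(normalize=self.normalize, eps=self.eps)
        if self.normalize:
            kw_args.update(
                norm_scale=self.norm_scale.data.copy(),
                norm_shift=self.norm_shift.data.copy(),
                norm_running_mean=self.running_mean.copy(),
                norm_running_var=self.running_var.copy(),
            )
        return CrossWindowSpec(self.kh, self.kw, self.w_vertical.data.copy(),
                               self.w_horizontal.data.copy(), **kw_args)

    def forward(self, x):
        if x.shape[1] != self.channels:
            raise ValueError(f"channel mismatch: input has {x.shape[1]} channels, layer has {self.channels}")
        c = self.channels
        wv = self.w_vertical.data.reshape(c, 1, self.kh, 1)
        wh = self.w_horizontal.data.reshape(c, 1, 1, self.kw)
        v, cache_v = F.conv2d_forward(x, wv, pad=((self.kh - 1) // 2, 0), groups=c)
        h, cache_h = F.conv2d_forward(x, wh, pad=(0, (self.kw - 1) // 2), groups=c)
        cond = v + h
        if self.normalize:
            cond, cache_bn = F.batchnorm_forward(
                cond, self.norm_scale.data, self.norm_shift.data,
                self.running_mean, self.running_var, self.training, self.momentum, self.eps)
        else:
            cache_bn = None
        take_cond = cond > x  # ties route to the identity branch
        self._cache = (take_cond, cache_v, cache_h, cache_bn)
        return np.where(take_cond, cond, x)

    def backward(self, grad_out):
        take_cond, cache_v, cache_h, cache_bn = self._cache
        grad_x = np.where(take_cond, np.zeros((), dtype=grad_out.dtype), grad_out)
        grad_cond = np.where(take_cond, grad_out, np.zeros((), dtype=grad_out.dtype))
        if cache_bn is not None:
            grad_cond, g_scale, g_shift = F.batchnorm_backward(grad_cond, cache_bn)
            self.norm_scale.grad = self.norm_scale.grad + g_scale
            self.norm_shift.grad = self.norm_shift.grad + g_shift
        gx_v, gw_v, _ = F.conv2d_backward(grad_cond, cache_v)
        gx_h, gw_h, _ = F.conv2d_backward(grad_cond, cache_h)
        c = self.channels
        self.w_vertical.grad = self.w_vertical.grad + gw_v.reshape(c, self.kh)
        self.w_horizontal.grad = self.w_horizontal.grad + gw_h.reshape(c, self.kw)
        return grad_x + gx_v + gx_h

    def extra_param_count(self) -> int:
        return condition_param_count(self.channels, self.kh, self.kw, normalize=self.normalize)
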