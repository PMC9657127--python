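"""Array-level primitives shared by the layers.

Convolutions use an im2col/GEMM formulation with full support for stride,
zero padding and channel groups (``groups == in_channels`` gives depthwise
convolution, the form the cross-shaped activation condition uses).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv2d_forward",
    "conv2d_backward",
    "batchnorm_forward",
    "batchnorm_backward",
    "softmax",
    "cross_entropy",
]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: tuple[int, int], pad: tuple[int, int]):
    """(N, C, H, W) -> columns (N, C, kh, kw, Ho, Wo), zero padded."""
    sh, sw = stride
    ph, pw = pad
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    windows = sliding_window_view(x, (kh, kw), axis=(2, 3))  # N,C,Ho*,Wo*,kh,kw
    windows = windows[:, :, ::sh, ::sw]
    return np.ascontiguousarray(windows.transpose(0, 1, 4, 5, 2, 3))


def conv2d_forward(x, weight, stride=(1, 1), pad=(0, 0), groups=1, bias=None):
    """2-D cross-correlation.

    x: (N, Cin, H, W); weight: (Cout, Cin // groups, kh, kw).
    Returns (out, cache) where cache feeds :func:`conv2d_backward`.
    """
    n, cin, _, _ = x.shape
    cout, cig, kh, kw = weight.shape
    if cin != cig * groups:
        raise ValueError(f"channel mismatch: input has {cin} channels, kernel expects {cig * groups}")
    if cout % groups:
        raise ValueError("out_channels must be divisible by groups")
    cols = _im2col(x, kh, kw, stride, pad)  # N,Cin,kh,kw,Ho,Wo
    ho, wo = cols.shape[4], cols.shape[5]
    cols = cols.reshape(n, groups, cig * kh * kw, ho * wo)
    w = weight.reshape(groups, cout // groups, cig * kh * kw)
    out = np.matmul(w, cols)  # N,g,cog,L
    out = out.reshape(n, cout, ho, wo)
    if bias is not None:
        out = out + bias[None, :, None, None]
    cache = (cols, weight, x.shape, stride, pad, groups, (ho, wo), bias is not None)
    return out, cache


def conv2d_backward(grad_out, cache):
    """Returns (grad_x, grad_weight, grad_bias-or-None)."""
    cols, weight, x_shape, stride, pad, groups, (ho, wo), has_bias = cache
    n, cin, h, w_in = x_shape
    cout, cig, kh, kw = weight.shape
    sh, sw = stride
    ph, pw = pad
    g = grad_out.reshape(n, groups, cout // groups, ho * wo)
    grad_w = np.matmul(g, cols.transpose(0, 1, 3, 2)).sum(axis=0)
    grad_w = grad_w.reshape(cout, cig, kh, kw)
    wmat = weight.reshape(groups, cout // groups, cig * kh * kw)
    grad_cols = np.matmul(wmat.transpose(0, 2, 1), g)  # N,g,K,L
    grad_cols = grad_cols.reshape(n, cin, kh, kw, ho, wo)
    grad_xp = np.zeros((n, cin, h + 2 * ph, w_in + 2 * pw), dtype=grad_out.dtype)
    for ki in range(kh):
        for kj in range(kw):
            grad_xp[:, :, ki : ki + sh * ho : sh, kj : kj + sw * wo : sw] += grad_cols[:, :, ki, kj]
    grad_x = grad_xp[:, :, ph : ph + h, pw : pw + w_in]
    grad_b = grad_out.sum(axis=(0, 2, 3)) if has_bias else None
    return grad_x, grad_w, grad_b


def batchnorm_forward(x, scale, shift, running_mean, running_var, training, momentum=0.1, eps=1e-5):
    """Per-channel normalisation over (N, H, W) of an (N, C, H, W) array.

    In training mode batch statistics are used and the running statistics
    are updated in place; in inference mode the running statistics are used.
    """
    if training:
        mean = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        m = x.shape[0] * x.shape[2] * x.shape[3]
        unbiased = var * m / max(m - 1, 1)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out = xhat * scale[None, :, None, None] + shift[None, :, None, None]
    cache = (xhat, inv_std, scale, training)
    return out, cache


def batchnorm_backward(grad_out, cache):
    """Returns (grad_x, grad_scale, grad_shift)."""
    xhat, inv_std, scale, training = cache
    grad_scale = (grad_out * xhat).sum(axis=(0, 2, 3))
    grad_shift = grad_out.sum(axis=(0, 2, 3))
    gxhat = grad_out * scale[None, :, None, None]
    if not training:
        return gxhat * inv_std[None, :, None, None], grad_scale, grad_shift
    m = grad_out.shape[0] * grad_out.shape[2] * grad_out.shape[3]
    # batch statistics depend on x: full backward through mean/var
    grad_x = (
        gxhat
        - gxhat.mean(axis=(0, 2, 3))[None, :, None, None]
        - xhat * (gxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None] / m
    ) * inv_std[None, :, None, None]
    return grad_x, grad_scale, grad_shift


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean softmax cross-entropy. Returns (loss, grad_logits)."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n
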