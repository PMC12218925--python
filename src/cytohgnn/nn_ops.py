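"""Numpy building blocks for the neural components.

Convolutions use an im2col strategy built on
:func:`numpy.lib.stride_tricks.sliding_window_view` with the same-padding
convention (padding ``(f-1)/2`` for odd kernel size ``f``), so the spatial
output size is ``ceil(n / stride)``.

Batch normalisation follows ``y = (x - mu) / sqrt(var + eps) * gamma + beta``
with the biased (population) variance over the mini-batch during training
and exponentially averaged running statistics (momentum 0.1) at inference.
The functional forward/backward pair is shared by the feature-extractor
blocks and the hand-written classifier backprop.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

from .exceptions import DegenerateInputError, ShapeError
from .scaling import conv_output_size, padding_for_kernel

__all__ = [
    "sigmoid",
    "swish",
    "relu",
    "softmax",
    "conv2d",
    "depthwise_conv2d",
    "global_avg_pool",
    "BatchNorm",
    "bn_forward",
    "bn_backward",
]


def sigmoid(x):
    """Logistic sigmoid, numerically stable for large |x|."""
    return expit(np.asarray(x))


def swish(x):
    """Self-gated activation ``x * sigmoid(x)``."""
    x = np.asarray(x)
    return x * expit(x)


def relu(x):
    return np.maximum(np.asarray(x), 0)


def softmax(z, axis=-1):
    """Row-normalised exponentials; rows sum to one."""
    z = np.asarray(z, dtype=np.float64)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _windows(x, kernel_size, stride):
    """Padded sliding windows of shape (N, C, Ho, Wo, f, f)."""
    pad = padding_for_kernel(kernel_size)
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kernel_size, kernel_size), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def conv2d(x, weight, bias=None, stride=1):
    """2-D cross-correlation with same padding.

    Parameters
    ----------
    x : ndarray, shape (N, C_in, H, W)
    weight : ndarray, shape (C_out, C_in, f, f) with f odd
    """
    x = np.asarray(x)
    weight = np.asarray(weight)
    if x.ndim != 4 or weight.ndim != 4:
        raise ShapeError("conv2d expects x (N,C,H,W) and weight (Co,Ci,f,f)")
    if x.shape[1] != weight.shape[1]:
        raise ShapeError(
            f"channel mismatch: input has {x.shape[1]} channels, kernel expects {weight.shape[1]}"
        )
    if weight.shape[2] != weight.shape[3]:
        raise ShapeError("only square kernels are supported")
    win = _windows(x, weight.shape[2], stride)
    out = np.einsum("nchwij,ocij->nohw", win, weight, optimize=True)
    if bias is not None:
        out = out + bias[None, :, None, None]
    return out


def depthwise_convolve(x, weight, stride=1):
    """Per-channel (depthwise) convolution with same padding.

    One ``f x f`` kernel per input channel; no cross-channel mixing, so the
    number of kernels must equal the number of channels.  Spatial size
    follows ``ceil(n / stride)``.

    Parameters
    ----------
    x : ndarray, shape (N, C, H, W)
    weight : ndarray, shape (C, f, f)
    """
    x = np.asarray(x)
    weight = np.asarray(weight)
    if x.ndim != 4 or weight.ndim != 3:
        raise ShapeError("depthwise_convolve expects x (N,C,H,W) and weight (C,f,f)")
    if x.shape[1] != weight.shape[0]:
        raise ShapeError(
            f"kernel count {weight.shape[0]} does not match channel count {x.shape[1]}"
        )
    if weight.shape[1] != weight.shape[2]:
        raise ShapeError("only square kernels are supported")
    win = _windows(x, weight.shape[1], stride)
    return np.einsum("nchwij,cij->nchw", win, weight, optimize=True)


# alias matching the more conventional name used inside the backbone
depthwise_conv2d = depthwise_convolve


def global_avg_pool(x):
    """Spatial mean of each feature map: (N, C, H, W) -> (N, C)."""
    x = np.asarray(x)
    if x.ndim != 4:
        raise ShapeError("global_avg_pool expects a (N,C,H,W) array")
    return x.mean(axis=(2, 3))


def _bn_axes(x):
    if x.ndim == 2:  # (N, C): per-feature over samples
        return (0,)
    if x.ndim == 4:  # (N, C, H, W): per-channel over batch and space
        return (0, 2, 3)
    raise ShapeError(f"batch norm supports 2-D or 4-D inputs, got ndim={x.ndim}")


def bn_forward(x, gamma, beta, running_mean, running_var, *, training,
               eps=1e-5, momentum=0.1):
    """Batch-normalisation forward pass.

    Returns ``(y, cache)``; ``cache`` is None at inference.  During
    training the running statistics are updated in place with momentum 0.1
    and the biased batch variance is used for normalisation.
    """
    x = np.asarray(x)
    axes = _bn_axes(x)
    if x.shape[0] == 0 or x.size == 0:
        raise DegenerateInputError("batch normalisation requires a non-empty batch")
    shape = [1] * x.ndim
    shape[1 if x.ndim == 4 else -1] = -1

    def _b(v):
        return np.reshape(v, shape)

    if training:
        mu = x.mean(axis=axes)
        var = x.var(axis=axes)  # biased estimator
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x - _b(mu)) * _b(inv_std)
    y = xhat * _b(gamma) + _b(beta)
    cache = None
    if training:
        cache = (xhat, inv_std, gamma, axes, shape)
    return y, cache


def bn_backward(dy, cache):
    """Gradients of the training-mode batch-norm transform.

    Returns ``(dx, dgamma, dbeta)`` for the biased-variance normalisation
    used in :func:`bn_forward`.
    """
    xhat, inv_std, gamma, axes, shape = cache
    m = np.prod([xhat.shape[a] for a in axes])

    def _b(v):
        return np.reshape(v, shape)

    dgamma = np.sum(dy * xhat, axis=axes)
    dbeta = np.sum(dy, axis=axes)
    dxhat = dy * _b(gamma)
    dx = (_b(inv_std) / m) * (
        m * dxhat
        - _b(np.sum(dxhat, axis=axes))
        - xhat * _b(np.sum(dxhat * xhat, axis=axes))
    )
    return dx, dgamma, dbeta


class BatchNorm:
    """Stateful per-channel batch normalisation.

    Works on feature matrices ``(N, C)`` (normalising over samples) and on
    feature maps ``(N, C, H, W)`` (normalising over batch and space).
    """

    def __init__(self, n_channels, eps=1e-5, momentum=0.1, dtype=np.float32):
        if eps <= 0:
            raise DegenerateInputError(f"eps must be positive, got {eps}")
        self.gamma = np.ones(n_channels, dtype=dtype)
        self.beta = np.zeros(n_channels, dtype=dtype)
        self.running_mean = np.zeros(n_channels, dtype=dtype)
        self.running_var = np.ones(n_channels, dtype=dtype)
        self.eps = eps
        self.momentum = momentum

    def __call__(self, x, training=False):
        y, _ = bn_forward(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training=training, eps=self.eps, momentum=self.momentum,
        )
        return y


def batch_normalize(x, gamma=1.0, beta=0.0, eps=1e-5):
    """One-shot training-mode batch normalisation of a per-channel batch.

    Convenience wrapper: normalises with the batch mean and biased batch
    variance, then applies the affine ``gamma``/``beta``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise DegenerateInputError("batch normalisation requires a non-empty batch")
    axes = (0,) if x.ndim <= 2 else _bn_axes(x)
    mu = x.mean(axis=axes, keepdims=True)
    var = x.var(axis=axes, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * gamma + beta
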