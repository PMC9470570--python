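"""Differentiable operations used by the network layers.

All image tensors are NCHW float64.  Convolution and pooling are written as
nine slice operations (one per kernel tap) feeding a batched matmul, which
keeps the hot loops inside numpy.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor

__all__ = [
    "relu", "sigmoid", "conv2d", "max_pool2d", "batch_norm2d",
    "upsample_nearest", "linear", "global_avg_pool", "cross_entropy_logits",
]


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0

    def bw(g):
        return (g * mask,)

    return Tensor(x.data * mask, parents=(x,), backward=bw)


def _stable_sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = _stable_sigmoid(x.data)

    def bw(g):
        return (g * s * (1.0 - s),)

    return Tensor(s, parents=(x,), backward=bw)


def _extract_patches(xp: np.ndarray, kh: int, kw: int, stride: int,
                     oh: int, ow: int) -> np.ndarray:
    """(N, C, KH, KW, OH, OW) view-copies of a padded NCHW array."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i:i + stride * oh:stride,
                                  j:j + stride * ow:stride]
    return cols


def _fold_patches(dcols: np.ndarray, in_shape, kh: int, kw: int,
                  stride: int, padding: int) -> np.ndarray:
    """Scatter-add patch gradients back to the (unpadded) input."""
    n, c, h, w = in_shape
    oh, ow = dcols.shape[-2:]
    dxp = np.zeros((n, c, h + 2 * padding, w + 2 * padding), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * oh:stride,
                j:j + stride * ow:stride] += dcols[:, :, i, j]
    if padding:
        dxp = dxp[:, :, padding:-padding, padding:-padding]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    cout, cin_g, kh, kw = weight.data.shape
    if c != cin_g * groups or cout % groups:
        raise ValueError("channel/group mismatch in conv2d")
    oh = (h + 2 * padding - kh) // stride + 1
    ow = (w + 2 * padding - kw) // stride + 1
    if oh < 1 or ow < 1:
        raise ValueError(f"conv2d output would be empty for input {h}x{w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2)) \
        if padding else x.data
    cols = _extract_patches(xp, kh, kw, stride, oh, ow)
    # (N, G, Cg*KH*KW, OH*OW) @ (G, Og, Cg*KH*KW)^T
    cols_g = cols.reshape(n, groups, (c // groups) * kh * kw, oh * ow)
    w_g = weight.data.reshape(groups, cout // groups, (c // groups) * kh * kw)
    out = np.matmul(w_g[None], cols_g).reshape(n, cout, oh, ow)
    if bias is not None:
        out = out + bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        g_g = g.reshape(n, groups, cout // groups, oh * ow)
        dw = np.einsum("ngop,ngkp->gok", g_g, cols_g).reshape(weight.data.shape)
        dcols = np.matmul(np.swapaxes(w_g, 1, 2)[None], g_g)
        dx = _fold_patches(
            dcols.reshape(n, c, kh, kw, oh, ow), x.data.shape, kh, kw,
            stride, padding)
        if bias is None:
            return dx, dw
        return dx, dw, g.sum(axis=(0, 2, 3))

    return Tensor(out, parents=parents, backward=bw)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2,
               padding: int = 1) -> Tensor:
    """Max pooling; with kernel 3, stride 2, padding 1 the output side is
    ``ceil(side / 2)`` — the downsampling convention of the backbone."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    oh = (h + 2 * padding - kernel) // stride + 1
    ow = (w + 2 * padding - kernel) // stride + 1
    if oh < 1 or ow < 1:
        raise ValueError(f"max_pool2d output would be empty for input {h}x{w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2),
                constant_values=-np.inf) if padding else x.data
    cols = _extract_patches(xp, kernel, kernel, stride, oh, ow)
    flat = cols.reshape(n, c, kernel * kernel, oh, ow)
    idx = flat.argmax(axis=2)
    out = np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]

    def bw(g):
        dcols = np.zeros_like(flat)
        np.put_along_axis(dcols, idx[:, :, None], g[:, :, None], axis=2)
        return (_fold_patches(
            dcols.reshape(n, c, kernel, kernel, oh, ow), x.data.shape,
            kernel, kernel, stride, padding),)

    return Tensor(out, parents=(x,), backward=bw)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization; running stats updated in place."""
    x = as_tensor(x)
    axes = (0, 2, 3)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def bw(g):
        dgamma = (g * xhat).sum(axis=axes)
        dbeta = g.sum(axis=axes)
        scale = (gamma.data * inv_std)[None, :, None, None]
        if training:
            dx = scale * (g - dbeta[None, :, None, None] / m
                          - xhat * dgamma[None, :, None, None] / m)
        else:
            dx = scale * g
        return dx, dgamma, dbeta

    return Tensor(out, parents=(x, gamma, beta), backward=bw)


def upsample_nearest(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Nearest-neighbour resize to an arbitrary (larger or equal) size."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    oh, ow = size
    ih = (np.arange(oh) * h) // oh
    iw = (np.arange(ow) * w) // ow
    out = x.data[:, :, ih][:, :, :, iw]

    def bw(g):
        tmp = np.zeros((w, n, c, oh), dtype=g.dtype)
        np.add.at(tmp, iw, np.moveaxis(g, 3, 0))
        dx = np.zeros((h, w, n, c), dtype=g.dtype)
        np.add.at(dx, ih, np.moveaxis(tmp, 3, 0))
        return (np.moveaxis(dx, (0, 1), (2, 3)),)

    return Tensor(out, parents=(x,), backward=bw)


def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """x (N, in) @ weight (out, in)^T + bias."""
    x = as_tensor(x)
    out = x.data @ weight.data.T
    if bias is not None:
        out = out + bias.data
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        dx = g @ weight.data
        dw = g.T @ x.data
        if bias is None:
            return dx, dw
        return dx, dw, g.sum(axis=0)

    return Tensor(out, parents=parents, backward=bw)


def global_avg_pool(x: Tensor) -> Tensor:
    """NCHW -> (N, C) spatial mean."""
    return x.mean(axis=(2, 3))


def cross_entropy_logits(logits: Tensor, labels: np.ndarray,
                         class_weights: np.ndarray | None = None) -> Tensor:
    """Mean of per-sample weighted cross-entropy losses from raw logits.

    Per sample: ``w_class * (-x_class + logsumexp(x))``; the batch reduction
    is a plain mean of the weighted per-sample terms.
    """
    logits = as_tensor(logits)
    labels = np.asarray(labels, dtype=np.intp)
    n, k = logits.data.shape
    zmax = logits.data.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(logits.data - zmax).sum(axis=1))
    per = lse - logits.data[np.arange(n), labels]
    w = np.ones(n) if class_weights is None else \
        np.asarray(class_weights, dtype=np.float64)[labels]
    loss = float((w * per).mean())

    def bw(g):
        soft = np.exp(logits.data - lse[:, None])
        soft[np.arange(n), labels] -= 1.0
        return (g * soft * (w / n)[:, None],)

    return Tensor(loss, parents=(logits,), backward=bw)
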