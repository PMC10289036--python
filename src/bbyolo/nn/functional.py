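"""Convolution, pooling, normalisation and loss primitives.

Every function accepts either a real :class:`~bbyolo.nn.tensor.Tensor`
(NCHW layout) or a :class:`Shadow` — a shape-only stand-in that propagates
output shapes and accumulates multiply-accumulate counts without touching
any pixel data.  Model profiling (parameter/FLOP counting) runs the very
same ``forward`` code on shadows, so the profile can never drift from the
computation it describes.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, _stable_sigmoid

__all__ = [
    "Shadow", "conv2d", "linear", "batch_norm", "max_pool2d",
    "global_avg_pool", "global_max_pool", "channel_mean", "channel_max",
    "upsample_nearest", "bce_with_logits",
]


class Shadow:
    """Shape-only tensor used for analytic profiling.

    ``counter['macs']`` accumulates multiply-accumulates of conv/linear
    layers; elementwise ops, pooling, BN and upsampling contribute zero,
    which matches the convention behind published detector GFLOP tables.
    """

    def __init__(self, shape, counter=None):
        self.shape = tuple(int(s) for s in shape)
        self.counter = counter if counter is not None else {"macs": 0}

    @property
    def ndim(self):
        return len(self.shape)

    def _same(self):
        return Shadow(self.shape, self.counter)

    def _broadcast(self, other):
        if isinstance(other, Shadow):
            shape = np.broadcast_shapes(self.shape, other.shape)
            return Shadow(shape, self.counter)
        return self._same()

    # elementwise / gate ops: shape-preserving, zero cost
    sigmoid = relu = silu = hswish = mish = tanh = exp = log = _same
    __add__ = __radd__ = __mul__ = __rmul__ = __sub__ = __truediv__ = _broadcast

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        n = int(np.prod(self.shape))
        shape = tuple(shape)
        if -1 in shape:
            known = int(np.prod([s for s in shape if s != -1]))
            shape = tuple(n // known if s == -1 else s for s in shape)
        return Shadow(shape, self.counter)

    def mean(self, axis=None, keepdims=False):
        return _shadow_reduce(self, axis, keepdims)

    def max(self, axis, keepdims=False):
        return _shadow_reduce(self, axis, keepdims)

    def sum(self, axis=None, keepdims=False):
        return _shadow_reduce(self, axis, keepdims)


def _shadow_reduce(s, axis, keepdims):
    if axis is None:
        return Shadow((), s.counter) if not keepdims else Shadow((1,) * s.ndim, s.counter)
    ax = (axis,) if isinstance(axis, int) else tuple(axis)
    ax = tuple(a % s.ndim for a in ax)
    shape = tuple(
        1 if i in ax else d for i, d in enumerate(s.shape) if keepdims or i not in ax
    )
    return Shadow(shape, s.counter)


def _conv_out(size, k, stride, pad, dil):
    return (size + 2 * pad - dil * (k - 1) - 1) // stride + 1


def _im2col(xp, kh, kw, stride, dil, ho, wo):
    n, c = xp.shape[:2]
    col = np.empty((n, c, kh, kw, ho, wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            col[:, :, i, j] = xp[
                :, :,
                i * dil: i * dil + (ho - 1) * stride + 1: stride,
                j * dil: j * dil + (wo - 1) * stride + 1: stride,
            ]
    return col


def conv2d(x, weight, bias=None, stride=1, padding=0, dilation=1, groups=1):
    """2-D convolution (cross-correlation), NCHW, grouped/dilated/strided.

    ``padding`` may be an int or an ``(ph, pw)`` pair (asymmetric kernels).
    """
    co, cig, kh, kw = weight.shape if not isinstance(weight, Tensor) else weight.data.shape
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    if isinstance(x, Shadow):
        n, ci, h, w = x.shape
        ho = _conv_out(h, kh, stride, ph, dilation)
        wo = _conv_out(w, kw, stride, pw, dilation)
        x.counter["macs"] += n * kh * kw * cig * co * ho * wo
        return Shadow((n, co, ho, wo), x.counter)

    n, ci, h, w = x.data.shape
    assert ci == cig * groups, f"channel mismatch: {ci} vs {cig}x{groups}"
    ho = _conv_out(h, kh, stride, ph, dilation)
    wo = _conv_out(w, kw, stride, pw, dilation)
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) \
        if ph or pw else x.data
    col = _im2col(xp, kh, kw, stride, dilation, ho, wo)
    # (n, g, cig*kh*kw, ho*wo)
    x2 = col.reshape(n, groups, cig * kh * kw, ho * wo)
    w2 = weight.data.reshape(groups, co // groups, cig * kh * kw)
    out = np.matmul(w2[None], x2).reshape(n, co, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, co, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        go = g.reshape(n, groups, co // groups, ho * wo)
        if weight.requires_grad:
            gw = np.matmul(go, x2.transpose(0, 1, 3, 2)).sum(axis=0)
            weight._accum(gw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx2 = np.matmul(w2[None].transpose(0, 1, 3, 2), go)
            gcol = gx2.reshape(n, ci, kh, kw, ho, wo)
            gxp = np.zeros((n, ci, h + 2 * ph, w + 2 * pw), dtype=x.data.dtype)
            for i in range(kh):
                for j in range(kw):
                    gxp[
                        :, :,
                        i * dilation: i * dilation + (ho - 1) * stride + 1: stride,
                        j * dilation: j * dilation + (wo - 1) * stride + 1: stride,
                    ] += gcol[:, :, i, j]
            gx = gxp[:, :, ph: ph + h, pw: pw + w] if ph or pw else gxp
            x._accum(gx)

    return Tensor._make(out, parents, backward)


def linear(x, weight, bias=None):
    """``x @ weight.T + bias`` with MAC accounting under shadows."""
    if isinstance(x, Shadow):
        out_f, in_f = weight.data.shape if isinstance(weight, Tensor) else weight.shape
        batch = int(np.prod(x.shape[:-1]))
        x.counter["macs"] += batch * in_f * out_f
        return Shadow(x.shape[:-1] + (out_f,), x.counter)
    out = x @ weight.transpose(1, 0)
    if bias is not None:
        out = out + bias
    return out


def batch_norm(x, gamma, beta, running_mean, running_var,
               training: bool, momentum: float = 0.03, eps: float = 1e-5):
    """Channel-wise batch normalisation (NCHW).

    ``running_mean``/``running_var`` are plain numpy buffers updated in
    place when ``training`` is true.
    """
    if isinstance(x, Shadow):
        return x._same()
    c = x.shape[1]
    if training:
        mu = x.mean(axis=(0, 2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu.data.reshape(c)
        running_var *= 1.0 - momentum
        running_var += momentum * var.data.reshape(c)
        inv = (var + eps) ** -0.5
        xhat = xc * inv
    else:
        inv = 1.0 / np.sqrt(running_var + eps)
        xhat = (x - running_mean.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
    return xhat * gamma.reshape(1, c, 1, 1) + beta.reshape(1, c, 1, 1)


def max_pool2d(x, kernel: int, stride: int = None, padding: int = 0):
    stride = stride or kernel
    if isinstance(x, Shadow):
        n, c, h, w = x.shape
        ho = _conv_out(h, kernel, stride, padding, 1)
        wo = _conv_out(w, kernel, stride, padding, 1)
        return Shadow((n, c, ho, wo), x.counter)
    n, c, h, w = x.data.shape
    ho = _conv_out(h, kernel, stride, padding, 1)
    wo = _conv_out(w, kernel, stride, padding, 1)
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    col = _im2col(xp, kernel, kernel, stride, 1, ho, wo)
    flat = col.reshape(n, c, kernel * kernel, ho, wo)
    idx = np.argmax(flat, axis=2)
    out = np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        if not x.requires_grad:
            return
        gcol = np.zeros_like(flat)
        np.put_along_axis(gcol, idx[:, :, None], g[:, :, None], axis=2)
        gcol = gcol.reshape(n, c, kernel, kernel, ho, wo)
        gxp = np.zeros(xp.shape, dtype=x.data.dtype)
        for i in range(kernel):
            for j in range(kernel):
                gxp[:, :, i: i + (ho - 1) * stride + 1: stride,
                    j: j + (wo - 1) * stride + 1: stride] += gcol[:, :, i, j]
        gx = gxp[:, :, padding: padding + h, padding: padding + w] if padding else gxp
        x._accum(gx)

    return Tensor._make(out, (x,), backward)


def global_avg_pool(x):
    """(N,C,H,W) -> (N,C,1,1) spatial mean."""
    if isinstance(x, Shadow):
        return Shadow(x.shape[:2] + (1, 1), x.counter)
    return x.mean(axis=(2, 3), keepdims=True)


def global_max_pool(x):
    """(N,C,H,W) -> (N,C,1,1) spatial max."""
    if isinstance(x, Shadow):
        return Shadow(x.shape[:2] + (1, 1), x.counter)
    n, c, h, w = x.shape
    return x.reshape(n, c, h * w).max(axis=2, keepdims=True).reshape(n, c, 1, 1)


def channel_mean(x):
    """(N,C,H,W) -> (N,1,H,W) mean over channels."""
    if isinstance(x, Shadow):
        return Shadow((x.shape[0], 1) + x.shape[2:], x.counter)
    return x.mean(axis=1, keepdims=True)


def channel_max(x):
    if isinstance(x, Shadow):
        return Shadow((x.shape[0], 1) + x.shape[2:], x.counter)
    return x.max(axis=1, keepdims=True)


def upsample_nearest(x, scale: int = 2):
    if isinstance(x, Shadow):
        n, c, h, w = x.shape
        return Shadow((n, c, h * scale, w * scale), x.counter)
    n, c, h, w = x.shape
    out = np.repeat(np.repeat(x.data, scale, axis=2), scale, axis=3)

    def backward(g):
        if x.requires_grad:
            gg = g.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5))
            x._accum(gg)

    return Tensor._make(out, (x,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray, reduction: str = "mean"):
    """Numerically-stable binary cross-entropy on raw logits."""
    z = np.asarray(targets, dtype=logits.data.dtype)
    x = logits.data
    loss = np.maximum(x, 0) - x * z + np.log1p(np.exp(-np.abs(x)))
    if reduction == "mean":
        out = loss.mean()
        scale = 1.0 / loss.size
    elif reduction == "sum":
        out = loss.sum()
        scale = 1.0
    else:
        raise ValueError(f"unknown reduction {reduction!r}")

    def backward(g):
        if logits.requires_grad:
            logits._accum(g * (_stable_sigmoid(x) - z) * scale)

    return Tensor._make(np.asarray(out, dtype=x.dtype), (logits,), backward)
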