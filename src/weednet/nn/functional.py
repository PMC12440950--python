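"""Differentiable operations on :class:`~weednet.nn.autograd.Tensor`.

Convolutions use an im2col lowering onto BLAS matmuls; the input
gradient is computed as a stride-dilated transposed convolution through
the same lowering, so only one fast path needs to be correct (and it is
checked against finite differences in the test suite).
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .autograd import Tensor, as_tensor, unbroadcast
from . import profile as _profile

IntPair = Union[int, Tuple[int, int]]


def _pair(v: IntPair) -> Tuple[int, int]:
    return (v, v) if isinstance(v, int) else (int(v[0]), int(v[1]))


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def backward(g):
        a.accumulate(unbroadcast(g, a.shape))
        b.accumulate(unbroadcast(g, b.shape))

    return Tensor.result(out, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data - b.data

    def backward(g):
        a.accumulate(unbroadcast(g, a.shape))
        b.accumulate(unbroadcast(-g, b.shape))

    return Tensor.result(out, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def backward(g):
        a.accumulate(unbroadcast(g * b.data, a.shape))
        b.accumulate(unbroadcast(g * a.data, b.shape))

    return Tensor.result(out, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data / b.data

    def backward(g):
        a.accumulate(unbroadcast(g / b.data, a.shape))
        b.accumulate(unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    return Tensor.result(out, (a, b), backward)


def neg(a) -> Tensor:
    a = as_tensor(a)
    return Tensor.result(-a.data, (a,), lambda g: a.accumulate(-g))


def pow_(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    out = a.data ** exponent

    def backward(g):
        a.accumulate(g * exponent * a.data ** (exponent - 1.0))

    return Tensor.result(out, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)
    return Tensor.result(out, (a,), lambda g: a.accumulate(g * out))


def log(a) -> Tensor:
    a = as_tensor(a)
    return Tensor.result(np.log(a.data), (a,), lambda g: a.accumulate(g / a.data))


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    out = np.sqrt(a.data)
    return Tensor.result(out, (a,), lambda g: a.accumulate(g * 0.5 / np.maximum(out, 1e-12)))


def arctan(a) -> Tensor:
    a = as_tensor(a)
    out = np.arctan(a.data)
    return Tensor.result(out, (a,), lambda g: a.accumulate(g / (1.0 + a.data * a.data)))


def clip(a, lo: Optional[float], hi: Optional[float]) -> Tensor:
    a = as_tensor(a)
    out = np.clip(a.data, lo, hi)
    mask = np.ones_like(a.data)
    if lo is not None:
        mask *= a.data >= lo
    if hi is not None:
        mask *= a.data <= hi

    return Tensor.result(out, (a,), lambda g: a.accumulate(g * mask))


def maximum(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = np.maximum(a.data, b.data)
    amask = a.data >= b.data

    def backward(g):
        a.accumulate(unbroadcast(g * amask, a.shape))
        b.accumulate(unbroadcast(g * (~amask), b.shape))

    return Tensor.result(out, (a, b), backward)


def minimum(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = np.minimum(a.data, b.data)
    amask = a.data <= b.data

    def backward(g):
        a.accumulate(unbroadcast(g * amask, a.shape))
        b.accumulate(unbroadcast(g * (~amask), b.shape))

    return Tensor.result(out, (a, b), backward)


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-a.data))
    return Tensor.result(out, (a,), lambda g: a.accumulate(g * out * (1.0 - out)))


def silu(a) -> Tensor:
    """x * sigmoid(x) — the activation used throughout the network."""
    a = as_tensor(a)
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-a.data))
    out = a.data * s

    def backward(g):
        a.accumulate(g * (s + a.data * s * (1.0 - s)))

    return Tensor.result(out, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    return Tensor.result(a.data * mask, (a,), lambda g: a.accumulate(g * mask))


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        a.accumulate(out * (g - dot))

    return Tensor.result(out, (a,), backward)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse
    soft = np.exp(out)

    def backward(g):
        a.accumulate(g - soft * g.sum(axis=axis, keepdims=True))

    return Tensor.result(out, (a,), backward)


# ---------------------------------------------------------------------------
# reductions & shape
# ---------------------------------------------------------------------------

def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a.accumulate(np.broadcast_to(g, a.shape))
            return
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, axes)
        a.accumulate(np.broadcast_to(g, a.shape))

    return Tensor.result(out, (a,), backward)


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out = a.data.mean(axis=axis, keepdims=keepdims)
    denom = a.size / max(out.size, 1)

    def backward(g):
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, axes)
        a.accumulate(np.broadcast_to(g, a.shape) / denom)

    return Tensor.result(out, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    return Tensor.result(
        a.data.reshape(shape), (a,), lambda g: a.accumulate(g.reshape(a.shape))
    )


def transpose(a, axes: Sequence[int]) -> Tensor:
    a = as_tensor(a)
    inv = np.argsort(axes)
    return Tensor.result(
        np.ascontiguousarray(a.data.transpose(axes)),
        (a,),
        lambda g: a.accumulate(g.transpose(inv)),
    )


def concat(tensors: Sequence, axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t.accumulate(g[tuple(idx)])

    return Tensor.result(out, ts, backward)


def getitem(a, key) -> Tensor:
    a = as_tensor(a)
    out = a.data[key]
    advanced = isinstance(key, (np.ndarray, list)) or (
        isinstance(key, tuple) and any(isinstance(k, (np.ndarray, list)) for k in key)
    )

    def backward(g):
        buf = np.zeros_like(a.data)
        if advanced:
            np.add.at(buf, key, g)
        else:
            buf[key] += g
        a.accumulate(buf)

    return Tensor.result(np.ascontiguousarray(out), (a,), backward)


def pad2d(a, pad: Tuple[int, int, int, int], value: float = 0.0) -> Tensor:
    """Pad the two trailing axes by (top, bottom, left, right)."""
    a = as_tensor(a)
    t, b, l, r = pad
    out = np.pad(
        a.data,
        [(0, 0)] * (a.ndim - 2) + [(t, b), (l, r)],
        constant_values=value,
    )

    def backward(g):
        sl = (Ellipsis, slice(t, g.shape[-2] - b), slice(l, g.shape[-1] - r))
        a.accumulate(g[sl])

    return Tensor.result(out, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = np.matmul(a.data, b.data)
    _profile.add_macs(out.size * a.data.shape[-1])

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        a.accumulate(unbroadcast(ga, a.shape))
        b.accumulate(unbroadcast(gb, b.shape))

    return Tensor.result(out, (a, b), backward)


def linear(x, w, b=None) -> Tensor:
    """x @ w.T + b with w of shape (out_features, in_features)."""
    out = matmul(x, transpose(w, (1, 0)))
    if b is not None:
        out = add(out, b)
    return out


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """(B,C,H,W) already padded -> (B, C*kh*kw, Ho*Wo)."""
    B, C, H, W = x.shape
    view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    view = view[:, :, ::sh, ::sw]  # B,C,Ho,Wo,kh,kw
    Ho, Wo = view.shape[2], view.shape[3]
    cols = view.transpose(0, 1, 4, 5, 2, 3).reshape(B, C * kh * kw, Ho * Wo)
    return np.ascontiguousarray(cols), Ho, Wo


def _conv2d_raw(
    x: np.ndarray,
    w: np.ndarray,
    stride: Tuple[int, int],
    padding: Tuple[int, int],
    groups: int,
    return_cols: bool = False,
):
    sh, sw = stride
    ph, pw = padding
    Cout, Cg, kh, kw = w.shape
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols, Ho, Wo = _im2col(x, kh, kw, sh, sw)
    B = x.shape[0]
    G = groups
    cols_g = cols.reshape(B, G, Cg * kh * kw, Ho * Wo)
    w_g = w.reshape(G, Cout // G, Cg * kh * kw)
    out = np.matmul(w_g[None], cols_g)  # (B,G,CoutG,L)
    out = out.reshape(B, Cout, Ho, Wo)
    if return_cols:
        return out, cols_g, Ho, Wo
    return out


def _depthwise_forward(xp: np.ndarray, w: np.ndarray, sh: int, sw: int) -> np.ndarray:
    """Depthwise conv as shifted multiply-adds (no im2col copy)."""
    C = w.shape[0]
    kh, kw = w.shape[2], w.shape[3]
    B, _, Hp, Wp = xp.shape
    Ho = (Hp - kh) // sh + 1
    Wo = (Wp - kw) // sw + 1
    out = np.zeros((B, C, Ho, Wo), xp.dtype)
    for dy in range(kh):
        for dx in range(kw):
            sl = xp[:, :, dy : dy + sh * Ho : sh, dx : dx + sw * Wo : sw]
            out += w[None, :, 0, dy, dx, None, None] * sl
    return out


def conv2d(
    x,
    w,
    b=None,
    stride: IntPair = 1,
    padding: IntPair = 0,
    groups: int = 1,
) -> Tensor:
    """Grouped 2-D cross-correlation, NCHW layout, weights (Cout, Cin/G, kh, kw)."""
    x, w = as_tensor(x), as_tensor(w)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    Cout, Cg, kh, kw = w.shape
    G = groups
    depthwise = Cg == 1 and G == Cout == x.shape[1]
    saved_cols = [None]
    if depthwise:
        xp = x.data
        if ph or pw:
            xp = np.pad(xp, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        out_data = _depthwise_forward(xp, w.data, sh, sw)
    else:
        xp = None
        from .autograd import is_grad_enabled

        want_cols = (
            is_grad_enabled()
            and w.requires_grad
            and x.data.size * Cg * kh * kw // max(x.shape[1], 1) * 4 < 24_000_000
        )
        if want_cols:
            out_data, cols_keep, _, _ = _conv2d_raw(
                x.data, w.data, (sh, sw), (ph, pw), G, return_cols=True
            )
            saved_cols[0] = cols_keep
        else:
            out_data = _conv2d_raw(x.data, w.data, (sh, sw), (ph, pw), G)
    _profile.add_macs(out_data.size * Cg * kh * kw)
    parents = [x, w]
    bias = None
    if b is not None:
        bias = as_tensor(b)
        out_data = out_data + bias.data.reshape(1, -1, 1, 1)
        parents.append(bias)
    B, _, H, W = x.shape
    Ho, Wo = out_data.shape[2], out_data.shape[3]

    def backward(g):
        gg = g.reshape(B, G, Cout // G, Ho * Wo)
        if bias is not None:
            bias.accumulate(g.sum(axis=(0, 2, 3)))
        if depthwise:
            xpad = x.data
            if ph or pw:
                xpad = np.pad(xpad, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
            if w.requires_grad:
                gw = np.empty_like(w.data)
                for dy in range(kh):
                    for dx in range(kw):
                        sl = xpad[:, :, dy : dy + sh * Ho : sh, dx : dx + sw * Wo : sw]
                        gw[:, 0, dy, dx] = (sl * g).sum(axis=(0, 2, 3))
                w.accumulate(gw)
            if x.requires_grad:
                gxp = np.zeros_like(xpad)
                for dy in range(kh):
                    for dx in range(kw):
                        gxp[:, :, dy : dy + sh * Ho : sh, dx : dx + sw * Wo : sw] += (
                            w.data[None, :, 0, dy, dx, None, None] * g
                        )
                if ph or pw:
                    gxp = gxp[:, :, ph : gxp.shape[2] - ph, pw : gxp.shape[3] - pw]
                x.accumulate(gxp)
            return
        if w.requires_grad:
            cols_g = saved_cols[0]
            if cols_g is None:
                xp2 = x.data
                if ph or pw:
                    xp2 = np.pad(xp2, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
                cols, _, _ = _im2col(xp2, kh, kw, sh, sw)
                cols_g = cols.reshape(B, G, Cg * kh * kw, Ho * Wo)
            else:
                saved_cols[0] = None
            gw = np.matmul(gg, cols_g.transpose(0, 1, 3, 2)).sum(axis=0)
            w.accumulate(gw.reshape(w.shape))
        if x.requires_grad:
            # transposed convolution: dilate the gradient by the stride,
            # convolve with the spatially-flipped, channel-swapped kernel
            eh = (H + 2 * ph - kh) % sh
            ew = (W + 2 * pw - kw) % sw
            dil = np.zeros(
                (B, Cout, sh * (Ho - 1) + 1 + eh, sw * (Wo - 1) + 1 + ew),
                dtype=g.dtype,
            )
            dil[:, :, 0 : sh * (Ho - 1) + 1 : sh, 0 : sw * (Wo - 1) + 1 : sw] = g
            wt = w.data.reshape(G, Cout // G, Cg, kh, kw)
            wt = wt.transpose(0, 2, 1, 3, 4)[:, :, :, ::-1, ::-1]
            wt = np.ascontiguousarray(wt.reshape(G * Cg, Cout // G, kh, kw))
            gx = _conv2d_raw(dil, wt, (1, 1), (kh - 1 - ph, kw - 1 - pw), G)
            x.accumulate(gx)

    return Tensor.result(out_data, parents, backward)


def max_pool2d(x, kernel: IntPair, stride: IntPair = 1, padding: IntPair = 0) -> Tensor:
    x = as_tensor(x)
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    xp = x.data
    if ph or pw:
        xp = np.pad(xp, ((0, 0), (0, 0), (ph, ph), (pw, pw)), constant_values=-np.inf)
    B, C, Hp, Wp = xp.shape
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    view = view[:, :, ::sh, ::sw]
    Ho, Wo = view.shape[2], view.shape[3]
    flat = view.reshape(B, C, Ho, Wo, kh * kw)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        buf = np.zeros((B, C, Hp, Wp), dtype=g.dtype)
        ho, wo = np.meshgrid(np.arange(Ho), np.arange(Wo), indexing="ij")
        hi = ho[None, None] * sh + arg // kw
        wi = wo[None, None] * sw + arg % kw
        bi = np.arange(B)[:, None, None, None]
        ci = np.arange(C)[None, :, None, None]
        np.add.at(buf, (bi, ci, hi, wi), g)
        if ph or pw:
            buf = buf[:, :, ph : Hp - ph, pw : Wp - pw]
        x.accumulate(buf)

    return Tensor.result(np.ascontiguousarray(out), (x,), backward)


def avg_pool2d(x, kernel: int) -> Tensor:
    """Non-overlapping average pooling (kernel == stride), exact-fit input."""
    x = as_tensor(x)
    k = int(kernel)
    B, C, H, W = x.shape
    if H % k or W % k:
        raise ValueError(f"avg_pool2d: {H}x{W} not divisible by kernel {k}")
    out = x.data.reshape(B, C, H // k, k, W // k, k).mean(axis=(3, 5))

    def backward(g):
        gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        x.accumulate(gx)

    return Tensor.result(out, (x,), backward)


def interpolate_bilinear(x, size: Tuple[int, int]) -> Tensor:
    """Bilinear resize (align_corners=False, half-pixel centers)."""
    x = as_tensor(x)
    B, C, H, W = x.shape
    Ho, Wo = size

    def src_idx(n_out, n_in):
        s = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
        s = np.clip(s, 0, n_in - 1)
        i0 = np.floor(s).astype(np.int64)
        i1 = np.minimum(i0 + 1, n_in - 1)
        frac = (s - i0).astype(np.float32)
        return i0, i1, frac

    h0, h1, fh = src_idx(Ho, H)
    w0, w1, fw = src_idx(Wo, W)
    fh = fh[:, None]
    fw = fw[None, :]
    tl = x.data[:, :, h0][:, :, :, w0]
    tr = x.data[:, :, h0][:, :, :, w1]
    bl = x.data[:, :, h1][:, :, :, w0]
    br = x.data[:, :, h1][:, :, :, w1]
    out = (
        tl * (1 - fh) * (1 - fw)
        + tr * (1 - fh) * fw
        + bl * fh * (1 - fw)
        + br * fh * fw
    ).astype(x.dtype)

    def backward(g):
        buf = np.zeros_like(x.data)
        hh0 = h0[:, None]
        hh1 = h1[:, None]
        ww0 = w0[None, :]
        ww1 = w1[None, :]
        np.add.at(buf, (slice(None), slice(None), hh0, ww0), g * (1 - fh) * (1 - fw))
        np.add.at(buf, (slice(None), slice(None), hh0, ww1), g * (1 - fh) * fw)
        np.add.at(buf, (slice(None), slice(None), hh1, ww0), g * fh * (1 - fw))
        np.add.at(buf, (slice(None), slice(None), hh1, ww1), g * fh * fw)
        x.accumulate(buf)

    return Tensor.result(out, (x,), backward)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def batch_norm2d(
    x,
    gamma,
    beta,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.03,
    eps: float = 1e-3,
) -> Tensor:
    x = as_tensor(x)
    gamma, beta = as_tensor(gamma), as_tensor(beta)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
    out = xhat * gamma.data.reshape(1, -1, 1, 1) + beta.data.reshape(1, -1, 1, 1)

    def backward(g):
        beta.accumulate(g.sum(axis=(0, 2, 3)))
        gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = g * gamma.data.reshape(1, -1, 1, 1)
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                gmean = gi.mean(axis=(0, 2, 3), keepdims=True)
                gdot = (gi * xhat).mean(axis=(0, 2, 3), keepdims=True)
                gx = (gi - gmean - xhat * gdot) * inv.reshape(1, -1, 1, 1)
            else:
                gx = gi * inv.reshape(1, -1, 1, 1)
            x.accumulate(gx.astype(x.dtype))

    return Tensor.result(out.astype(np.float32), (x, gamma, beta), backward)


def layer_norm(x, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis."""
    x = as_tensor(x)
    gamma, beta = as_tensor(gamma), as_tensor(beta)
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = xhat * gamma.data + beta.data

    def backward(g):
        beta.accumulate(unbroadcast(g, beta.shape))
        gamma.accumulate(unbroadcast(g * xhat, gamma.shape))
        if x.requires_grad:
            gi = g * gamma.data
            gmean = gi.mean(axis=-1, keepdims=True)
            gdot = (gi * xhat).mean(axis=-1, keepdims=True)
            x.accumulate(((gi - gmean - xhat * gdot) * inv).astype(x.dtype))

    return Tensor.result(out.astype(np.float32), (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def bce_with_logits(logits, targets, reduction: str = "mean") -> Tensor:
    """Numerically-stable binary cross-entropy on raw scores."""
    logits = as_tensor(logits)
    t = targets.data if isinstance(targets, Tensor) else np.asarray(targets, np.float32)
    x = logits.data
    with np.errstate(over="ignore"):
        loss = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
        s = 1.0 / (1.0 + np.exp(-x))

    if reduction == "none":
        def backward(g):
            logits.accumulate(g * (s - t))

        return Tensor.result(loss, (logits,), backward)
    if reduction == "sum":
        def backward(g):
            logits.accumulate(g * (s - t))

        return Tensor.result(loss.sum(), (logits,), backward)

    n = loss.size

    def backward(g):
        logits.accumulate(g * (s - t) / n)

    return Tensor.result(loss.mean(), (logits,), backward)


# operator bindings ---------------------------------------------------------

def _bind_operators():
    Tensor.__add__ = lambda self, o: add(self, o)
    Tensor.__radd__ = lambda self, o: add(o, self)
    Tensor.__sub__ = lambda self, o: sub(self, o)
    Tensor.__rsub__ = lambda self, o: sub(o, self)
    Tensor.__mul__ = lambda self, o: mul(self, o)
    Tensor.__rmul__ = lambda self, o: mul(o, self)
    Tensor.__truediv__ = lambda self, o: div(self, o)
    Tensor.__rtruediv__ = lambda self, o: div(o, self)
    Tensor.__neg__ = lambda self: neg(self)
    Tensor.__pow__ = lambda self, e: pow_(self, e)
    Tensor.__getitem__ = lambda self, key: getitem(self, key)
    Tensor.reshape = lambda self, *shape: reshape(
        self, shape[0] if len(shape) == 1 and isinstance(shape[0], (tuple, list)) else shape
    )
    Tensor.transpose = lambda self, *axes: transpose(
        self, axes[0] if len(axes) == 1 and isinstance(axes[0], (tuple, list)) else axes
    )
    Tensor.sum = lambda self, axis=None, keepdims=False: sum_(self, axis, keepdims)
    Tensor.mean = lambda self, axis=None, keepdims=False: mean(self, axis, keepdims)


_bind_operators()
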