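"""Differentiable array operations.

Convolution is im2col + GEMM: patches are gathered into a
(N, Cin*k*k, H*W) tensor (one fused pass, JIT-compiled when numba is
available) and contracted with batched matmuls for the forward, weight
and input gradients — the input gradient being a transposed convolution.
Resizing (bilinear/nearest) is expressed as two small dense interpolation
matrices, so its backward pass is also just matmuls.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .tensor import Tensor, accumulate_grad, astensor, make_op, unbroadcast

try:  # optional JIT for the patch gather (the memory-bound hot spot)
    from numba import njit as _njit

    @_njit(cache=True)
    def _gather_patches(x, cols6, kh, kw, d, ph, pw):
        n, cin, h, w = x.shape
        for b in range(n):
            for c in range(cin):
                for i in range(kh):
                    oy = i * d - ph
                    for j in range(kw):
                        ox = j * d - pw
                        for p in range(h):
                            sp = p + oy
                            if sp < 0 or sp >= h:
                                for q in range(w):
                                    cols6[b, c, i, j, p, q] = 0.0
                            else:
                                for q in range(w):
                                    sq = q + ox
                                    if 0 <= sq < w:
                                        cols6[b, c, i, j, p, q] = x[b, c, sp, sq]
                                    else:
                                        cols6[b, c, i, j, p, q] = 0.0

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is present in supported envs
    _HAVE_NUMBA = False

# --------------------------------------------------------------------------
# elementwise / reductions
# --------------------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)

    def backward(g):
        accumulate_grad(a, unbroadcast(g, a.shape))
        accumulate_grad(b, unbroadcast(g, b.shape))

    return make_op(a.data + b.data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)

    def backward(g):
        accumulate_grad(a, unbroadcast(g, a.shape))
        accumulate_grad(b, unbroadcast(-g, b.shape))

    return make_op(a.data - b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)

    def backward(g):
        accumulate_grad(a, unbroadcast(g * b.data, a.shape), own=True)
        accumulate_grad(b, unbroadcast(g * a.data, b.shape), own=True)

    return make_op(a.data * b.data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)

    def backward(g):
        accumulate_grad(a, unbroadcast(g / b.data, a.shape))
        accumulate_grad(b, unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    return make_op(a.data / b.data, (a, b), backward)


def relu(x) -> Tensor:
    x = astensor(x)
    mask = x.data > 0

    def backward(g):
        accumulate_grad(x, g * mask, own=True)

    return make_op(np.maximum(x.data, 0), (x,), backward)


def sigmoid(x) -> Tensor:
    x = astensor(x)
    s = expit(x.data)

    def backward(g):
        accumulate_grad(x, g * s * (1.0 - s), own=True)

    return make_op(s, (x,), backward)


def tsum(x, axis=None, keepdims: bool = False) -> Tensor:
    x = astensor(x)
    y = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            accumulate_grad(x, np.broadcast_to(g, x.shape))
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            accumulate_grad(x, np.broadcast_to(g, x.shape))

    return make_op(y, (x,), backward)


def tmean(x, axis=None, keepdims: bool = False) -> Tensor:
    x = astensor(x)
    n = x.size if axis is None else np.prod([x.shape[a] for a in np.atleast_1d(axis)])
    return mul(tsum(x, axis=axis, keepdims=keepdims), 1.0 / float(n))


def tmax(x, axis, keepdims: bool = False) -> Tensor:
    """Max over axes; gradient is split evenly among ties."""
    x = astensor(x)
    y = x.data.max(axis=axis, keepdims=True)
    mask = x.data == y
    counts = mask.sum(axis=axis, keepdims=True)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        accumulate_grad(x, mask * (g / counts))

    out = y if keepdims else np.squeeze(y, axis=axis)
    return make_op(out, (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            accumulate_grad(t, g[tuple(idx)])

    return make_op(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def reshape(x, shape) -> Tensor:
    x = astensor(x)

    def backward(g):
        accumulate_grad(x, g.reshape(x.shape))

    return make_op(x.data.reshape(shape), (x,), backward)


# --------------------------------------------------------------------------
# dense / convolution
# --------------------------------------------------------------------------


def linear(x, w, b=None) -> Tensor:
    """x: (N, Cin), w: (Cout, Cin), b: (Cout,)."""
    x, w = astensor(x), astensor(w)
    y = x.data @ w.data.T
    parents = [x, w]
    if b is not None:
        b = astensor(b)
        parents.append(b)
        y = y + b.data

    def backward(g):
        accumulate_grad(x, g @ w.data)
        accumulate_grad(w, g.T @ x.data)
        if b is not None:
            accumulate_grad(b, g.sum(axis=0))

    return make_op(y, tuple(parents), backward)


def _im2col(x: np.ndarray, kh: int, kw: int, d: int) -> np.ndarray:
    """Patch tensor (N, Cin*kh*kw, H*W) for a stride-1 'same' convolution.

    Built by one aligned copy per kernel tap, so every copy is a strided
    memcpy — much cheaper than transposing a 6-D window view.
    """
    n, cin, h, w = x.shape
    ph, pw = ((kh - 1) * d) // 2, ((kw - 1) * d) // 2
    cols = np.empty((n, cin, kh, kw, h, w), dtype=x.dtype)
    if _HAVE_NUMBA:
        _gather_patches(x, cols, kh, kw, d, ph, pw)
    else:
        xp = np.empty((n, cin, h + 2 * ph, w + 2 * pw), dtype=x.dtype)
        xp[:, :, :ph, :] = 0
        xp[:, :, ph + h:, :] = 0
        xp[:, :, :, :pw] = 0
        xp[:, :, :, pw + w:] = 0
        xp[:, :, ph:ph + h, pw:pw + w] = x
        for i in range(kh):
            for j in range(kw):
                cols[:, :, i, j] = xp[:, :, i * d:i * d + h, j * d:j * d + w]
    return cols.reshape(n, cin * kh * kw, h * w)


def _conv_raw(x: np.ndarray, w: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    """GEMM-based stride-1 'same' convolution; returns (y, patch tensor)."""
    n, cin, h, wd = x.shape
    cout, _, kh, kw = w.shape
    cols = _im2col(x, kh, kw, d)
    y = np.matmul(w.reshape(cout, -1), cols)  # (N, Cout, H*W)
    return y.reshape(n, cout, h, wd), cols


def conv2d(x, w, b=None, dilation: int = 1) -> Tensor:
    """2-D convolution, stride 1, zero 'same' padding, square dilation.

    x: (N, Cin, H, W); w: (Cout, Cin, kh, kw) with odd kh == kw.
    Output spatial extents equal the input's.  The input gradient is the
    transposed convolution (channel-swapped, 180deg-rotated kernel).
    """
    x, w = astensor(x), astensor(w)
    n, cin, h, wd = x.shape
    cout, cin_w, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"conv2d: input has {cin} channels, weight expects {cin_w}")
    d = int(dilation)
    y, cols = _conv_raw(x.data, w.data, d)
    parents = [x, w]
    if b is not None:
        b = astensor(b)
        parents.append(b)
        y += b.data.reshape(1, -1, 1, 1)

    def backward(g):
        g3 = np.ascontiguousarray(g).reshape(n, cout, h * wd)
        # batched GEMM (BLAS handles the transposed operand without a copy)
        gw = np.matmul(g3, cols.transpose(0, 2, 1)).sum(axis=0)
        accumulate_grad(w, gw.reshape(cout, cin, kh, kw), own=True)
        if b is not None:
            accumulate_grad(b, g3.sum(axis=(0, 2)))
        if x.requires_grad:
            w_flip = np.ascontiguousarray(w.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
            gx, _ = _conv_raw(g3.reshape(n, cout, h, wd), w_flip, d)
            accumulate_grad(x, gx, own=True)

    return make_op(y, tuple(parents), backward)


# --------------------------------------------------------------------------
# pooling / resampling
# --------------------------------------------------------------------------


def max_pool2d(x) -> Tensor:
    """2x2 max pooling, stride 2 (extents must be even)."""
    x = astensor(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2d: extents ({h}, {w}) must be even")
    view = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    y = view.max(axis=(3, 5))
    mask = view == y[:, :, :, None, :, None]
    counts = mask.sum(axis=(3, 5), keepdims=True)

    def backward(g):
        gx = mask * (g[:, :, :, None, :, None] / counts)
        accumulate_grad(x, gx.reshape(n, c, h, w))

    return make_op(y, (x,), backward)


def avg_pool2d(x) -> Tensor:
    """2x2 average pooling, stride 2 (extents must be even)."""
    x = astensor(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"avg_pool2d: extents ({h}, {w}) must be even")
    view = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    y = view.mean(axis=(3, 5))

    def backward(g):
        gx = np.broadcast_to(g[:, :, :, None, :, None] * 0.25, view.shape)
        accumulate_grad(x, gx.reshape(n, c, h, w))

    return make_op(y, (x,), backward)


def global_avg_pool(x) -> Tensor:
    return tmean(x, axis=(2, 3), keepdims=True)


def global_max_pool(x) -> Tensor:
    return tmax(x, axis=(2, 3), keepdims=True)


def channel_mean(x) -> Tensor:
    return tmean(x, axis=1, keepdims=True)


def channel_max(x) -> Tensor:
    return tmax(x, axis=1, keepdims=True)


def _interp_matrix(n_in: int, n_out: int, mode: str, dtype) -> np.ndarray:
    """Dense (n_out, n_in) 1-D interpolation operator (half-pixel centers)."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    if mode == "nearest":
        src = np.floor(np.arange(n_out) * (n_in / n_out)).astype(int)
        m[np.arange(n_out), np.clip(src, 0, n_in - 1)] = 1.0
    elif mode == "bilinear":
        src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
        src = np.clip(src, 0.0, n_in - 1.0)
        i0 = np.floor(src).astype(int)
        i1 = np.minimum(i0 + 1, n_in - 1)
        frac = src - i0
        m[np.arange(n_out), i0] += 1.0 - frac
        m[np.arange(n_out), i1] += frac
    else:
        raise ValueError(f"unknown resize mode {mode!r}")
    return m


def resize(x, size: tuple[int, int], mode: str = "bilinear") -> Tensor:
    """Resize (N, C, H, W) to spatial ``size`` by separable interpolation."""
    x = astensor(x)
    h, w = x.shape[2], x.shape[3]
    oh, ow = size
    if (oh, ow) == (h, w):
        return x
    ry = _interp_matrix(h, oh, mode, x.dtype)  # (oh, h)
    cx = _interp_matrix(w, ow, mode, x.dtype)  # (ow, w)
    y = np.matmul(ry, np.matmul(x.data, cx.T))

    def backward(g):
        accumulate_grad(x, np.matmul(ry.T, np.matmul(g, cx)), own=True)

    return make_op(y, (x,), backward)


def upsample2x(x, mode: str = "bilinear") -> Tensor:
    return resize(x, (2 * x.shape[2], 2 * x.shape[3]), mode=mode)


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------


def batch_norm(x, gamma, beta, running_mean, running_var, training: bool,
               momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    ``running_mean``/``running_var`` are plain arrays mutated in place
    during training (exponential moving average, biased variance).
    """
    x = astensor(x)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    std = np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, -1, 1, 1)) / std.reshape(1, -1, 1, 1)
    y = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

    def backward(g):
        accumulate_grad(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        accumulate_grad(beta, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = gamma.data.reshape(1, -1, 1, 1) / std.reshape(1, -1, 1, 1)
            if training:
                m = x.shape[0] * x.shape[2] * x.shape[3]
                sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
                sum_gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
                accumulate_grad(x, gs * (g - sum_g / m - xhat * sum_gx / m), own=True)
            else:
                accumulate_grad(x, gs * g, own=True)

    return make_op(y, (x, gamma, beta), backward)
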