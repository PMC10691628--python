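"""Spatial operators (stride-1 'same' convolution, pooling, resampling).

All feature maps are channels-first ``(N, C, H, W)``.  Convolution is
implemented by im2col + BLAS matmul; the transposed 2x2/stride-2 convolution
used by the decoder exploits the non-overlapping kernel so forward and
backward are plain einsums.  Adaptive average pooling and bilinear
resampling are expressed as separable linear maps ``y = A x B^T`` acting on
the last two axes, which makes their adjoints (the backward passes)
``A^T y B``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .autograd import Tensor, accumulate, make_node

__all__ = [
    "conv2d",
    "conv_transpose2x",
    "max_pool2d",
    "max_pool_same3",
    "adaptive_avg_pool2d",
    "upsample_bilinear",
    "global_avg_pool",
    "batch_norm2d",
]


def _im2col(x: np.ndarray, kh: int, kw: int, ph: int, pw: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*kh*kw, H*W) patches for stride-1 'same' conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = np.empty((n, c, kh, kw, h, w), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + h, j : j + w]
    return cols.reshape(n, c * kh * kw, h * w)


def _col2im(cols: np.ndarray, shape: tuple, kh: int, kw: int, ph: int, pw: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    n, c, h, w = shape
    cols = cols.reshape(n, c, kh, kw, h, w)
    xp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + h, j : j + w] += cols[:, :, i, j]
    if ph or pw:
        return xp[:, :, ph : ph + h, pw : pw + w]
    return xp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1 'same'-padded convolution; ``w`` has shape (O, C, kh, kw)."""
    n, c, h, wd = x.shape
    o, ci, kh, kw = w.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {ci}")
    ph, pw = kh // 2, kw // 2
    cols = _im2col(x.data, kh, kw, ph, pw)  # (N, K, P)
    wm = w.data.reshape(o, -1)  # (O, K)
    out = np.matmul(wm, cols)  # (N, O, P)
    if b is not None:
        out = out + b.data[:, None]
    out = out.reshape(n, o, h, wd)

    def backward(g):
        gm = g.reshape(n, o, h * wd)
        accumulate(w, np.einsum("nop,nkp->ok", gm, cols).reshape(w.shape))
        if b is not None:
            accumulate(b, gm.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = np.matmul(wm.T, gm)  # (N, K, P)
            accumulate(x, _col2im(dcols, x.shape, kh, kw, ph, pw))

    parents = (x, w) if b is None else (x, w, b)
    return make_node(out, parents, backward)


def conv_transpose2x(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2x2, stride 2 (exact 2x upsampling).

    ``w`` has shape (C_in, O, 2, 2); output is (N, O, 2H, 2W).
    """
    n, c, h, wd = x.shape
    out6 = np.einsum("nchw,coab->nohawb", x.data, w.data)
    out = out6.reshape(n, w.shape[1], 2 * h, 2 * wd)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def backward(g):
        g6 = g.reshape(n, w.shape[1], h, 2, wd, 2)
        accumulate(w, np.einsum("nchw,nohawb->coab", x.data, g6))
        if b is not None:
            accumulate(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            accumulate(x, np.einsum("nohawb,coab->nchw", g6, w.data))

    parents = (x, w) if b is None else (x, w, b)
    return make_node(out, parents, backward)


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (H, W must be even)."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("max_pool2d requires even spatial dimensions")
    windows = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    windows = windows.reshape(n, c, h // 2, w // 2, 4)
    arg = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        dw = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(dw, arg[..., None], g[..., None], axis=-1)
        dx = dw.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        accumulate(x, dx)

    return make_node(out, (x,), backward)


def max_pool_same3(x: Tensor) -> Tensor:
    """3x3 max pooling, stride 1, 'same' padding (Inception pooling branch)."""
    n, c, h, w = x.shape
    neg = np.finfo(x.dtype).min
    xp = np.full((n, c, h + 2, w + 2), neg, dtype=x.dtype)
    xp[:, :, 1 : 1 + h, 1 : 1 + w] = x.data
    stack = np.empty((9, n, c, h, w), dtype=x.dtype)
    for k, (i, j) in enumerate((i, j) for i in range(3) for j in range(3)):
        stack[k] = xp[:, :, i : i + h, j : j + w]
    arg = stack.argmax(axis=0)
    out = np.take_along_axis(stack, arg[None], axis=0)[0]

    def backward(g):
        gp = np.zeros((n, c, h + 2, w + 2), dtype=g.dtype)
        for k, (i, j) in enumerate((i, j) for i in range(3) for j in range(3)):
            mask = arg == k
            if mask.any():
                np.add.at(gp[:, :, i : i + h, j : j + w], np.nonzero(mask), g[mask])
        accumulate(x, gp[:, :, 1 : 1 + h, 1 : 1 + w])

    return make_node(out, (x,), backward)


@lru_cache(maxsize=None)
def _avg_pool_matrix(n_in: int, n_out: int, dtype_str: str) -> np.ndarray:
    """Adaptive averaging matrix (n_out, n_in): bin i covers
    [floor(i*n_in/n_out), ceil((i+1)*n_in/n_out))."""
    m = np.zeros((n_out, n_in), dtype=np.dtype(dtype_str))
    for i in range(n_out):
        lo = (i * n_in) // n_out
        hi = -(-((i + 1) * n_in) // n_out)  # ceil
        m[i, lo:hi] = 1.0 / (hi - lo)
    return m


@lru_cache(maxsize=None)
def _bilinear_matrix(n_in: int, n_out: int, dtype_str: str) -> np.ndarray:
    """Bilinear interpolation matrix (n_out, n_in), half-pixel-centre aligned."""
    m = np.zeros((n_out, n_in), dtype=np.dtype(dtype_str))
    for i in range(n_out):
        src = (i + 0.5) * n_in / n_out - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n_in - 1)
        frac = src - i0
        m[i, i0] += 1.0 - frac
        m[i, i1] += frac
    return m


def _linresize(x: Tensor, a_rows: np.ndarray, a_cols: np.ndarray) -> Tensor:
    """Separable linear resample ``y[.., i, j] = sum A[i,h] x[.., h, w] B[j,w]``."""
    tmp = np.matmul(a_rows, x.data)  # (N, C, out_h, W)
    out = np.matmul(tmp, a_cols.T)  # (N, C, out_h, out_w)

    def backward(g):
        accumulate(x, np.matmul(a_rows.T, np.matmul(g, a_cols)))

    return make_node(out, (x,), backward)


def adaptive_avg_pool2d(x: Tensor, out_hw: tuple[int, int] | int) -> Tensor:
    if isinstance(out_hw, int):
        out_hw = (out_hw, out_hw)
    h, w = x.shape[2], x.shape[3]
    ds = str(x.dtype)
    return _linresize(x, _avg_pool_matrix(h, out_hw[0], ds), _avg_pool_matrix(w, out_hw[1], ds))


def upsample_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    h, w = x.shape[2], x.shape[3]
    ds = str(x.dtype)
    return _linresize(x, _bilinear_matrix(h, out_hw[0], ds), _bilinear_matrix(w, out_hw[1], ds))


def global_avg_pool(x: Tensor) -> Tensor:
    """Squeeze step: spatial mean per channel, (N, C, H, W) -> (N, C)."""
    n, c, h, w = x.shape
    out = x.data.mean(axis=(2, 3))

    def backward(g):
        accumulate(x, np.broadcast_to(g[:, :, None, None] / (h * w), x.shape).astype(g.dtype, copy=True))

    return make_node(out, (x,), backward)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalisation over (N, H, W) per channel, with running statistics.

    ``running_mean``/``running_var`` are updated in place in training mode.
    """
    n, c, h, w = x.shape
    m = n * h * w
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var * (m / max(m - 1, 1))  # unbiased for inference
    else:
        mu = running_mean
        var = running_var
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * ivar[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        accumulate(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        accumulate(beta, g.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        dxhat = g * gamma.data[None, :, None, None]
        if training:
            s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            dx = (ivar[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        else:
            dx = dxhat * ivar[None, :, None, None]
        accumulate(x, dx.astype(g.dtype, copy=False))

    return make_node(out, (x, gamma, beta), backward)
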