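"""Spatial operators (NCHW convolution, pooling, bilinear resampling)."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = ["conv2d", "max_pool2d", "upsample_bilinear", "global_avg_pool"]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # (n, c, ho, wo, kh, kw) -> (n, ho*wo, c*kh*kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    xp = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                cols[:, :, :, :, i, j]
    if pad:
        xp = xp[:, :, pad:pad + h, pad:pad + w]
    return xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation, ``x`` (N,C,H,W), ``weight`` (F, C/groups, kh, kw)."""
    n, c, h, w = x.shape
    f, cg, kh, kw = weight.shape
    if c != cg * groups or f % groups:
        raise ValueError(
            f"channel mismatch: input has {c} channels, weight expects "
            f"{cg * groups} (groups={groups})")
    fg = f // groups
    outs = []
    cols_cache = []
    for g in range(groups):
        xg = x.data[:, g * cg:(g + 1) * cg]
        cols, ho, wo = _im2col(xg, kh, kw, stride, padding)
        cols_cache.append(cols)
        wg = weight.data[g * fg:(g + 1) * fg].reshape(fg, cg * kh * kw)
        outs.append(cols @ wg.T)  # (n, ho*wo, fg)
    out_data = np.concatenate(outs, axis=2).transpose(0, 2, 1).reshape(n, f, ho, wo)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, f, 1, 1)

    def backward(g):
        gl = g.reshape(n, f, ho * wo).transpose(0, 2, 1)  # (n, L, f)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad or x.requires_grad:
            gw = np.empty_like(weight.data) if weight.requires_grad else None
            gx = np.empty((n, c, h, w)) if x.requires_grad else None
            for gi in range(groups):
                gg = gl[:, :, gi * fg:(gi + 1) * fg]  # (n, L, fg)
                wg = weight.data[gi * fg:(gi + 1) * fg].reshape(fg, cg * kh * kw)
                if gw is not None:
                    gw[gi * fg:(gi + 1) * fg] = np.einsum(
                        "nlf,nlk->fk", gg, cols_cache[gi]).reshape(fg, cg, kh, kw)
                if gx is not None:
                    gcols = gg @ wg  # (n, L, cg*kh*kw)
                    gx[:, gi * cg:(gi + 1) * cg] = _col2im(
                        gcols, (n, cg, h, w), kh, kw, stride, padding)
            if gw is not None:
                weight._accum(gw)
            if gx is not None:
                x._accum(gx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out_data, parents, backward)


def max_pool2d(x: Tensor, kernel: int = 2) -> Tensor:
    n, c, h, w = x.shape
    if h % kernel or w % kernel:
        raise ValueError(f"spatial size {h}x{w} not divisible by pool {kernel}")
    ho, wo = h // kernel, w // kernel
    win = x.data.reshape(n, c, ho, kernel, wo, kernel) \
        .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, kernel * kernel)
    idx = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gwin = np.zeros((n, c, ho, wo, kernel * kernel))
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = gwin.reshape(n, c, ho, wo, kernel, kernel) \
            .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accum(gx)

    return Tensor._make(out_data, (x,), backward)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic linear-interpolation matrix (align-corners mapping)."""
    mat = np.zeros((n_out, n_in))
    if n_out == 1 or n_in == 1:
        mat[:, 0] = 1.0
        return mat
    src = np.arange(n_out) * (n_in - 1) / (n_out - 1)
    lo = np.minimum(src.astype(int), n_in - 2)
    frac = src - lo
    mat[np.arange(n_out), lo] += 1.0 - frac
    mat[np.arange(n_out), lo + 1] += frac
    return mat


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resampling of (N,C,H,W) to spatial ``size`` (align corners)."""
    h_out, w_out = size
    n, c, h, w = x.shape
    if (h_out, w_out) == (h, w):
        return x
    a = _interp_matrix(h_out, h)
    b = _interp_matrix(w_out, w)
    out_data = np.einsum("oh,nchw,pw->ncop", a, x.data, b, optimize=True)

    def backward(g):
        x._accum(np.einsum("oh,ncop,pw->nchw", a, g, b, optimize=True))

    return Tensor._make(out_data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C) spatial mean."""
    return x.mean(axis=(2, 3))
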