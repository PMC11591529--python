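"""Convolution and pooling primitives (im2col based)."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = ["conv2d", "conv_transpose2d", "max_pool2d"]


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    # (B, C, Ho, Wo, kh, kw) view on the padded input
    cols = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return cols[:, :, ::stride, ::stride]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation. ``w``: (F, C, kh, kw), ``b``: (F,)."""
    B, C, H, W = x.shape
    F, Cw, kh, kw = w.shape
    if C != Cw:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = _im2col(xp, kh, kw, stride)  # B,C,Ho,Wo,kh,kw
    Ho, Wo = cols.shape[2], cols.shape[3]
    cols2 = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * Ho * Wo, C * kh * kw
    )
    wf = w.data.reshape(F, C * kh * kw)
    out = (cols2 @ wf.T).reshape(B, Ho, Wo, F).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data.reshape(1, F, 1, 1)
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    if not req:
        return Tensor(out)

    def bwd(g):
        gf = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * Ho * Wo, F)
        gw = (gf.T @ cols2).reshape(F, C, kh, kw) if w.requires_grad else None
        gb = g.sum(axis=(0, 2, 3)) if (b is not None and b.requires_grad) else None
        gx = None
        if x.requires_grad:
            gcols = (gf @ wf).reshape(B, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += (
                        gcols[:, :, :, :, i, j]
                    )
            gx = gxp[:, :, padding : padding + H, padding : padding + W]
        parents_grads = [gx, gw]
        if b is not None:
            parents_grads.append(gb)
        return tuple(parents_grads)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, True, parents, bwd)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 2) -> Tensor:
    """Transposed convolution with kernel size equal to stride (no overlap).

    ``w``: (C_in, C_out, k, k); output spatial size = input * stride. This is
    the 2x2-deconvolution-by-stride-2 upsampling used by the decoder.
    """
    B, C, H, W = x.shape
    Cin, F, kh, kw = w.shape
    if C != Cin:
        raise ValueError(f"conv_transpose2d channel mismatch: input {C}, weight {Cin}")
    if kh != stride or kw != stride:
        raise ValueError("conv_transpose2d supports kernel size == stride only")
    xf = np.ascontiguousarray(x.data.transpose(0, 2, 3, 1)).reshape(B * H * W, C)
    wf = w.data.reshape(C, F * kh * kw)
    pieces = (xf @ wf).reshape(B, H, W, F, kh, kw)
    out = np.zeros((B, F, H * stride, W * stride), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i::stride, j::stride] = pieces[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data.reshape(1, F, 1, 1)
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    if not req:
        return Tensor(out)

    def bwd(g):
        gp = np.empty((B, H, W, F, kh, kw), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                gp[:, :, :, :, i, j] = g[:, :, i::stride, j::stride].transpose(0, 2, 3, 1)
        gpf = gp.reshape(B * H * W, F * kh * kw)
        gx = (gpf @ wf.T).reshape(B, H, W, C).transpose(0, 3, 1, 2) if x.requires_grad else None
        gw = (xf.T @ gpf).reshape(C, F, kh, kw) if w.requires_grad else None
        gb = g.sum(axis=(0, 2, 3)) if (b is not None and b.requires_grad) else None
        parents_grads = [gx, gw]
        if b is not None:
            parents_grads.append(gb)
        return tuple(parents_grads)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, True, parents, bwd)


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    B, C, H, W = x.shape
    xp = np.pad(
        x.data,
        ((0, 0), (0, 0), (padding, padding), (padding, padding)),
        constant_values=-np.inf,
    )
    cols = _im2col(xp, kernel, kernel, stride)  # B,C,Ho,Wo,k,k
    Ho, Wo = cols.shape[2], cols.shape[3]
    flat = cols.reshape(B, C, Ho, Wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    if not x.requires_grad:
        return Tensor(out)
    Hp, Wp = xp.shape[2], xp.shape[3]

    def bwd(g):
        ki, kj = np.divmod(arg, kernel)
        ho = np.arange(Ho)[None, None, :, None]
        wo = np.arange(Wo)[None, None, None, :]
        rows = ho * stride + ki
        colsx = wo * stride + kj
        bidx = np.arange(B)[:, None, None, None]
        cidx = np.arange(C)[None, :, None, None]
        gxp = np.zeros((B, C, Hp, Wp), dtype=np.float32)
        np.add.at(
            gxp,
            (
                np.broadcast_to(bidx, arg.shape),
                np.broadcast_to(cidx, arg.shape),
                rows,
                colsx,
            ),
            g,
        )
        return (gxp[:, :, padding : padding + H, padding : padding + W],)

    return Tensor(out, True, (x,), bwd)
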