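"""Volumetric network primitives with hand-written backward passes.

All operations take and return :class:`~glioseg.nn.tensor.Tensor` objects
with layout ``(N, C, D, H, W)``. Convolution is implemented by patch
extraction (im2col) followed by a single matmul; the transposed convolution
is specialized to the kernel-2/stride-2 upsampling used by the decoders,
which has non-overlapping output blocks and therefore reduces to a
tensordot plus reshape.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, as_tensor


def _im2col_cl(arr_cl: np.ndarray, k: int, stride: int):
    """Unfold k³ patches of a channels-last (N,D,H,W,C) array into rows.

    Row layout is (k, k, k, C); with C innermost the copy reads memory
    almost sequentially, which is what makes the im2col approach fast.
    """
    view = sliding_window_view(arr_cl, (k, k, k), axis=(1, 2, 3))
    view = view[:, ::stride, ::stride, ::stride]
    n, do, ho, wo, c = view.shape[:5]
    cols = np.ascontiguousarray(view.transpose(0, 1, 2, 3, 5, 6, 7, 4)).reshape(
        n * do * ho * wo, k**3 * c)
    return cols, (n, do, ho, wo)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1,
           padding: int | None = None) -> Tensor:
    """3D convolution, kernel ``k^3``, isotropic stride, zero padding.

    ``padding=None`` chooses ``(k-1)//2`` so stride-1 preserves extent and
    stride-2 halves even extents. The backward pass computes the input
    gradient as a full correlation of the (dilated) output gradient with
    the flipped kernel — another im2col matmul rather than a scatter.
    """
    x, weight, bias = as_tensor(x), as_tensor(weight), as_tensor(bias)
    n_out, n_in, k = weight.data.shape[:3]
    if x.data.shape[1] != n_in:
        raise ValueError(f"expected {n_in} input channels, got {x.data.shape[1]}")
    if padding is None:
        padding = (k - 1) // 2
    s, p = int(stride), int(padding)

    xp = np.ascontiguousarray(x.data.transpose(0, 2, 3, 4, 1))  # channels last
    if p:
        xp = np.pad(xp, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
    cols, (n, do, ho, wo) = _im2col_cl(xp, k, s)
    # weight rows in the same (k, k, k, C_in) layout as the unfolded patches
    w_mat = np.ascontiguousarray(weight.data.transpose(2, 3, 4, 1, 0)).reshape(-1, n_out)
    out = cols @ w_mat + bias.data
    out = out.reshape(n, do, ho, wo, n_out).transpose(0, 4, 1, 2, 3)

    in_spatial = x.data.shape[2:]

    def backward(g):
        g_cols = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(-1, n_out)
        if weight.requires_grad:
            dw = (cols.T @ g_cols).reshape(k, k, k, n_in, n_out)
            weight._accum(dw.transpose(4, 3, 0, 1, 2))
        if bias.requires_grad:
            bias._accum(g_cols.sum(axis=0))
        if x.requires_grad:
            # dilate g by the stride, pad so that a stride-1 correlation with
            # the flipped kernel lands exactly on the input grid
            g_cl = g_cols.reshape(n, do, ho, wo, n_out)
            if s > 1:
                gd = np.zeros((n,) + tuple((e - 1) * s + 1 for e in (do, ho, wo))
                              + (n_out,), dtype=g.dtype)
                gd[:, ::s, ::s, ::s] = g_cl
            else:
                gd = g_cl
            pads = []
            for i, din in enumerate(in_spatial):
                before = k - 1 - p
                after = din + p - 1 - (gd.shape[1 + i] - 1)
                pads.append((before, after))
            gdp = np.pad(gd, ((0, 0),) + tuple(pads) + ((0, 0),))
            g_cols2, _ = _im2col_cl(gdp, k, 1)
            w_flip = np.ascontiguousarray(
                weight.data[:, :, ::-1, ::-1, ::-1].transpose(2, 3, 4, 0, 1)
            ).reshape(-1, n_in)
            dx = g_cols2 @ w_flip
            x._accum(dx.reshape((n,) + tuple(in_spatial) + (n_in,)).transpose(0, 4, 1, 2, 3))

    return Tensor._make(out, (x, weight, bias), backward)


def conv_transpose3d_x2(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Transposed convolution with kernel 2^3 and stride 2^3 (extent doubles).

    ``weight`` has shape ``(C_in, C_out, 2, 2, 2)``.
    """
    x, weight, bias = as_tensor(x), as_tensor(weight), as_tensor(bias)
    n, c_in, d, h, w = x.data.shape
    c_out = weight.data.shape[1]
    # (N,D,H,W,Co,2,2,2) -> interleave the kernel axes with the spatial ones
    t = np.tensordot(x.data, weight.data, axes=([1], [0]))
    out = t.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(n, c_out, 2 * d, 2 * h, 2 * w)
    out = out + bias.data.reshape(1, c_out, 1, 1, 1)

    def backward(g):
        g6 = g.reshape(n, c_out, d, 2, h, 2, w, 2).transpose(0, 2, 4, 6, 1, 3, 5, 7)
        if x.requires_grad:
            dx = np.tensordot(g6, weight.data, axes=([4, 5, 6, 7], [1, 2, 3, 4]))
            x._accum(dx.transpose(0, 4, 1, 2, 3))
        if weight.requires_grad:
            dw = np.tensordot(x.data, g6, axes=([0, 2, 3, 4], [0, 1, 2, 3]))
            weight._accum(dw)
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3, 4)))

    return Tensor._make(out, (x, weight, bias), backward)


def upsample_nearest_x2(x: Tensor) -> Tensor:
    """Nearest-neighbor spatial upsampling by a factor of 2 per axis."""
    x = as_tensor(x)
    n, c, d, h, w = x.data.shape
    out = x.data.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(g):
        if x.requires_grad:
            x._accum(g.reshape(n, c, d, 2, h, 2, w, 2).sum(axis=(3, 5, 7)))

    return Tensor._make(out, (x,), backward)


def instance_norm(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial axes.

    Composed from differentiable primitives, so the backward pass follows
    from the graph; ``weight``/``bias`` are per-channel affine parameters.
    """
    axes = (2, 3, 4)
    mu = x.mean(axis=axes, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=axes, keepdims=True)
    inv_std = (var + eps) ** -0.5
    c = x.shape[1]
    return centered * inv_std * weight.reshape(1, c, 1, 1, 1) + bias.reshape(1, c, 1, 1, 1)


def global_mean_pool(x: Tensor) -> Tensor:
    """Average over the spatial axes: (N,C,D,H,W) -> (N,C)."""
    return x.mean(axis=(2, 3, 4))
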