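"""3D convolution, transposed convolution, trilinear upsampling and max
pooling as differentiable tensor operations.

Forward convolution is im2col over ``numpy.lib.stride_tricks``
sliding windows followed by a tensordot; the input gradient is the usual
zero-dilated correlation with the flipped kernel.  Transposed convolution is
implemented directly as a scatter over kernel offsets (its input gradient is
an ordinary strided gather).  Trilinear 2x upsampling is a fixed depthwise
transposed convolution with the separable kernel [1,3,3,1]/8 per axis, which
reproduces factor-2 linear interpolation in the volume interior.

All tensors are (N, C, D, H, W); kernels are cubic.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autodiff import Tensor


def _windows(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, Do, Ho, Wo, k, k, k) view of padded input, given stride."""
    v = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    if stride > 1:
        v = v[:, :, ::stride, ::stride, ::stride]
    return v


def _conv3d_forward(x: np.ndarray, w: np.ndarray, stride: int, padding: int):
    p = padding
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
    v = _windows(xp, w.shape[2], stride)
    y = np.tensordot(v, w, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
    return np.moveaxis(y, -1, 1), xp


def _conv3d_backward_weight(gy: np.ndarray, xp: np.ndarray, k: int, stride: int):
    v = _windows(xp, k, stride)
    # gw[o,c,i,j,l] = sum_{n,d,h,w} gy[n,o,d,h,w] * v[n,c,d,h,w,i,j,l]
    return np.tensordot(gy, v, axes=([0, 2, 3, 4], [0, 2, 3, 4]))


def _conv3d_backward_input(
    gy: np.ndarray, w: np.ndarray, stride: int, padding: int, x_spatial
):
    n, o = gy.shape[:2]
    k = w.shape[2]
    s = stride
    # zero-dilate the output gradient back onto the stride-1 grid
    dil = [(d - 1) * s + 1 for d in gy.shape[2:]]
    gd = np.zeros((n, o, *dil), dtype=gy.dtype)
    gd[:, :, ::s, ::s, ::s] = gy
    # pad so a stride-1 correlation with the flipped kernel recovers x+2p
    pads = []
    for x_dim, d_dim in zip(x_spatial, gy.shape[2:]):
        r = (x_dim + 2 * padding - k) - (d_dim - 1) * s
        pads.append((k - 1, k - 1 + r))
    gd = np.pad(gd, ((0, 0), (0, 0), *pads))
    w2 = np.ascontiguousarray(
        np.swapaxes(w[:, :, ::-1, ::-1, ::-1], 0, 1)
    )  # (C, O, k, k, k)
    gx_full, _ = _conv3d_forward(gd, w2, stride=1, padding=0)
    p = padding
    if p:
        gx_full = gx_full[:, :, p:-p, p:-p, p:-p]
    return gx_full


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0):
    """Cross-correlation of (N,C,D,H,W) with (O,C,k,k,k) weights + bias."""
    y, xp = _conv3d_forward(x.data, w.data, stride, padding)
    k = w.data.shape[2]
    x_spatial = x.data.shape[2:]

    def backward(g):
        gx = _conv3d_backward_input(g, w.data, stride, padding, x_spatial)
        gw = _conv3d_backward_weight(g, xp, k, stride)
        return gx, gw

    out = Tensor._node(y, (x, w), backward)
    if b is not None:
        out = out + b.reshape(1, -1, 1, 1, 1)
    return out


def _convtr3d_forward(x: np.ndarray, w: np.ndarray, stride: int):
    """Transposed conv, no padding: out = (X-1)*s + k per axis.

    x: (N, C, D, H, W); w: (C, O, k, k, k).
    """
    n, c, d, h, wd = x.shape
    k = w.shape[2]
    s = stride
    out_sp = ((d - 1) * s + k, (h - 1) * s + k, (wd - 1) * s + k)
    t = np.tensordot(x, w, axes=([1], [0]))  # (N, D, H, W, O, k, k, k)
    t = np.moveaxis(t, 4, 1)  # (N, O, D, H, W, k, k, k)
    y = np.zeros((n, w.shape[1], *out_sp), dtype=x.dtype)
    for i, j, l in product(range(k), repeat=3):
        y[
            :,
            :,
            i : i + (d - 1) * s + 1 : s,
            j : j + (h - 1) * s + 1 : s,
            l : l + (wd - 1) * s + 1 : s,
        ] += t[..., i, j, l]
    return y


def _convtr3d_backward(gy: np.ndarray, x: np.ndarray, w: np.ndarray, stride: int):
    d, h, wd = x.shape[2:]
    k = w.shape[2]
    s = stride
    gx = np.zeros_like(x)
    gw = np.zeros_like(w)
    for i, j, l in product(range(k), repeat=3):
        part = gy[
            :,
            :,
            i : i + (d - 1) * s + 1 : s,
            j : j + (h - 1) * s + 1 : s,
            l : l + (wd - 1) * s + 1 : s,
        ]  # (N, O, D, H, W)
        gx += np.moveaxis(np.tensordot(part, w[:, :, i, j, l], axes=([1], [1])), -1, 1)
        gw[:, :, i, j, l] = np.tensordot(x, part, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
    return gx, gw


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 2):
    """Transposed 3D convolution; with k = stride it doubles each spatial dim."""
    y = _convtr3d_forward(x.data, w.data, stride)

    def backward(g):
        return _convtr3d_backward(g, x.data, w.data, stride)

    out = Tensor._node(y, (x, w), backward)
    if b is not None:
        out = out + b.reshape(1, -1, 1, 1, 1)
    return out


# fixed separable trilinear kernel for x2 upsampling (transposed, k=4, s=2, p=1)
_LIN = np.array([1.0, 3.0, 3.0, 1.0]) / 4.0
_TRILINEAR_K4 = (_LIN[:, None, None] * _LIN[None, :, None] * _LIN[None, None, :])[
    None, None
]


def upsample_trilinear_2x(x: Tensor) -> Tensor:
    """Factor-2 trilinear upsampling via a fixed depthwise transposed conv."""
    n, c, d, h, wd = x.shape
    xs = x.reshape(n * c, 1, d, h, wd)

    w = Tensor(_TRILINEAR_K4)  # constant, no grad
    y = conv_transpose3d(xs, w, None, stride=2)
    # crop the padding-1 border: (X-1)*2+4 -> 2X
    y = y[:, :, 1:-1, 1:-1, 1:-1]
    return y.reshape(n, c, 2 * d, 2 * h, 2 * wd)


def maxpool3d_2x(x: Tensor) -> Tensor:
    """2x2x2 max pooling (spatial dims must be even)."""
    n, c, d, h, wd = x.shape
    if d % 2 or h % 2 or wd % 2:
        raise ValueError(f"maxpool3d_2x needs even spatial dims, got {(d, h, wd)}")
    blocks = x.data.reshape(n, c, d // 2, 2, h // 2, 2, wd // 2, 2)
    blocks = blocks.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
        n, c, d // 2, h // 2, wd // 2, 8
    )
    idx = blocks.argmax(axis=-1)
    y = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gb = np.zeros((n, c, d // 2, h // 2, wd // 2, 8), dtype=g.dtype)
        np.put_along_axis(gb, idx[..., None], g[..., None], axis=-1)
        gb = gb.reshape(n, c, d // 2, h // 2, wd // 2, 2, 2, 2)
        gx = gb.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, d, h, wd)
        return (gx,)

    return Tensor._node(y, (x,), backward)
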