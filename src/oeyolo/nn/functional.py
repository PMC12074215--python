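"""Structured neural-net ops (convolution, pooling, upsampling) with
hand-written backward rules, plus a FLOP accounting context.

Convolution is lowered to im2col + BLAS matmul.  Supported group counts are
1 (dense) and C_in (depthwise) — exactly what the detector's blocks use.
FLOPs are counted as 2 x multiply-accumulates over convolutions and linear
maps whenever a :func:`count_flops` context is active.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from oeyolo.nn.tensor import Tensor, add_flops, count_flops

__all__ = ["conv2d", "maxpool2d", "upsample_nearest2x", "count_flops", "add_flops"]


def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int, oh: int, ow: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C, kh, kw, oh, ow) window stack (copies)."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw]
    return cols


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Optional[Tensor] = None,
    stride: int = 1,
    padding: Optional[int] = None,
    groups: int = 1,
) -> Tensor:
    """2-D convolution (cross-correlation) over NCHW input.

    ``padding=None`` means "same" for stride 1 (k//2), and k//2 likewise for
    stride 2 which halves spatial dims for even inputs.
    """
    n, c, h, w = x.data.shape
    cout, cin_g, kh, kw = weight.data.shape
    if padding is None:
        padding = kh // 2
    if groups == 1:
        if cin_g != c:
            raise ValueError(f"channel mismatch: input has {c}, kernel expects {cin_g}")
    elif groups == c:
        if cin_g != 1 or cout != c:
            raise ValueError("depthwise conv requires weight shape (C, 1, kh, kw)")
    else:
        raise ValueError("only dense (groups=1) and depthwise (groups=C) convs are supported")

    # 1x1 stride-1 convolutions reduce to a channel-mixing matmul
    if kh == 1 and kw == 1 and stride == 1 and padding == 0 and groups == 1:
        return _conv1x1(x, weight, bias)

    sh = sw = stride
    oh = (h + 2 * padding - kh) // sh + 1
    ow = (w + 2 * padding - kw) // sw + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = _im2col(xp, kh, kw, sh, sw, oh, ow)  # (N,C,kh,kw,oh,ow)

    if groups == 1:
        cols2 = cols.reshape(n, c * kh * kw, oh * ow)
        w2 = weight.data.reshape(cout, c * kh * kw)
        out_data = np.matmul(w2[None], cols2).reshape(n, cout, oh, ow)
        add_flops(2 * n * cout * c * kh * kw * oh * ow)
    else:  # depthwise
        colsd = cols.reshape(n, c, kh * kw, oh * ow)
        wd = weight.data.reshape(c, kh * kw)
        out_data = np.matmul(wd[None, :, None, :], colsd)[:, :, 0].reshape(n, c, oh, ow)
        add_flops(2 * n * c * kh * kw * oh * ow)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, -1, 1, 1)
        add_flops(n * cout * oh * ow)

    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(out_data, requires_grad=any(p.requires_grad for p in parents), _prev=parents)

    def _bw(g):
        gflat = g.reshape(n, cout, oh * ow)
        if groups == 1:
            cols2b = cols.reshape(n, c * kh * kw, oh * ow)
            if weight.requires_grad:
                gw = np.matmul(gflat, cols2b.transpose(0, 2, 1)).sum(axis=0)
                weight._acc(gw.reshape(weight.data.shape))
            if x.requires_grad:
                w2b = weight.data.reshape(cout, c * kh * kw)
                gcols = np.matmul(w2b.T[None], gflat).reshape(n, c, kh, kw, oh, ow)
                x._acc(_col2im(gcols, xp.shape, kh, kw, sh, sw, oh, ow, padding, (h, w)))
        else:
            colsdb = cols.reshape(n, c, kh * kw, oh * ow)
            gd = g.reshape(n, c, oh * ow)
            if weight.requires_grad:
                gw = np.matmul(colsdb, gd[:, :, :, None])[:, :, :, 0].sum(axis=0)
                weight._acc(gw.reshape(weight.data.shape))
            if x.requires_grad:
                wd2 = weight.data.reshape(c, kh * kw)
                gcols = (gd[:, :, None, :] * wd2[None, :, :, None]).reshape(
                    n, c, kh, kw, oh, ow
                )
                x._acc(_col2im(gcols, xp.shape, kh, kw, sh, sw, oh, ow, padding, (h, w)))
        if bias is not None and bias.requires_grad:
            bias._acc(g.sum(axis=(0, 2, 3)))

    out._backward = _bw
    return out


def _conv1x1(x: Tensor, weight: Tensor, bias: Optional[Tensor]) -> Tensor:
    n, c, h, w = x.data.shape
    cout = weight.data.shape[0]
    w2 = weight.data.reshape(cout, c)
    xf = x.data.reshape(n, c, h * w)
    out_data = np.matmul(w2[None], xf).reshape(n, cout, h, w)
    add_flops(2 * n * cout * c * h * w)
    if bias is not None:
        out_data += bias.data.reshape(1, -1, 1, 1)
        add_flops(n * cout * h * w)
    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(out_data, requires_grad=any(p.requires_grad for p in parents), _prev=parents)

    def _bw(g):
        gflat = g.reshape(n, cout, h * w)
        if weight.requires_grad:
            gw = np.matmul(gflat, xf.transpose(0, 2, 1)).sum(axis=0)
            weight._acc(gw.reshape(weight.data.shape))
        if x.requires_grad:
            gx = np.matmul(w2.T[None], gflat).reshape(n, c, h, w)
            x._acc(gx)
        if bias is not None and bias.requires_grad:
            bias._acc(g.sum(axis=(0, 2, 3)))

    out._backward = _bw
    return out


def _col2im(gcols, xp_shape, kh, kw, sh, sw, oh, ow, padding, hw) -> np.ndarray:
    gpad = np.zeros(xp_shape, dtype=gcols.dtype)
    for i in range(kh):
        for j in range(kw):
            gpad[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw] += gcols[:, :, i, j]
    h, w = hw
    if padding:
        return gpad[:, :, padding : padding + h, padding : padding + w]
    return gpad


def maxpool2d(x: Tensor, kernel: int, stride: int = 1, padding: Optional[int] = None) -> Tensor:
    """Max pooling; default padding keeps spatial size for stride 1."""
    if padding is None:
        padding = kernel // 2
    n, c, h, w = x.data.shape
    oh = (h + 2 * padding - kernel) // stride + 1
    ow = (w + 2 * padding - kernel) // stride + 1
    xp = np.pad(
        x.data,
        ((0, 0), (0, 0), (padding, padding), (padding, padding)),
        constant_values=-np.inf,
    )
    cols = _im2col(xp, kernel, kernel, stride, stride, oh, ow)
    flat = cols.reshape(n, c, kernel * kernel, oh, ow)
    arg = flat.argmax(axis=2)
    out_data = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]
    out = Tensor(out_data, requires_grad=x.requires_grad, _prev=(x,))

    def _bw(g):
        if not x.requires_grad:
            return
        gcols = np.zeros_like(flat)
        np.put_along_axis(gcols, arg[:, :, None], g[:, :, None], axis=2)
        gcols = gcols.reshape(n, c, kernel, kernel, oh, ow)
        x._acc(_col2im(gcols, xp.shape, kernel, kernel, stride, stride, oh, ow, padding, (h, w)))

    out._backward = _bw
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    n, c, h, w = x.data.shape
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    out = Tensor(out_data, requires_grad=x.requires_grad, _prev=(x,))

    def _bw(g):
        if x.requires_grad:
            x._acc(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    out._backward = _bw
    return out
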