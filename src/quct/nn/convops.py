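"""Convolution primitives for the autodiff engine.

Convolutions are evaluated by looping over kernel offsets: for each tap
(kh, kw) a strided view of the (padded) input is contracted with the
corresponding weight slice via einsum.  For the small kernels used here
(<= 9 taps per axis) this is BLAS-bound and needs no im2col buffer.

Layout is NCHW; weights are (C_out, C_in, kh, kw) for standard
convolutions, (C, 1, kh, kw) for depthwise, and (C_in, C_out, kh, kw) for
transposed convolutions.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, _make


def _pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


def conv_out_shape(in_hw, kernel, stride, dilation, padding):
    """Static output-shape arithmetic shared by layers and builders."""
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride)
    dh, dw = _pair(dilation)
    H, W = in_hw
    ekh, ekw = (kh - 1) * dh + 1, (kw - 1) * dw + 1
    if padding == "same":
        return (-(-H // sh), -(-W // sw))
    if padding == "valid":
        if H < ekh or W < ekw:
            raise ValueError(f"valid conv kernel {kernel} exceeds input {in_hw}")
        return ((H - ekh) // sh + 1, (W - ekw) // sw + 1)
    raise ValueError(f"unknown padding {padding!r}")


def conv_transpose_out_shape(in_hw, kernel, stride):
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride)
    H, W = in_hw
    return ((H - 1) * sh + kh, (W - 1) * sw + kw)


def _same_pads(in_hw, kernel, stride, dilation):
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride)
    dh, dw = _pair(dilation)
    H, W = in_hw
    out_h, out_w = -(-H // sh), -(-W // sw)
    ph = max((out_h - 1) * sh + (kh - 1) * dh + 1 - H, 0)
    pw = max((out_w - 1) * sw + (kw - 1) * dw + 1 - W, 0)
    return (ph // 2, ph - ph // 2, pw // 2, pw - pw // 2)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride=1, dilation=1,
           padding="same", depthwise=False) -> Tensor:
    kh, kw = w.shape[-2], w.shape[-1]
    sh, sw = _pair(stride)
    dh, dw = _pair(dilation)
    N, Cin, H, W = x.shape

    if padding == "same":
        pt, pb, pl, pr = _same_pads((H, W), (kh, kw), (sh, sw), (dh, dw))
    else:
        pt = pb = pl = pr = 0
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr))) if (pt or pb or pl or pr) else x.data
    Hp, Wp = xp.shape[-2:]
    ekh, ekw = (kh - 1) * dh + 1, (kw - 1) * dw + 1
    Ho = (Hp - ekh) // sh + 1
    Wo = (Wp - ekw) // sw + 1
    Cout = w.shape[0]

    # two evaluation paths: an im2col matmul for small kernels (the column
    # buffer is taps-fold larger than x) and per-tap accumulation for large
    # kernels, which avoids the blowup at the cost of taps BLAS calls.
    im2col = kh * kw <= 25 and not depthwise
    cols = None
    if im2col:
        win = np.lib.stride_tricks.sliding_window_view(xp, (ekh, ekw),
                                                       axis=(2, 3))
        win = win[:, :, ::sh, ::sw, ::dh, ::dw]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)) \
            .reshape(N * Ho * Wo, Cin * kh * kw)
        out_data = (cols @ w.data.reshape(Cout, -1).T) \
            .reshape(N, Ho, Wo, Cout).transpose(0, 3, 1, 2)
        out_data = np.ascontiguousarray(out_data)
    else:
        out_data = np.zeros((N, Cout, Ho, Wo), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i * dh: i * dh + (Ho - 1) * sh + 1: sh,
                        j * dw: j * dw + (Wo - 1) * sw + 1: sw]
                wk = w.data[:, :, i, j]
                if depthwise:
                    out_data += xs * wk[:, 0][None, :, None, None]
                else:
                    out_data += np.einsum("ncij,oc->noij", xs, wk,
                                          optimize=True)
    if b is not None:
        out_data += b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def tap_slices(i, j):
        return (slice(None), slice(None),
                slice(i * dh, i * dh + (Ho - 1) * sh + 1, sh),
                slice(j * dw, j * dw + (Wo - 1) * sw + 1, sw))

    def backward():
        gy = out.grad
        if b is not None and b.requires_grad:
            b.accumulate(gy.sum(axis=(0, 2, 3)))
        gy2 = None
        if im2col:
            gy2 = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)) \
                .reshape(N * Ho * Wo, Cout)
        if w.requires_grad:
            if im2col:
                gw = (gy2.T @ cols).reshape(w.shape)
            else:
                gw = np.empty_like(w.data)
                for i in range(kh):
                    for j in range(kw):
                        xs = xp[tap_slices(i, j)]
                        if depthwise:
                            gw[:, 0, i, j] = (xs * gy).sum(axis=(0, 2, 3))
                        else:
                            gw[:, :, i, j] = np.einsum("ncij,noij->oc", xs, gy,
                                                       optimize=True)
            w.accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            if im2col:
                gwin = (gy2 @ w.data.reshape(Cout, -1)) \
                    .reshape(N, Ho, Wo, Cin, kh, kw).transpose(0, 3, 1, 2, 4, 5)
                for i in range(kh):
                    for j in range(kw):
                        gxp[tap_slices(i, j)] += gwin[:, :, :, :, i, j]
            else:
                for i in range(kh):
                    for j in range(kw):
                        wk = w.data[:, :, i, j]
                        if depthwise:
                            gxp[tap_slices(i, j)] += gy * wk[:, 0][None, :,
                                                                   None, None]
                        else:
                            gxp[tap_slices(i, j)] += np.einsum(
                                "noij,oc->ncij", gy, wk, optimize=True)
            gx = gxp[:, :, pt: pt + H, pl: pl + W] if (pt or pb or pl or pr) else gxp
            x.accumulate(gx)

    out = _make(out_data, parents, backward)
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None, stride=1) -> Tensor:
    kh, kw = w.shape[-2], w.shape[-1]
    sh, sw = _pair(stride)
    N, Cin, H, W = x.shape
    Cout = w.shape[1]
    Ho, Wo = (H - 1) * sh + kh, (W - 1) * sw + kw
    out_data = np.zeros((N, Cout, Ho, Wo), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            sl = (slice(None), slice(None),
                  slice(i, i + (H - 1) * sh + 1, sh),
                  slice(j, j + (W - 1) * sw + 1, sw))
            out_data[sl] += np.einsum("ncij,co->noij", x.data, w.data[:, :, i, j],
                                      optimize=True)
    if b is not None:
        out_data += b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def backward():
        gy = out.grad
        if b is not None and b.requires_grad:
            b.accumulate(gy.sum(axis=(0, 2, 3)))
        for i in range(kh):
            for j in range(kw):
                gys = gy[:, :, i: i + (H - 1) * sh + 1: sh,
                         j: j + (W - 1) * sw + 1: sw]
                if w.requires_grad:
                    if i == j == 0:
                        gw = np.empty_like(w.data)
                    gw[:, :, i, j] = np.einsum("ncij,noij->co", x.data, gys,
                                               optimize=True)
                if x.requires_grad:
                    if i == j == 0:
                        gx = np.zeros_like(x.data)
                    gx += np.einsum("noij,co->ncij", gys, w.data[:, :, i, j],
                                    optimize=True)
        if w.requires_grad:
            w.accumulate(gw)
        if x.requires_grad:
            x.accumulate(gx)

    out = _make(out_data, parents, backward)
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize across the channel axis at every spatial position."""
    mu = x.data.mean(axis=1, keepdims=True)
    var = x.data.var(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    g = gamma.data[None, :, None, None]
    out_data = (xhat * g + beta.data[None, :, None, None]).astype(np.float32)

    def backward():
        gy = out.grad
        if beta.requires_grad:
            beta.accumulate(gy.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma.accumulate((gy * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxhat = gy * g
            m1 = dxhat.mean(axis=1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=1, keepdims=True)
            x.accumulate(((dxhat - m1 - xhat * m2) * inv).astype(np.float32))

    out = _make(out_data, (x, gamma, beta), backward)
    return out
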