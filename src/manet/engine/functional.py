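"""Convolution-style differentiable operations (NCHW layout).

Forward passes are im2col/einsum based; each op returns a Tensor whose
backward closure produces exact gradients.  Kernel/stride combinations are
restricted to what the segmentation network uses, and every op is covered by
a numerical-gradient test.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .tensor import Tensor


def _pair(v):
    return v if isinstance(v, tuple) else (v, v)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *, stride: int = 1,
           dilation: int = 1, padding=0) -> Tensor:
    """2-D cross-correlation; ``x`` (N,C,H,W), ``w`` (O,C,kh,kw).

    Implemented as a loop over the kh*kw kernel taps, each a channel-mixing
    matmul on a strided view of the padded input: this keeps memory traffic
    proportional to the input (im2col materialization is quadratic in the
    kernel footprint and dominates at wide channel counts).
    """
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    O, Cw, kh, kw = wd.shape
    if Cw != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cw}")
    ph, pw = _pair(padding)
    eh = (kh - 1) * dilation + 1
    ew = (kw - 1) * dilation + 1
    xp = np.pad(xd, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else xd
    Ho = (H + 2 * ph - eh) // stride + 1
    Wo = (W + 2 * pw - ew) // stride + 1
    if Ho < 1 or Wo < 1:
        raise ValueError("conv2d: kernel larger than padded input")

    def tap_view(arr, i, j):
        return arr[:, :,
                   i * dilation: i * dilation + stride * Ho: stride,
                   j * dilation: j * dilation + stride * Wo: stride]

    y = np.zeros((N, O, Ho, Wo), dtype=np.result_type(xd.dtype, wd.dtype))
    for i in range(kh):
        for j in range(kw):
            y += np.einsum("oc,nchw->nohw", wd[:, :, i, j], tap_view(xp, i, j),
                           optimize=True)
    if b is not None:
        y += b.data.reshape(1, O, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gw = np.empty_like(wd)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                xs = tap_view(xp, i, j)
                gw[:, :, i, j] = np.einsum("nohw,nchw->oc", g, xs, optimize=True)
                tap_view(gxp, i, j)[...] += np.einsum(
                    "oc,nohw->nchw", wd[:, :, i, j], g, optimize=True)
        gx = gxp[:, :, ph:ph + H, pw:pw + W] if (ph or pw) else gxp
        if b is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 2, 3))

    return Tensor._make(y, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None, *, stride: int = 2,
                     padding: int = 0, output_padding: int = 0) -> Tensor:
    """Transposed convolution; ``x`` (N,C,H,W), ``w`` (C,O,kh,kw).

    Output spatial size is ``(H-1)*stride - 2*padding + kh + output_padding``;
    the (kernel, stride, padding) combinations used here all double H and W.
    """
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    Cw, O, kh, kw = wd.shape
    if Cw != C:
        raise ValueError(f"conv_transpose2d channel mismatch: input {C}, weight {Cw}")
    Ho = (H - 1) * stride - 2 * padding + kh + output_padding
    Wo = (W - 1) * stride - 2 * padding + kw + output_padding
    fh = (H - 1) * stride + kh
    fw = (W - 1) * stride + kw
    if padding + Ho > fh or padding + Wo > fw:
        raise ValueError("conv_transpose2d: output_padding too large for kernel/stride")

    yf = np.zeros((N, O, fh, fw), dtype=np.result_type(xd.dtype, wd.dtype))
    for i in range(kh):
        for j in range(kw):
            contrib = np.einsum("nchw,co->nohw", xd, wd[:, :, i, j], optimize=True)
            yf[:, :, i:i + stride * H:stride, j:j + stride * W:stride] += contrib
    y = yf[:, :, padding:padding + Ho, padding:padding + Wo]
    if b is not None:
        y = y + b.data.reshape(1, O, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gf = np.zeros((N, O, fh, fw), dtype=g.dtype)
        gf[:, :, padding:padding + Ho, padding:padding + Wo] = g
        gx = np.zeros_like(xd)
        gw = np.zeros_like(wd)
        for i in range(kh):
            for j in range(kw):
                sl = gf[:, :, i:i + stride * H:stride, j:j + stride * W:stride]
                gx += np.einsum("nohw,co->nchw", sl, wd[:, :, i, j], optimize=True)
                gw[:, :, i, j] = np.einsum("nchw,nohw->co", xd, sl, optimize=True)
        if b is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 2, 3))

    return Tensor._make(y, parents, backward)


def max_pool2d(x: Tensor, kernel: int, stride: int | None = None) -> Tensor:
    """Max pooling with stride = kernel (floor mode); ties go to the first entry."""
    if stride is None:
        stride = kernel
    if stride != kernel:
        raise ValueError("max_pool2d supports stride == kernel only")
    xd = x.data
    N, C, H, W = xd.shape
    Ho, Wo = H // kernel, W // kernel
    if Ho < 1 or Wo < 1:
        raise ValueError(f"max_pool2d: kernel {kernel} does not fit input {H}x{W}")
    xc = xd[:, :, :Ho * kernel, :Wo * kernel]
    xr = xc.reshape(N, C, Ho, kernel, Wo, kernel)
    flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, Ho, Wo, kernel * kernel)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gcrop = gflat.reshape(N, C, Ho, Wo, kernel, kernel).transpose(0, 1, 2, 4, 3, 5)
        gx = np.zeros_like(xd)
        gx[:, :, :Ho * kernel, :Wo * kernel] = gcrop.reshape(N, C, Ho * kernel, Wo * kernel)
        return (gx,)

    return Tensor._make(y, (x,), backward)


@lru_cache(maxsize=256)
def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (half-pixel centers)."""
    if n_in == n_out:
        return np.eye(n_in)
    pos = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    i0 = np.floor(pos).astype(int)
    frac = pos - i0
    lo = np.clip(i0, 0, n_in - 1)
    hi = np.clip(i0 + 1, 0, n_in - 1)
    m = np.zeros((n_out, n_in))
    rows = np.arange(n_out)
    np.add.at(m, (rows, lo), 1.0 - frac)
    np.add.at(m, (rows, hi), frac)
    return m


def bilinear_resize(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Differentiable bilinear resize of (N,C,H,W) to spatial ``size``."""
    xd = x.data
    _, _, H, W = xd.shape
    Ho, Wo = size
    wr = _interp_matrix(H, Ho).astype(xd.dtype)
    wc = _interp_matrix(W, Wo).astype(xd.dtype)
    y = np.einsum("io,ncop,jp->ncij", wr, xd, wc, optimize=True)

    def backward(g):
        return (np.einsum("io,ncij,jp->ncop", wr, g, wc, optimize=True),)

    return Tensor._make(y, (x,), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
               running_var: np.ndarray, *, training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization; updates running stats in place when training."""
    xd = x.data
    N, C, H, W = xd.shape
    if training:
        mean = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    std = np.sqrt(var + eps)
    xhat = (xd - mean[None, :, None, None]) / std[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        ggamma = (g * xhat).sum(axis=(0, 2, 3))
        gbeta = g.sum(axis=(0, 2, 3))
        gxhat = g * gamma.data[None, :, None, None]
        if training:
            m1 = gxhat.mean(axis=(0, 2, 3), keepdims=True)
            m2 = (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
            gx = (gxhat - m1 - xhat * m2) / std[None, :, None, None]
        else:
            gx = gxhat / std[None, :, None, None]
        return gx, ggamma, gbeta

    return Tensor._make(y, (x, gamma, beta), backward)
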