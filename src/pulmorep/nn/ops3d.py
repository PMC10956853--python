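"""3D network primitives (convolution, pooling, upsampling, Sobel) as
autodiff ops.

Convolutions use im2col + GEMM with stride 1 and same-size zero padding; the
input gradient is computed as a convolution of the output gradient with the
spatially flipped, channel-transposed kernel, which is exact for this
configuration.  The Sobel operator uses separable [1,2,1]/[-1,0,1] taps with
replicate padding so that spatially constant fields map to exactly zero.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autodiff import Tensor

__all__ = [
    "conv3d",
    "maxpool3d",
    "upsample_nearest3d",
    "sobel_axis",
    "sobel_axis_adjoint",
    "sobel_magnitude",
]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, D, H, W) -> (N, C*k^3, D*H*W) with same-size zero padding.

    Channel-major column layout: the copy walks shifted sub-volumes with a
    contiguous innermost axis, which keeps it at near-memcpy speed.
    """
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    n, c, d, h, w = x.shape
    # (N, C, D, H, W, kz, ky, kx) -> (N, C, kz, ky, kx, D, H, W) -> flat
    return np.ascontiguousarray(
        win.transpose(0, 1, 5, 6, 7, 2, 3, 4)
    ).reshape(n, c * k**3, d * h * w)


def _conv3d_data(
    x: np.ndarray, w: np.ndarray, b: np.ndarray | None, return_cols: bool = False
):
    n, c, d, h, wd = x.shape
    cout, cin, k = w.shape[0], w.shape[1], w.shape[2]
    if cin != c:
        raise ValueError(f"channel mismatch: input {c}, kernel {cin}")
    cols = _im2col(x, k)  # (N, C*k^3, V)
    y = np.matmul(w.reshape(cout, cin * k**3), cols)  # (N, Cout, V)
    if b is not None:
        y += b[:, None]
    y = y.reshape(n, cout, d, h, wd)
    return (y, cols) if return_cols else y


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1, same-padding 3D convolution (cross-correlation convention)."""
    needs_grad = x.requires_grad or w.requires_grad
    out, cols = _conv3d_data(
        x.data, w.data, None if b is None else b.data, return_cols=needs_grad
    ) if needs_grad else (_conv3d_data(x.data, w.data, None if b is None else b.data), None)
    k = w.shape[2]
    n, _, d, h, wd = x.shape
    cout = w.shape[0]

    def backward(g):
        gmat = np.ascontiguousarray(g.reshape(n, cout, d * h * wd))
        # batched GEMM with transposed B view (no repacking of cols)
        dwmat = np.matmul(gmat, np.swapaxes(cols, 1, 2)).sum(axis=0)
        dw = dwmat.reshape(w.shape)
        db = None if b is None else g.sum(axis=(0, 2, 3, 4)).reshape(b.shape)
        # input grad: convolve g with the flipped, channel-transposed kernel
        wflip = w.data.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
        dx = _conv3d_data(g, np.ascontiguousarray(wflip), None)
        if b is None:
            return dx, dw
        return dx, dw, db

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def maxpool3d(x: Tensor, factor: int = 2) -> Tensor:
    """Non-overlapping max pooling; spatial dims must be divisible by `factor`.

    Gradient is routed to every voxel attaining the block maximum (ties share).
    """
    n, c, d, h, w = x.shape
    f = factor
    if d % f or h % f or w % f:
        raise ValueError(f"spatial dims {(d, h, w)} not divisible by {f}")
    blocks = x.data.reshape(n, c, d // f, f, h // f, f, w // f, f)
    out = blocks.max(axis=(3, 5, 7))

    def backward(g):
        up = out.reshape(n, c, d // f, 1, h // f, 1, w // f, 1)
        mask = blocks == up
        gb = g.reshape(n, c, d // f, 1, h // f, 1, w // f, 1)
        dx = (mask * gb).reshape(n, c, d, h, w)
        return (dx,)

    return Tensor._make(out, (x,), backward)


def upsample_nearest3d(x: Tensor, factor: int = 2) -> Tensor:
    f = factor
    n, c, d, h, w = x.shape
    out = (
        x.data.reshape(n, c, d, 1, h, 1, w, 1)
        .repeat(f, 3)
        .repeat(f, 5)
        .repeat(f, 7)
        .reshape(n, c, d * f, h * f, w * f)
    )

    def backward(g):
        dx = g.reshape(n, c, d, f, h, f, w, f).sum(axis=(3, 5, 7))
        return (dx,)

    return Tensor._make(out, (x,), backward)


# ---------------------------------------------------------------------------
# Sobel operator with replicate padding
# ---------------------------------------------------------------------------

_DERIV = np.array([-1.0, 0.0, 1.0])
_SMOOTH = np.array([1.0, 2.0, 1.0])


def _corr1d_replicate(x: np.ndarray, taps: np.ndarray, axis: int) -> np.ndarray:
    """Correlate with a 3-tap kernel along `axis` under replicate padding."""
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    taps = taps.astype(x.dtype, copy=False)
    xp = np.concatenate([x[..., :1], x, x[..., -1:]], axis=-1)
    y = taps[0] * xp[..., 0:n] + taps[1] * xp[..., 1 : n + 1] + taps[2] * xp[..., 2 : n + 2]
    return np.moveaxis(y, -1, axis)


def _corr1d_replicate_adjoint(g: np.ndarray, taps: np.ndarray, axis: int) -> np.ndarray:
    """Adjoint of `_corr1d_replicate` (fold pad contributions onto the edges)."""
    g = np.moveaxis(g, axis, -1)
    n = g.shape[-1]
    taps = taps.astype(g.dtype, copy=False)
    dxp = np.zeros(g.shape[:-1] + (n + 2,), dtype=g.dtype)
    for j in range(3):
        dxp[..., j : j + n] += taps[j] * g
    dx = dxp[..., 1 : n + 1].copy()
    dx[..., 0] += dxp[..., 0]
    dx[..., -1] += dxp[..., n + 1]
    return np.moveaxis(dx, -1, axis)


def _sobel_taps(deriv_axis: int, axis: int) -> np.ndarray:
    return _DERIV if axis == deriv_axis else _SMOOTH


def sobel_axis(x: np.ndarray, deriv_axis: int, spatial_axes: tuple[int, ...]) -> np.ndarray:
    """3D Sobel response differentiating along `deriv_axis` (an entry of
    `spatial_axes`), smoothing along the other two; replicate padding."""
    y = x
    for ax in spatial_axes:
        y = _corr1d_replicate(y, _sobel_taps(deriv_axis, ax), ax)
    return y


def sobel_axis_adjoint(
    g: np.ndarray, deriv_axis: int, spatial_axes: tuple[int, ...]
) -> np.ndarray:
    y = g
    for ax in reversed(spatial_axes):
        y = _corr1d_replicate_adjoint(y, _sobel_taps(deriv_axis, ax), ax)
    return y


def sobel_magnitude(p: Tensor | np.ndarray, spatial_axes: tuple[int, ...] | None = None):
    """Per-voxel L2 magnitude of the 3-axis Sobel response, per channel.

    Accepts arrays of shape (..., D, H, W); the last three axes are spatial
    unless `spatial_axes` is given.  Returns the same shape as the input.
    """
    arr = p.data if isinstance(p, Tensor) else np.asarray(p)
    if spatial_axes is None:
        spatial_axes = (arr.ndim - 3, arr.ndim - 2, arr.ndim - 1)
    if any(arr.shape[a] < 3 for a in spatial_axes):
        raise ValueError("grid must span at least 3 voxels per spatial axis")
    comps = [sobel_axis(arr, a, spatial_axes) for a in spatial_axes]
    sq = sum(c * c for c in comps)
    mag = np.sqrt(sq)
    if not isinstance(p, Tensor):
        return mag

    def backward(g):
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(mag > 0, g / np.where(mag > 0, mag, 1.0), 0.0)
        dx = np.zeros_like(arr)
        for a, comp in zip(spatial_axes, comps):
            dx += sobel_axis_adjoint(scale * comp, a, spatial_axes)
        return (dx,)

    return Tensor._make(mag, (p,), backward)
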