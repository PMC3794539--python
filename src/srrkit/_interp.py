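"""Low-level linear-resampling primitives shared by geometry and acquisition.

These are deliberately hand-rolled: the forward/backward operators of the
reconstruction need exact control over interpolation weights, fill values
and support masks, and they must be fast enough to sit inside the inner
loop of an iterative reconstruction (a few fancy-indexing gathers each).
"""

from __future__ import annotations

import numpy as np


def sample_along_axis(
    data: np.ndarray,
    positions: np.ndarray,
    axis: int,
    *,
    interpolation: str = "linear",
    mode: str = "fill",
    fill: float = 0.0,
) -> np.ndarray:
    """Sample ``data`` at fractional index ``positions`` along one axis.

    Parameters
    ----------
    positions : 1-D array of fractional indices along ``axis``.
    interpolation : "linear" or "nearest".
    mode : "fill" replaces out-of-range samples by ``fill``;
        "clamp" holds them at the first/last sample.
    """
    pos = np.asarray(positions, dtype=np.float64)
    n = data.shape[axis]
    if mode == "clamp":
        pos = np.clip(pos, 0.0, n - 1.0)
    if interpolation == "nearest":
        idx = np.rint(pos).astype(np.intp)
        out = np.take(data, np.clip(idx, 0, n - 1), axis=axis)
    elif interpolation == "linear":
        i0 = np.floor(pos).astype(np.intp)
        w = pos - i0
        a = np.take(data, np.clip(i0, 0, n - 1), axis=axis)
        b = np.take(data, np.clip(i0 + 1, 0, n - 1), axis=axis)
        shp = [1] * data.ndim
        shp[axis] = pos.size
        w = w.reshape(shp)
        out = (1.0 - w) * a + w * b
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if mode == "fill":
        valid = (pos >= 0.0) & (pos <= n - 1.0)
        shp = [1] * data.ndim
        shp[axis] = pos.size
        out = np.where(valid.reshape(shp), out, fill)
    return out


def shift_along_axis(
    data: np.ndarray,
    offset_vox: float,
    axis: int,
    *,
    interpolation: str = "linear",
    fill: float = 0.0,
) -> np.ndarray:
    """Resample so that ``out[i] = data[i + offset_vox]`` along ``axis``.

    Implemented with plain slice arithmetic (a uniform shift needs at
    most two shifted copies), which keeps it cheap inside the IBP loop.
    """
    n = data.shape[axis]
    if interpolation == "nearest":
        offset_vox = float(np.rint(offset_vox))
    elif interpolation != "linear":
        raise ValueError(f"unknown interpolation {interpolation!r}")
    k = int(np.floor(offset_vox))
    w = offset_vox - k
    out = np.full_like(data, fill)
    src = np.moveaxis(data, axis, 0)
    dst = np.moveaxis(out, axis, 0)
    if w == 0.0:
        lo = max(0, -k)
        hi = min(n, n - k)
        if hi > lo:
            dst[lo:hi] = src[lo + k : hi + k]
    else:
        lo = max(0, -k)
        hi = min(n, n - 1 - k)  # need both i+k and i+k+1 in range
        if hi > lo:
            dst[lo:hi] = (1.0 - w) * src[lo + k : hi + k] + w * src[lo + k + 1 : hi + k + 1]
    return out


_ROTATION_PLAN_CACHE: dict = {}


def _rotation_plan(ny: int, nx: int, angle_deg: float, interpolation: str):
    """Precomputed source indices/weights for one inplane rotation; the
    reconstruction loop reuses the same few angles hundreds of times."""
    key = (ny, nx, round(float(angle_deg), 9), interpolation)
    plan = _ROTATION_PLAN_CACHE.get(key)
    if plan is not None:
        return plan
    t = np.deg2rad(angle_deg)
    ct, st = np.cos(t), np.sin(t)
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    iy, ix = np.meshgrid(
        np.arange(ny, dtype=np.float64), np.arange(nx, dtype=np.float64), indexing="ij"
    )
    dy, dx = iy - cy, ix - cx
    ys = ct * dy - st * dx + cy
    xs = st * dy + ct * dx + cx
    valid = (ys >= 0.0) & (ys <= ny - 1.0) & (xs >= 0.0) & (xs <= nx - 1.0)
    if interpolation == "nearest":
        y0 = np.clip(np.rint(ys).astype(np.intp), 0, ny - 1)
        x0 = np.clip(np.rint(xs).astype(np.intp), 0, nx - 1)
        plan = ("nearest", y0, x0, valid)
    elif interpolation == "linear":
        y0 = np.floor(ys).astype(np.intp)
        x0 = np.floor(xs).astype(np.intp)
        wy = (ys - y0)[None, :, :]
        wx = (xs - x0)[None, :, :]
        plan = (
            "linear",
            np.clip(y0, 0, ny - 1),
            np.clip(y0 + 1, 0, ny - 1),
            np.clip(x0, 0, nx - 1),
            np.clip(x0 + 1, 0, nx - 1),
            wy,
            wx,
            valid,
        )
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    _ROTATION_PLAN_CACHE[key] = plan
    return plan


def rotate_about_axis0(
    data: np.ndarray,
    angle_deg: float,
    *,
    interpolation: str = "linear",
    fill: float = 0.0,
) -> np.ndarray:
    """Rotate in the (y, x) plane about the volume centre, axis 0 fixed.

    ``out[z, y, x] = data(z, R(angle) @ ([y, x] - c) + c)`` with bilinear
    (or nearest) sampling; samples outside the grid take ``fill``.
    """
    nz, ny, nx = data.shape
    plan = _rotation_plan(ny, nx, angle_deg, interpolation)
    if plan[0] == "nearest":
        _, y0, x0, valid = plan
        out = data[:, y0, x0]
    else:
        _, y0c, y1c, x0c, x1c, wy, wx, valid = plan
        out = (1 - wy) * ((1 - wx) * data[:, y0c, x0c] + wx * data[:, y0c, x1c]) + wy * (
            (1 - wx) * data[:, y1c, x0c] + wx * data[:, y1c, x1c]
        )
    return np.where(valid[None, :, :], out, fill)
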