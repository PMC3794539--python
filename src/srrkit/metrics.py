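"""Quantitative image-quality metrics.

* SNR — mean intensity of a signal ROI over the standard deviation of a
  background-noise ROI.
* CNR — |mean_high - mean_low| / max(sd_high, sd_low) between two ROIs.
* Edge width — a logistic (sigmoid) edge model
  ``f(x) = a1 + a2 / (1 + exp(-a3 (x - a4)))`` is fitted to an intensity
  profile by nonlinear least squares; the 10-90% rise length of the
  normalised logistic is ``2 ln 9 / a3 ≈ 4.4 / a3`` pixels, so ``a3 =
  4.4`` corresponds to a one-voxel rise.  Mean edge width averages the
  converged fits of (by default 20) boundary-crossing profiles.
* Tube modulation — depth of the local minima of a profile across a row
  of dark tubes, relative to the profile's dynamic range; zero when the
  expected number of minima is not detected (tubes unresolved).

ROIs are 9x9x9 voxel boxes inside homogeneous regions; on synthetic
phantoms their placement comes from the generator's own region map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .volume import Volume

LOGISTIC_RISE_CONSTANT = 4.4  # ~= 2 ln 9, the 10-90% rise of the unit logistic


@dataclass(frozen=True)
class BoxROI:
    """An axis-aligned box of voxels: corner index + extent."""

    corner: tuple[int, int, int]
    size: tuple[int, int, int] = (9, 9, 9)

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.size):
            raise ValueError("ROI size components must be >= 1")

    def extract(self, volume: Volume) -> np.ndarray:
        for c, s, n in zip(self.corner, self.size, volume.shape):
            if c < 0 or c + s > n:
                raise ValueError(f"ROI {self.corner}+{self.size} outside volume {volume.shape}")
        z, y, x = self.corner
        dz, dy, dx = self.size
        return volume.data[z : z + dz, y : y + dy, x : x + dx]


def compute_snr(volume: Volume, signal_roi: BoxROI, noise_roi: BoxROI) -> float:
    """Mean(signal ROI) / sd(noise ROI).  A zero noise sd is an error
    (SNR undefined), never infinity."""
    signal = float(signal_roi.extract(volume).mean())
    sd = float(noise_roi.extract(volume).std(ddof=0))
    if sd == 0.0:
        raise ValueError("noise ROI has zero standard deviation; SNR undefined")
    return signal / sd


def compute_cnr(volume: Volume, roi_high: BoxROI, roi_low: BoxROI) -> float:
    """|mean_high - mean_low| / max(sd_high, sd_low)."""
    a = roi_high.extract(volume)
    b = roi_low.extract(volume)
    denom = max(float(a.std(ddof=0)), float(b.std(ddof=0)))
    if denom == 0.0:
        raise ValueError("both ROIs have zero standard deviation; CNR undefined")
    return abs(float(a.mean()) - float(b.mean())) / denom


# ------------------------------------------------------------ profiles


@dataclass
class LineProfile:
    """Intensities sampled along a straight segment; coordinates are in
    HR pixels along the segment."""

    x_pixels: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def extract_line_profile(
    volume: Volume, start_mm, end_mm, n_samples: int
) -> LineProfile:
    """Trilinear samples at ``n_samples`` evenly spaced points on the
    segment from ``start_mm`` to ``end_mm`` (mm, (z, y, x) order)."""
    if n_samples < 2:
        raise ValueError("need at least two samples")
    start = np.asarray(start_mm, dtype=np.float64)
    end = np.asarray(end_mm, dtype=np.float64)
    t = np.linspace(0.0, 1.0, n_samples)
    pts = start[None, :] + t[:, None] * (end - start)[None, :]
    idx = (pts - np.asarray(volume.origin)) / np.asarray(volume.spacing)

    # vectorised trilinear interpolation with edge clamping
    i0 = np.floor(idx).astype(np.intp)
    w = idx - i0
    vals = np.zeros(n_samples)
    shape = volume.shape
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                iz = np.clip(i0[:, 0] + dz, 0, shape[0] - 1)
                iy = np.clip(i0[:, 1] + dy, 0, shape[1] - 1)
                ix = np.clip(i0[:, 2] + dx, 0, shape[2] - 1)
                wz = w[:, 0] if dz else 1.0 - w[:, 0]
                wy = w[:, 1] if dy else 1.0 - w[:, 1]
                wx = w[:, 2] if dx else 1.0 - w[:, 2]
                vals += wz * wy * wx * volume.data[iz, iy, ix]
    length_px = float(np.linalg.norm(end - start)) / float(np.mean(volume.spacing))
    return LineProfile(x_pixels=t * length_px, values=vals)


# --------------------------------------------------------- sigmoid fit


@dataclass
class SigmoidFit:
    """Parameters of the logistic edge model and the derived edge width."""

    a1: float  # baseline intensity
    a2: float  # amplitude
    a3: float  # slope, per HR pixel
    a4: float  # edge location, HR pixels
    residual_ss: float = float("nan")
    converged: bool = True
    flipped: bool = False  # profile was descending and got reversed

    @property
    def edge_width_pixels(self) -> float:
        return LOGISTIC_RISE_CONSTANT / self.a3


def sigmoid_edge_model(x, a1, a2, a3, a4):
    return a1 + a2 / (1.0 + np.exp(-a3 * (x - a4)))


def _crossing(x: np.ndarray, v: np.ndarray, level: float) -> float:
    """First linear-interpolated crossing of ``level`` by ``v(x)``."""
    above = v >= level
    idx = np.nonzero(above[1:] != above[:-1])[0]
    if idx.size == 0:
        return float(x[np.argmin(np.abs(v - level))])
    i = idx[0]
    frac = (level - v[i]) / (v[i + 1] - v[i])
    return float(x[i] + frac * (x[i + 1] - x[i]))


def fit_sigmoid_edge(profile) -> SigmoidFit:
    """Least-squares fit of the logistic edge model to a profile.

    Accepts a :class:`LineProfile` or a plain value array (x then taken
    as 0..n-1 pixels).  Descending profiles are flipped before fitting
    so that a3 > 0.  Initial values come from the data: a1 = min,
    a2 = range, a4 = half-range crossing, a3 = 4.4 over the 10-90%
    crossing distance.  A fit that fails to converge is returned with
    ``converged=False`` (callers exclude those from means); a flat
    profile is an error.
    """
    if isinstance(profile, LineProfile):
        x = np.asarray(profile.x_pixels, dtype=np.float64)
        v = np.asarray(profile.values, dtype=np.float64)
    else:
        v = np.asarray(profile, dtype=np.float64)
        x = np.arange(v.size, dtype=np.float64)
    if v.size < 8:
        raise ValueError("edge profile needs at least 8 samples")
    rng_v = float(v.max() - v.min())
    if rng_v == 0.0:
        raise ValueError("flat profile: no edge to fit")

    q = max(2, v.size // 4)
    flipped = bool(v[:q].mean() > v[-q:].mean())
    if flipped:
        v = v[::-1].copy()

    a1_0 = float(v.min())
    a2_0 = rng_v
    half = a1_0 + 0.5 * a2_0
    x10 = _crossing(x, v, a1_0 + 0.1 * a2_0)
    x90 = _crossing(x, v, a1_0 + 0.9 * a2_0)
    rise = abs(x90 - x10)
    a3_0 = LOGISTIC_RISE_CONSTANT / rise if rise > 0 else 1.0
    a4_0 = _crossing(x, v, half)
    p0 = (a1_0, a2_0, a3_0, a4_0)
    bounds = (
        (-np.inf, 0.0, 1e-9, x[0] - (x[-1] - x[0])),
        (np.inf, np.inf, np.inf, x[-1] + (x[-1] - x[0])),
    )
    try:
        popt, _ = curve_fit(sigmoid_edge_model, x, v, p0=p0, bounds=bounds, maxfev=5000)
    except (RuntimeError, ValueError):
        return SigmoidFit(*p0, residual_ss=float("nan"), converged=False, flipped=flipped)
    resid = v - sigmoid_edge_model(x, *popt)
    return SigmoidFit(
        a1=float(popt[0]),
        a2=float(popt[1]),
        a3=float(popt[2]),
        a4=float(popt[3]),
        residual_ss=float(np.sum(resid**2)),
        converged=True,
        flipped=flipped,
    )


def edge_width_pixels(fit: SigmoidFit) -> float:
    """Edge width in HR pixels: 4.4 / a3 (the 10-90% rise length)."""
    return LOGISTIC_RISE_CONSTANT / fit.a3


@dataclass
class EdgeWidthSummary:
    mean_width_pixels: float
    n_converged: int
    n_total: int
    widths: list[float] = field(default_factory=list)


def mean_edge_width(
    volume: Volume,
    edge_segments: Sequence[tuple],
    n: Optional[int] = 20,
    samples_per_pixel: float = 4.0,
) -> EdgeWidthSummary:
    """Mean edge width over the converged fits of ``n`` profiles.

    ``edge_segments`` is a sequence of (start_mm, end_mm) pairs; each is
    sampled at 1/``samples_per_pixel`` HR-pixel steps (supersampling
    stabilises fits on sharp edges; a3 stays expressed per HR pixel
    because the profile coordinates are in pixels).
    """
    segments = list(edge_segments)[: n if n else None]
    widths = []
    for start, end in segments:
        length_px = float(np.linalg.norm(np.asarray(end) - np.asarray(start))) / float(
            np.mean(volume.spacing)
        )
        n_samples = max(8, int(np.ceil(length_px * samples_per_pixel)) + 1)
        prof = extract_line_profile(volume, start, end, n_samples)
        try:
            fit = fit_sigmoid_edge(prof)
        except ValueError:
            continue
        if fit.converged and fit.a3 > 0:
            widths.append(edge_width_pixels(fit))
    mean = float(np.mean(widths)) if widths else float("nan")
    return EdgeWidthSummary(
        mean_width_pixels=mean,
        n_converged=len(widths),
        n_total=len(segments),
        widths=widths,
    )


# ----------------------------------------------------- tube modulation


def tube_modulation(
    profile, n_tubes: int, prominence_fraction: float = 0.05
) -> float:
    """Resolvability score in [0, 1] of a profile across a row of dark
    tubes: mean depth of the ``n_tubes`` detected minima relative to the
    neighbouring inter-tube maxima, normalised by the profile's dynamic
    range.  Returns 0 when fewer than ``n_tubes`` minima (of prominence
    at least ``prominence_fraction`` of the range) are found — the tubes
    are unresolved.
    """
    v = np.asarray(profile.values if isinstance(profile, LineProfile) else profile, float)
    if n_tubes < 1:
        raise ValueError("n_tubes must be >= 1")
    dyn = float(v.max() - v.min())
    if dyn == 0.0:
        return 0.0
    minima, props = find_peaks(-v, prominence=prominence_fraction * dyn)
    if minima.size < n_tubes:
        return 0.0
    if minima.size > n_tubes:
        order = np.argsort(props["prominences"])[::-1][:n_tubes]
        minima = np.sort(minima[order])
    # highest value in each gap between consecutive minima (profile ends
    # count as gaps), then depth = mean of the two flanking maxima - minimum
    edges = [0, *minima.tolist(), v.size - 1]
    gap_max = [float(v[edges[i] : edges[i + 1] + 1].max()) for i in range(len(minima) + 1)]
    depths = [
        0.5 * (gap_max[i] + gap_max[i + 1]) - float(v[m]) for i, m in enumerate(minima)
    ]
    return float(np.clip(np.mean(depths) / dyn, 0.0, 1.0))
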