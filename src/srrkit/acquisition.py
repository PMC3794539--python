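"""Forward model: simulate a 2-D multislice LR stack from an HR volume.

The imaging process is modelled as (1) the geometric transform into the
stack frame, (2) a 1-D Gaussian slice-profile blur along the
slice-select axis with FWHM equal to the slice thickness (matching the
excitation profile of the multislice sequence), (3) point sampling of
the blurred volume at the slice centres (the blur carries all
partial-volume effect), and (4) additive noise.  No inplane degradation
is applied: multislice acquisitions are already at high resolution
inplane, only the slice-select axis is coarse.

Slice centres start half a slice thickness into the volume, i.e. the
first slice is centred in its slab, and consecutive slices are
contiguous (spaced by exactly one slice thickness).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from ._interp import sample_along_axis
from .geometry import StackGeometry, transform_volume
from .volume import Volume

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class AcquisitionModel:
    """Voxel geometry, slice profile and noise of one LR acquisition.

    ``blur_fwhm`` defaults to the slice thickness.  ``aspect_ratio`` is
    slice thickness over inplane spacing (the N of "1 : 1 : N").
    """

    inplane_spacing: float
    slice_thickness: float
    blur_fwhm: float | None = None
    noise_sigma: float = 0.0
    noise_model: str = "gaussian"

    def __post_init__(self) -> None:
        if self.blur_fwhm is None:
            self.blur_fwhm = self.slice_thickness
        if self.blur_fwhm <= 0:
            raise ValueError("blur_fwhm must be positive")
        if self.slice_thickness < self.inplane_spacing - 1e-12:
            raise ValueError("slice thickness must be >= inplane spacing")

    @property
    def aspect_ratio(self) -> float:
        return self.slice_thickness / self.inplane_spacing

    def to_dict(self) -> dict:
        return {
            "inplane_spacing": self.inplane_spacing,
            "slice_thickness": self.slice_thickness,
            "blur_fwhm": self.blur_fwhm,
            "noise_sigma": self.noise_sigma,
            "noise_model": self.noise_model,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionModel":
        return cls(**d)


@dataclass
class LRStack:
    """One simulated (or observed) low-resolution image stack f_k.

    ``data`` lives in the stack frame; along ``geometry.slice_axis`` it
    holds one sample per slice, the other two axes keep the HR inplane
    grid.  ``hr_shape``/``hr_spacing``/``origin`` record the HR grid the
    stack was sampled from, so it can be upsampled back onto it.
    """

    data: np.ndarray
    geometry: StackGeometry
    model: AcquisitionModel
    slice_positions: np.ndarray  # mm along the slice axis (stack frame)
    hr_shape: tuple[int, int, int]
    hr_spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.slice_positions = np.asarray(self.slice_positions, dtype=np.float64)
        n = self.data.shape[self.geometry.slice_axis]
        if self.slice_positions.shape != (n,):
            raise ValueError("one slice position per slice is required")
        if n > 1:
            steps = np.diff(self.slice_positions)
            if np.any(steps <= 0):
                raise ValueError("slice positions must be strictly increasing")
            if not np.allclose(steps, self.model.slice_thickness, rtol=1e-6, atol=1e-9):
                raise ValueError("slices must be contiguous (spaced by one slice thickness)")

    @property
    def n_slices(self) -> int:
        return self.data.shape[self.geometry.slice_axis]

    def with_data(self, data: np.ndarray) -> "LRStack":
        return replace(self, data=np.asarray(data, dtype=np.float64))


def slice_profile_kernel(fwhm: float, sample_spacing: float) -> np.ndarray:
    """Discrete Gaussian slice profile, sigma = FWHM / (2 sqrt(2 ln 2)),
    truncated at +-3 sigma and renormalised to unit sum."""
    if fwhm <= 0 or sample_spacing <= 0:
        raise ValueError("fwhm and sample_spacing must be positive")
    if fwhm < sample_spacing / 2.0:
        warnings.warn(
            f"slice-profile FWHM {fwhm} below half the sample spacing "
            f"{sample_spacing}; the discrete kernel degenerates to a delta",
            stacklevel=2,
        )
    sigma = fwhm * FWHM_TO_SIGMA
    radius = int(np.ceil(3.0 * sigma / sample_spacing))
    x = np.arange(-radius, radius + 1, dtype=np.float64) * sample_spacing
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def slice_center_indices(n_hr: int, aspect_ratio: float) -> np.ndarray:
    """Fractional HR indices of the slice centres: slice j is centred at
    ``(j + 1/2) * AR - 1/2`` so that contiguous slabs tile the volume and
    AR = 1 reduces to the identity sampling."""
    m = int(np.floor(n_hr / aspect_ratio + 1e-9))
    if m < 1:
        raise ValueError("volume thinner than one slice")
    return (np.arange(m, dtype=np.float64) + 0.5) * aspect_ratio - 0.5


_OBSERVATION_CACHE: dict = {}


def _observation_matrix(n_hr: int, aspect_ratio: float, fwhm: float, spacing: float) -> np.ndarray:
    """(m x n) operator along the slice axis: slice-profile convolution
    followed by linear point sampling at the slice centres.

    Row j holds the unit interpolation weights at ``centers[j]`` composed
    with the blur kernel (edge samples replicated, so every row still
    sums to one and DC is conserved).  Cached: the IBP loop applies the
    same operator every iteration, and evaluating the blur only at the
    slice centres is AR times cheaper than convolving the whole volume.
    """
    key = (n_hr, round(aspect_ratio, 12), round(fwhm, 12), round(spacing, 12))
    cached = _OBSERVATION_CACHE.get(key)
    if cached is not None:
        return cached
    kernel = slice_profile_kernel(fwhm, spacing)
    centers = slice_center_indices(n_hr, aspect_ratio)
    r = len(kernel) // 2
    w_mat = np.zeros((centers.size, n_hr))
    offsets = np.arange(-r, r + 1)
    for j, c in enumerate(centers):
        i0 = int(np.floor(c))
        frac = c - i0
        for base, wt in ((i0, 1.0 - frac), (i0 + 1, frac)):
            if wt == 0.0:
                continue
            idx = np.clip(base + offsets, 0, n_hr - 1)  # 'nearest' edge handling
            np.add.at(w_mat[j], idx, wt * kernel)
    _OBSERVATION_CACHE[key] = w_mat
    return w_mat


def _apply_along_axis(w_mat: np.ndarray, data: np.ndarray, axis: int) -> np.ndarray:
    moved = np.moveaxis(data, axis, 0)
    out = np.tensordot(w_mat, moved, axes=(1, 0))
    return np.moveaxis(out, 0, axis)


_UPSAMPLE_CACHE: dict = {}


def _upsample_matrix(n_hr: int, n_slices: int, aspect_ratio: float) -> np.ndarray:
    """(n x m) linear interpolation between slice centres, clamped at the
    terminal slices; the exact inverse sampling of slice_center_indices."""
    key = (n_hr, n_slices, round(aspect_ratio, 12))
    cached = _UPSAMPLE_CACHE.get(key)
    if cached is not None:
        return cached
    u = np.clip((np.arange(n_hr, dtype=np.float64) + 0.5) / aspect_ratio - 0.5,
                0.0, n_slices - 1.0)
    j0 = np.floor(u).astype(np.intp)
    w = u - j0
    mat = np.zeros((n_hr, n_slices))
    rows = np.arange(n_hr)
    mat[rows, j0] += 1.0 - w
    mat[rows, np.clip(j0 + 1, 0, n_slices - 1)] += w
    _UPSAMPLE_CACHE[key] = mat
    return mat


def simulate_lr_stack(
    hr: Volume,
    geometry: StackGeometry,
    model: AcquisitionModel,
    seed=None,
    *,
    fill: float = 0.0,
) -> LRStack:
    """Simulate the imaging process on an HR volume.

    The HR grid must be isotropic with spacing equal to the model's
    inplane spacing (the LR stack keeps the HR inplane grid).  ``seed``
    drives the noise (int or Generator); ``fill`` is the intensity used
    for out-of-support resampling during the geometric transform.
    """
    if not hr.is_isotropic:
        raise ValueError("HR volume must be isotropic")
    h = hr.spacing[0]
    # float32 header roundtrips perturb spacing at the 1e-7 level
    if abs(h - model.inplane_spacing) > 1e-6 * max(h, model.inplane_spacing):
        raise ValueError(
            f"HR spacing {h} must equal the model inplane spacing {model.inplane_spacing}"
        )
    ar = model.aspect_ratio
    if ar < 1.0 - 1e-9:
        raise ValueError("aspect ratio must be >= 1")
    stack_frame = transform_volume(hr, geometry, "forward", fill=fill)
    axis = geometry.slice_axis
    n_hr = stack_frame.shape[axis]
    # slice-profile blur + point sampling at the slice centres, fused into
    # one banded operator along the slice axis (mathematically identical
    # to correlating with slice_profile_kernel and then decimating)
    w_mat = _observation_matrix(n_hr, ar, model.blur_fwhm, h)
    data = _apply_along_axis(w_mat, stack_frame.data, axis)
    centers = slice_center_indices(n_hr, ar)
    positions = stack_frame.origin[axis] + centers * h
    stack = LRStack(
        data=data,
        geometry=geometry,
        model=model,
        slice_positions=positions,
        hr_shape=stack_frame.shape,
        hr_spacing=h,
        origin=stack_frame.origin,
    )
    if model.noise_sigma > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        if model.noise_model == "gaussian":
            noisy = stack.data + rng.normal(0.0, model.noise_sigma, stack.data.shape)
        elif model.noise_model == "rician":
            re = stack.data + rng.normal(0.0, model.noise_sigma, stack.data.shape)
            im = rng.normal(0.0, model.noise_sigma, stack.data.shape)
            noisy = np.hypot(re, im)
        else:
            raise ValueError(f"unknown noise model {model.noise_model!r}")
        stack = stack.with_data(noisy)
    return stack


def upsample_stack(
    stack: LRStack,
    target_spacing: float | None = None,
    interpolation: str = "linear",
) -> Volume:
    """Upsample a stack back onto its isotropic HR grid (stack frame).

    Linear interpolation between slice centres along the slice axis
    only; the inplane grid is untouched.  Beyond the first/last slice
    centre values are held at the nearest slice (clamped) so no signal
    is fabricated outside the acquired extent.
    """
    if stack.n_slices < 1 or stack.data.size == 0:
        raise ValueError("cannot upsample an empty stack")
    if target_spacing is None:
        target_spacing = stack.hr_spacing
    if target_spacing > stack.model.slice_thickness + 1e-12:
        raise ValueError("target spacing must not exceed the slice thickness")
    if abs(target_spacing - stack.hr_spacing) > 1e-9:
        raise ValueError("upsampling targets the stack's recorded HR grid spacing")
    axis = stack.geometry.slice_axis
    ar = stack.model.aspect_ratio
    n_hr = stack.hr_shape[axis]
    if interpolation == "linear":
        mat = _upsample_matrix(n_hr, stack.n_slices, ar)
        data = _apply_along_axis(mat, stack.data, axis)
    else:
        u = (np.arange(n_hr, dtype=np.float64) + 0.5) / ar - 0.5
        data = sample_along_axis(
            stack.data, u, axis, interpolation=interpolation, mode="clamp"
        )
    return Volume(
        data=data,
        spacing=(stack.hr_spacing,) * 3,
        origin=stack.origin,
    )
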