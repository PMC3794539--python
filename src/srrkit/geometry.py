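"""Acquisition-geometry planning and per-stack geometric transforms.

Three families of multislice acquisition geometry are planned here:

* ``shifted`` — N stacks translated by sub-voxel steps along the
  slice-select axis, N = slice_thickness / inplane_spacing (rounded), so
  the union of slice positions tiles one slice thickness;
* ``rotational`` — stacks whose slice-select direction is rotated in
  equal angular increments about the volume's z axis (30° steps by
  default, six views covering a half rotation);
* ``orthogonal`` — three stacks sliced along the three grid axes
  (axial / coronal / sagittal), implemented as exact axis permutations.

Each :class:`StackGeometry` carries the forward map (world frame → stack
frame) and its inverse.  Rotations and shifts resample about the volume
centre with linear interpolation; out-of-support samples take a declared
fill value.  Angles live in the half-open range [0°, 180°) because a
multislice stack at θ and θ + 180° samples identical planes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._interp import rotate_about_axis0, shift_along_axis
from .volume import Volume

PLANES = ("axial", "coronal", "sagittal")

# forward permutation: world axes -> stack axes, slice axis moved to front
_PLANE_PERM = {"axial": (0, 1, 2), "coronal": (1, 0, 2), "sagittal": (2, 0, 1)}
_PLANE_SLICE_AXIS_WORLD = {"axial": 0, "coronal": 1, "sagittal": 2}

ROTATION_AXIS = 0  # rotations are about the volume's z axis


@dataclass(frozen=True)
class StackGeometry:
    """One LR view's transform T_k (shift, rotation, or axis permutation).

    ``slice_axis`` is the slice-select axis *of the stack-frame array*.
    Exactly the fields of the geometry's kind are populated.
    """

    kind: str
    index: int = 0
    shift_mm: Optional[float] = None
    rotation_deg: Optional[float] = None
    plane: Optional[str] = None
    slice_axis: int = 0

    def __post_init__(self) -> None:
        if self.kind == "shifted":
            if self.shift_mm is None or self.rotation_deg is not None or self.plane is not None:
                raise ValueError("shifted geometry populates shift_mm only")
        elif self.kind == "rotational":
            if self.rotation_deg is None or self.shift_mm is not None or self.plane is not None:
                raise ValueError("rotational geometry populates rotation_deg only")
            if not (0.0 <= self.rotation_deg < 180.0):
                raise ValueError(f"rotation_deg must lie in [0, 180), got {self.rotation_deg}")
            if self.slice_axis == ROTATION_AXIS:
                raise ValueError("rotational slice axis must be perpendicular to the rotation axis")
        elif self.kind == "orthogonal":
            if self.plane not in PLANES:
                raise ValueError(f"orthogonal geometry needs plane in {PLANES}, got {self.plane}")
            if self.shift_mm is not None or self.rotation_deg is not None:
                raise ValueError("orthogonal geometry populates plane only")
            if self.slice_axis != 0:
                raise ValueError("orthogonal stacks carry their slice axis at position 0")
        else:
            raise ValueError(f"unknown geometry kind {self.kind!r}")

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "index": self.index, "slice_axis": self.slice_axis}
        if self.shift_mm is not None:
            d["shift_mm"] = self.shift_mm
        if self.rotation_deg is not None:
            d["rotation_deg"] = self.rotation_deg
        if self.plane is not None:
            d["plane"] = self.plane
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StackGeometry":
        return cls(**d)


@dataclass
class AcquisitionPlan:
    """An ordered set of stack geometries sharing one voxel geometry.

    ``aspect_ratio`` is the AR of "1 : 1 : N" notation, i.e. slice
    thickness over inplane voxel size; ``per_stack_minutes`` is the
    scan time of one 2-D multislice stack.
    """

    geometries: list[StackGeometry]
    slice_thickness: float
    inplane_spacing: float
    per_stack_minutes: float = 3.0

    def __post_init__(self) -> None:
        if not self.geometries:
            raise ValueError("a plan needs at least one stack geometry")
        if self.inplane_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("spacings must be positive")
        if self.aspect_ratio < 1.0 - 1e-9:
            raise ValueError("aspect ratio (thickness / inplane) must be >= 1")

    @property
    def aspect_ratio(self) -> float:
        return self.slice_thickness / self.inplane_spacing

    @property
    def n_stacks(self) -> int:
        return len(self.geometries)

    def to_dict(self) -> dict:
        return {
            "geometries": [g.to_dict() for g in self.geometries],
            "slice_thickness": self.slice_thickness,
            "inplane_spacing": self.inplane_spacing,
            "per_stack_minutes": self.per_stack_minutes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionPlan":
        d = dict(d)
        d["geometries"] = [StackGeometry.from_dict(g) for g in d["geometries"]]
        return cls(**d)


# ---------------------------------------------------------------- planners


def plan_shifted(
    slice_thickness: float,
    inplane_spacing: float,
    *,
    slice_axis: int = 0,
    per_stack_minutes: float = 3.0,
) -> AcquisitionPlan:
    """Sub-voxel-shifted plan: N = round(thickness / inplane) stacks at
    steps of thickness / N along the slice axis."""
    if slice_thickness <= 0 or inplane_spacing <= 0:
        raise ValueError("spacings must be positive")
    if slice_thickness < inplane_spacing - 1e-12:
        raise ValueError("slice thickness must be >= inplane spacing")
    n = max(1, round(slice_thickness / inplane_spacing))
    step = slice_thickness / n
    geoms = [
        StackGeometry(kind="shifted", index=k, shift_mm=k * step, slice_axis=slice_axis)
        for k in range(n)
    ]
    return AcquisitionPlan(geoms, slice_thickness, inplane_spacing, per_stack_minutes)


def plan_rotational(
    slice_thickness: float,
    inplane_spacing: float,
    *,
    n_views: int = 6,
    increment_deg: float = 30.0,
    per_stack_minutes: float = 3.0,
) -> AcquisitionPlan:
    """Rotational plan: views at k * increment about the z axis,
    k = 0..n_views-1; the slice-select direction sweeps the xy plane."""
    if n_views < 1:
        raise ValueError("need at least one view")
    if n_views * increment_deg > 180.0 + 1e-9:
        raise ValueError(
            f"{n_views} views at {increment_deg} deg exceed a half rotation; "
            "views would duplicate sampled planes"
        )
    geoms = [
        StackGeometry(kind="rotational", index=k, rotation_deg=k * increment_deg, slice_axis=1)
        for k in range(n_views)
    ]
    return AcquisitionPlan(geoms, slice_thickness, inplane_spacing, per_stack_minutes)


def plan_orthogonal(
    slice_thickness: float,
    inplane_spacing: float,
    *,
    per_stack_minutes: float = 3.0,
) -> AcquisitionPlan:
    """Three stacks sliced along the three distinct grid axes."""
    geoms = [
        StackGeometry(kind="orthogonal", index=k, plane=plane, slice_axis=0)
        for k, plane in enumerate(PLANES)
    ]
    return AcquisitionPlan(geoms, slice_thickness, inplane_spacing, per_stack_minutes)


# ---------------------------------------------------------------- transforms


def plane_permutation(plane: str, direction: str = "forward") -> tuple[int, int, int]:
    """Axis permutation mapping world axes to stack axes (or back)."""
    perm = _PLANE_PERM[plane]
    if direction == "forward":
        return perm
    return tuple(int(i) for i in np.argsort(perm))


def transform_volume(
    volume: Volume,
    geometry: StackGeometry,
    direction: str = "forward",
    *,
    interpolation: str = "linear",
    fill: float = 0.0,
) -> Volume:
    """Apply T_k (forward: world → stack frame) or its inverse.

    Orthogonal permutations are exact index permutations (no
    interpolation).  Shifts and rotations resample about the volume
    centre; samples falling outside the source grid take ``fill``.
    """
    if direction not in ("forward", "inverse"):
        raise ValueError(f"direction must be forward or inverse, got {direction!r}")
    if geometry.kind == "orthogonal":
        perm = plane_permutation(geometry.plane, direction)
        data = np.ascontiguousarray(np.transpose(volume.data, perm))
        spacing = tuple(volume.spacing[p] for p in perm)
        origin = tuple(volume.origin[p] for p in perm)
        return Volume(data=data, spacing=spacing, origin=origin)
    if geometry.kind == "shifted":
        axis = geometry.slice_axis
        offset = geometry.shift_mm / volume.spacing[axis]
        if direction == "inverse":
            offset = -offset
        data = shift_along_axis(
            volume.data, offset, axis, interpolation=interpolation, fill=fill
        )
        return volume.with_data(data)
    if geometry.kind == "rotational":
        if abs(volume.spacing[1] - volume.spacing[2]) > 1e-9:
            raise ValueError("rotational transforms need isotropic inplane (y, x) spacing")
        angle = geometry.rotation_deg if direction == "forward" else -geometry.rotation_deg
        data = rotate_about_axis0(volume.data, angle, interpolation=interpolation, fill=fill)
        return volume.with_data(data)
    raise ValueError(f"unknown geometry kind {geometry.kind!r}")


def transform_support(shape: tuple[int, int, int], geometry: StackGeometry, direction: str) -> np.ndarray:
    """Boolean mask of voxels whose resampled value uses only in-grid data."""
    ones = Volume(np.ones(shape), spacing=(1.0, 1.0, 1.0))
    out = transform_volume(ones, geometry, direction, interpolation="linear", fill=0.0)
    return out.data > 1.0 - 1e-6


def estimate_acquisition_time(plan: AcquisitionPlan) -> float:
    """Total scan time in minutes: one per-stack time per planned stack."""
    return plan.n_stacks * plan.per_stack_minutes
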