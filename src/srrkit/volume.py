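"""3-D scalar volumes with physical spacing, and NIfTI-1 I/O.

Array convention used throughout the package: axis order ``(z, y, x)``,
0-based indices, voxel centre of index ``i`` at ``origin + i * spacing``
(all in millimetres).  On disk volumes are stored as NIfTI-1 with the
fastest-varying axis first, so arrays are transposed to ``(x, y, z)``
order when written and transposed back when read; spacing lands in the
header ``pixdim`` and the origin in the affine translation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np

AXIS_LABELS = ("z", "y", "x")


@dataclass
class Volume:
    """A 3-D scalar intensity grid with physical geometry.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Intensities in arbitrary units; must be finite.
    spacing : tuple of float
        Per-axis voxel size in mm, ``(z, y, x)`` order, all > 0.
    origin : tuple of float
        Physical coordinate (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_labels: tuple[str, str, str] = AXIS_LABELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"every axis must have >= 1 voxel, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")

    # -- convenience -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_isotropic(self) -> bool:
        s = self.spacing
        return abs(s[0] - s[1]) < 1e-9 and abs(s[1] - s[2]) < 1e-9

    @property
    def dynamic_range(self) -> float:
        return float(self.data.max() - self.data.min())

    def center_mm(self) -> np.ndarray:
        """Physical coordinate of the grid centre (mm, (z, y, x))."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) / 2.0 * np.asarray(
            self.spacing
        )

    def index_to_mm(self, idx) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def mm_to_index(self, pos_mm) -> np.ndarray:
        return (np.asarray(pos_mm, dtype=float) - np.asarray(self.origin)) / np.asarray(
            self.spacing
        )

    def copy(self) -> "Volume":
        return replace(self, data=self.data.copy())

    def with_data(self, data: np.ndarray) -> "Volume":
        """New volume on the same grid with different intensities."""
        return replace(self, data=np.asarray(data, dtype=np.float64))


def write_volume(volume: Volume, path) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz)."""
    # disk order (x, y, z): reverse our (z, y, x) axes
    arr = np.ascontiguousarray(np.transpose(volume.data, (2, 1, 0)))
    sx, sy, sz = volume.spacing[2], volume.spacing[1], volume.spacing[0]
    ox, oy, oz = volume.origin[2], volume.origin[1], volume.origin[0]
    affine = np.diag([sx, sy, sz, 1.0])
    affine[:3, 3] = (ox, oy, oz)
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))


def read_volume(path) -> Volume:
    """Read a NIfTI-1 image as a :class:`Volume`.

    Raises
    ------
    ValueError
        If the image is not 3-D (trailing singleton dimensions are squeezed).
    """
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    while arr.ndim > 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    if arr.ndim != 3:
        raise ValueError(f"expected a 3-D image, got shape {arr.shape} from {path}")
    zooms = img.header.get_zooms()[:3]
    affine = img.affine
    origin_xyz = affine[:3, 3]
    data = np.transpose(arr, (2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = (float(origin_xyz[2]), float(origin_xyz[1]), float(origin_xyz[0]))
    return Volume(data=data, spacing=spacing, origin=origin)
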