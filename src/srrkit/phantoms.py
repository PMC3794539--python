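"""Digital high-resolution ground-truth phantoms and noise injection.

Two phantoms are generated:

* a *resolution phantom* — parallel sealed capillary tubes (signal voids
  over their full outer diameter) immersed in a bright homogeneous
  contrast-agent bath, optionally tilted obliquely to the grid axes; a
  line profile across the tube row probes whether a reconstruction
  resolves the tubes;
* a *biological phantom* — nested smoothed ellipsoids standing in for an
  ex-vivo mouse embryo: a dark surround (Fluorinert analogue), a body of
  uniform tissue, a bright liver-like organ with a sharp closed boundary
  for edge-spread measurements, a homogeneous brain-like region for SNR
  ROIs, plus thin bright shells and rods (rib analogues, 1–3 voxels wide).

Cylinder/ellipsoid membership at voxel boundaries is computed on a
3x3x3 sub-voxel grid and averaged, which approximates the scanner's
intrinsic partial-volume effect; hard binary masks would alias and
contaminate edge-width measurements.  All generators are bit
reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .volume import Volume

_SUBGRID = np.stack(
    np.meshgrid(*([(np.arange(3) - 1.0) / 3.0] * 3), indexing="ij"), axis=-1
).reshape(-1, 3)  # 27 sub-voxel offsets in voxel units


@dataclass
class PhantomSpec:
    """Construction parameters of a digital phantom.

    Lengths in mm, intensities in arbitrary units.  The defaults mirror
    the quartz-capillary resolution phantom: five tubes of 0.5 mm inner /
    0.7 mm outer diameter with 0.7 mm wall-to-wall separation in a bright
    bath.  ``orientation`` tilts the tubes: (angle in the xy plane about
    z, then angle in the yz plane about x), in degrees.
    """

    kind: str = "resolution"
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (0.203, 0.203, 0.203)
    tube_inner_diameter: float = 0.5
    tube_outer_diameter: float = 0.7
    tube_separation: float = 0.7
    tube_length_mm: Optional[float] = None  # None: tubes span the FOV
    n_tubes: int = 5
    orientation: tuple[float, float] = (0.0, 0.0)
    background_intensity: float = 100.0
    void_intensity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("resolution", "biological"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if not (self.tube_outer_diameter >= self.tube_inner_diameter > 0):
            raise ValueError("need tube_outer_diameter >= tube_inner_diameter > 0")
        if self.tube_separation <= 0:
            raise ValueError("tube_separation must be positive")
        if self.n_tubes < 0:
            raise ValueError("n_tubes must be >= 0")

    @property
    def pitch_mm(self) -> float:
        """Centre-to-centre tube distance (outer walls separated by
        ``tube_separation``)."""
        return self.tube_outer_diameter + self.tube_separation


# ------------------------------------------------------------- helpers


def _rotation_matrix(orientation_deg: tuple[float, float]) -> np.ndarray:
    """Rotation applied to the phantom, in (z, y, x) component order.

    First a rotation by ``angle_xy`` in the xy plane (about z), then by
    ``angle_yz`` in the yz plane (about x).
    """
    a_xy, a_yz = np.deg2rad(orientation_deg[0]), np.deg2rad(orientation_deg[1])
    c1, s1 = np.cos(a_xy), np.sin(a_xy)
    c2, s2 = np.cos(a_yz), np.sin(a_yz)
    # matrices act on (x, y, z) column vectors
    rz = np.array([[c1, -s1, 0.0], [s1, c1, 0.0], [0.0, 0.0, 1.0]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, c2, -s2], [0.0, s2, c2]])
    r_xyz = rx @ rz
    flip = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
    return flip @ r_xyz @ flip  # conjugate into (z, y, x) ordering


def _coord_grids(shape, spacing) -> list[np.ndarray]:
    return np.meshgrid(
        *[np.arange(n, dtype=np.float64) * s for n, s in zip(shape, spacing)],
        indexing="ij",
    )


def _cylinder_fraction(
    coords: list[np.ndarray],
    center: np.ndarray,
    axis_u: np.ndarray,
    radius: float,
    half_length: Optional[float],
    spacing: np.ndarray,
) -> np.ndarray:
    """Fraction of each voxel inside a (capped) cylinder, 3x3x3 supersampled
    only in the band of voxels straddling the surface."""
    d = [c - ctr for c, ctr in zip(coords, center)]
    t = d[0] * axis_u[0] + d[1] * axis_u[1] + d[2] * axis_u[2]
    rad2 = d[0] ** 2 + d[1] ** 2 + d[2] ** 2 - t**2
    rad = np.sqrt(np.maximum(rad2, 0.0))
    band = float(np.linalg.norm(spacing))  # voxel diagonal
    if half_length is None:
        inside = rad <= radius
        boundary = np.abs(rad - radius) < band
    else:
        inside = (rad <= radius) & (np.abs(t) <= half_length)
        boundary = (np.abs(rad - radius) < band) & (np.abs(t) <= half_length + band)
        boundary |= (rad <= radius + band) & (np.abs(np.abs(t) - half_length) < band)
    frac = inside.astype(np.float64)
    idx = np.nonzero(boundary)
    if idx[0].size:
        pts = np.stack([coords[a][idx] for a in range(3)], axis=-1)  # (m, 3) mm
        sub = pts[:, None, :] + _SUBGRID[None, :, :] * spacing[None, None, :]
        dd = sub - center[None, None, :]
        tt = dd @ axis_u
        rr2 = np.einsum("mki,mki->mk", dd, dd) - tt**2
        ins = rr2 <= radius**2
        if half_length is not None:
            ins &= np.abs(tt) <= half_length
        frac[idx] = ins.mean(axis=1)
    return frac


def _ellipsoid_fraction(
    coords: list[np.ndarray],
    center: np.ndarray,
    semi: np.ndarray,
    spacing: np.ndarray,
) -> np.ndarray:
    """Fraction of each voxel inside an axis-aligned ellipsoid (supersampled
    at the surface band)."""
    q = sum(((c - ctr) / r) ** 2 for c, ctr, r in zip(coords, center, semi))
    rq = np.sqrt(q)
    band = float(np.linalg.norm(spacing)) / float(np.min(semi))
    inside = q <= 1.0
    boundary = np.abs(rq - 1.0) < band
    frac = inside.astype(np.float64)
    idx = np.nonzero(boundary)
    if idx[0].size:
        pts = np.stack([coords[a][idx] for a in range(3)], axis=-1)
        sub = pts[:, None, :] + _SUBGRID[None, :, :] * spacing[None, None, :]
        qq = (((sub - center[None, None, :]) / semi[None, None, :]) ** 2).sum(axis=-1)
        frac[idx] = (qq <= 1.0).mean(axis=1)
    return frac


def _paint(data: np.ndarray, frac: np.ndarray, intensity: float) -> None:
    data *= 1.0 - frac
    data += intensity * frac


# ------------------------------------------------- resolution phantom


@dataclass
class ResolutionLayout:
    """Geometry bookkeeping for a generated resolution phantom."""

    tube_centers_mm: np.ndarray  # (n_tubes, 3) in (z, y, x)
    tube_axis: np.ndarray  # unit vector u along the tubes
    row_axis: np.ndarray  # unit vector v across the tube row
    profile_start_mm: np.ndarray
    profile_end_mm: np.ndarray
    n_tubes: int
    pitch_mm: float


def resolution_phantom_layout(spec: PhantomSpec) -> ResolutionLayout:
    """Tube centres and the line-profile segment across the tube row."""
    shape = np.asarray(spec.grid_shape, dtype=float)
    spacing = np.asarray(spec.spacing, dtype=float)
    center = (shape - 1.0) / 2.0 * spacing
    rot = _rotation_matrix(spec.orientation)
    u = rot @ np.array([0.0, 1.0, 0.0])  # tubes along y before tilting
    # The tube row runs across the slice-select (z) axis: it is the
    # component of z orthogonal to the tilted tube axis.  This keeps the
    # row as close to the slice axis as the tilt permits — the worst
    # case for through-plane partial-volume mixing, which is what the
    # oblique orientation probes.  (For the untilted phantom this is
    # exactly z.)
    zhat = np.array([1.0, 0.0, 0.0])  # z in (z, y, x) component order
    v = zhat - (zhat @ u) * u
    nv = np.linalg.norm(v)
    if nv < 1e-6:  # tubes along z: any inplane row direction works
        v = rot @ zhat
    else:
        v = v / nv
    n = spec.n_tubes
    offsets = (np.arange(n) - (n - 1) / 2.0) * spec.pitch_mm if n else np.zeros(0)
    centers = center[None, :] + offsets[:, None] * v[None, :]
    half_span = (max(n - 1, 0) / 2.0) * spec.pitch_mm
    ext = half_span + spec.pitch_mm
    return ResolutionLayout(
        tube_centers_mm=centers,
        tube_axis=u,
        row_axis=v,
        profile_start_mm=center - ext * v,
        profile_end_mm=center + ext * v,
        n_tubes=n,
        pitch_mm=spec.pitch_mm,
    )


def make_resolution_phantom(spec: PhantomSpec) -> Volume:
    """Render the tube phantom: uniform bright bath with dark parallel
    cylinders (full outer diameter rendered as void — sealed air-filled
    walls and lumen both yield no signal).

    Raises
    ------
    ValueError
        If spec.kind is not "resolution" or a tube does not fit in the FOV
        (the error names the offending tube index).
    """
    if spec.kind != "resolution":
        raise ValueError(f"spec.kind must be 'resolution', got {spec.kind!r}")
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    layout = resolution_phantom_layout(spec)
    radius = spec.tube_outer_diameter / 2.0
    half_len = None if spec.tube_length_mm is None else spec.tube_length_mm / 2.0

    fov_lo = -0.5 * spacing
    fov_hi = (np.asarray(shape) - 0.5) * spacing
    # a cylinder's extent about an axis point is radius * sqrt(1 - u_a^2)
    # along grid axis a (the radius acts only perpendicular to the tube)
    perp = radius * np.sqrt(np.clip(1.0 - layout.tube_axis**2, 0.0, 1.0))
    for i, c in enumerate(layout.tube_centers_mm):
        probes = [c] if half_len is None else [c - half_len * layout.tube_axis,
                                               c + half_len * layout.tube_axis]
        for p in probes:
            if np.any(p - perp < fov_lo) or np.any(p + perp > fov_hi):
                raise ValueError(f"tube {i} exceeds the field of view")

    data = np.full(shape, spec.background_intensity, dtype=np.float64)
    if spec.n_tubes:
        coords = _coord_grids(shape, spacing)
        total = np.zeros(shape, dtype=np.float64)
        for c in layout.tube_centers_mm:
            total += _cylinder_fraction(coords, c, layout.tube_axis, radius, half_len, spacing)
        np.clip(total, 0.0, 1.0, out=total)
        _paint(data, total, spec.void_intensity)
    return Volume(data=data, spacing=tuple(spacing))


# ------------------------------------------------- biological phantom


@dataclass
class BiologicalLayout:
    """ROIs and edge-profile segments derived from the generator's own
    region map (never hand-picked), in voxel indices / mm."""

    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    intensities: dict
    signal_roi: tuple[tuple[int, int, int], tuple[int, int, int]]  # (corner, size)
    noise_roi: tuple[tuple[int, int, int], tuple[int, int, int]]
    high_roi: tuple[tuple[int, int, int], tuple[int, int, int]]
    low_roi: tuple[tuple[int, int, int], tuple[int, int, int]]
    edge_segments: list[tuple[np.ndarray, np.ndarray]]  # (start_mm, end_mm)
    edge_normals: list[np.ndarray]
    intensity_range: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "spacing": list(self.spacing),
            "intensities": self.intensities,
            "signal_roi": [list(self.signal_roi[0]), list(self.signal_roi[1])],
            "noise_roi": [list(self.noise_roi[0]), list(self.noise_roi[1])],
            "high_roi": [list(self.high_roi[0]), list(self.high_roi[1])],
            "low_roi": [list(self.low_roi[0]), list(self.low_roi[1])],
            "edge_segments": [[list(map(float, s)), list(map(float, e))]
                              for s, e in self.edge_segments],
            "intensity_range": list(self.intensity_range),
        }


_INTENSITIES = {
    "air": 0.0,
    "body": 60.0,
    "liver": 100.0,
    "brain": 85.0,
    "fine": 120.0,
}

# organ geometry as fractions of the grid shape, (z, y, x); offsets and
# sizes are chosen so that the liver's boundary-normal edge profiles fit
# inside body tissue without touching the brain, ribs or rods
_BODY_SEMI = (0.30, 0.34, 0.32)
_LIVER_OFF = (-0.07, 0.045, 0.06)
_LIVER_SEMI = (0.125, 0.14, 0.155)
_BRAIN_OFF = (0.15, -0.10, -0.12)
_BRAIN_RADIUS = 0.105  # of the smallest grid dimension
_LOW_ROI_OFF = (-0.08, -0.16, -0.08)  # plain body tissue clear of all organs


def _fibonacci_directions(n: int) -> np.ndarray:
    """n roughly uniform unit vectors on the sphere (deterministic)."""
    i = np.arange(n, dtype=np.float64) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack(
        [np.cos(phi), np.sin(phi) * np.sin(theta), np.sin(phi) * np.cos(theta)], axis=-1
    )


def _organ_geometry(grid_shape, spacing, seed):
    shape = np.asarray(grid_shape, dtype=float)
    sp = np.asarray(spacing, dtype=float)
    center = (shape - 1.0) / 2.0 * sp
    ext = shape * sp
    rng = np.random.default_rng(seed)
    body_semi = np.asarray(_BODY_SEMI) * ext * rng.uniform(0.98, 1.02, 3)
    liver_c = center + np.asarray(_LIVER_OFF) * ext
    liver_semi = np.asarray(_LIVER_SEMI) * ext * rng.uniform(0.98, 1.02, 3)
    brain_c = center + np.asarray(_BRAIN_OFF) * ext
    brain_r = _BRAIN_RADIUS * float(np.min(ext)) * rng.uniform(0.98, 1.02)
    return center, ext, body_semi, liver_c, liver_semi, brain_c, brain_r


def biological_phantom_layout(grid_shape, spacing, seed: int = 0, n_profiles: int = 20) -> BiologicalLayout:
    """ROIs (9x9x9 by default placement) and boundary-normal edge segments
    for the biological phantom with the same parameters."""
    grid_shape = tuple(int(n) for n in grid_shape)
    spacing = tuple(float(s) for s in np.broadcast_to(np.asarray(spacing, float), (3,)))
    if min(grid_shape) < 64:
        raise ValueError(
            f"grid {grid_shape} too small to host the 9x9x9 ROIs; need >= 64 per axis"
        )
    center, ext, body_semi, liver_c, liver_semi, brain_c, brain_r = _organ_geometry(
        grid_shape, spacing, seed
    )
    sp = np.asarray(spacing)
    shape = np.asarray(grid_shape)

    def roi_at(pos_mm, size=9):
        idx = np.rint(pos_mm / sp).astype(int) - size // 2
        idx = np.clip(idx, 0, shape - size)
        return (tuple(int(i) for i in idx), (size, size, size))

    signal_roi = roi_at(brain_c)
    high_roi = roi_at(liver_c)
    low_roi = roi_at(center + np.asarray(_LOW_ROI_OFF) * ext)
    # background-noise ROI at the centre of the low-x face: in air, inside
    # the acquired FOV of every stack (rotated stacks lack support only at
    # the grid corners), clear of the body surface even on small grids
    noise_corner = (
        int(grid_shape[0] // 2 - 4),
        int(grid_shape[1] // 2 - 4),
        max(1, int(0.02 * grid_shape[2])),
    )
    noise_roi = (noise_corner, (9, 9, 9))

    # boundary-normal profiles across the liver surface; the window must be
    # long enough to host a heavily blurred edge (several voxels of 10-90%
    # rise), but is capped so it never leaves the surrounding body tissue
    dirs = _fibonacci_directions(n_profiles)
    mean_semi = float(np.mean(liver_semi))
    half_nominal = 0.32 * mean_semi + 2.5 * float(np.mean(sp))
    segments, normals = [], []
    safe_body = 0.94 * body_semi
    for d in dirs:
        t = 1.0 / np.sqrt(np.sum((d / liver_semi) ** 2))
        p = liver_c + t * d
        n = (p - liver_c) / liver_semi**2
        n = n / np.linalg.norm(n)
        # largest half-length keeping the outer end inside 0.97 x body
        a = float(np.sum((n / safe_body) ** 2))
        b = 2.0 * float(np.sum(n * (p - center) / safe_body**2))
        c = float(np.sum(((p - center) / safe_body) ** 2)) - 1.0
        h_max = (-b + np.sqrt(max(b * b - 4 * a * c, 0.0))) / (2 * a)
        half_mm = min(half_nominal, max(h_max, 1e-6))
        segments.append((p - half_mm * n, p + half_mm * n))
        normals.append(n)

    return BiologicalLayout(
        grid_shape=grid_shape,
        spacing=spacing,
        intensities=dict(_INTENSITIES),
        signal_roi=signal_roi,
        noise_roi=noise_roi,
        high_roi=high_roi,
        low_roi=low_roi,
        edge_segments=segments,
        edge_normals=normals,
        intensity_range=(_INTENSITIES["air"], _INTENSITIES["fine"]),
    )


def make_biological_phantom(grid_shape, spacing, seed: int = 0) -> Volume:
    """Render the embryo-like phantom (see module docstring).

    Deterministic for a fixed seed: the seed only jitters organ semi-axes
    by a few percent, so the ROIs of :func:`biological_phantom_layout`
    stay inside their organs.
    """
    layout = biological_phantom_layout(grid_shape, spacing, seed)  # validates size
    grid_shape = layout.grid_shape
    spacing = layout.spacing
    center, ext, body_semi, liver_c, liver_semi, brain_c, brain_r = _organ_geometry(
        grid_shape, spacing, seed
    )
    sp = np.asarray(spacing)
    coords = _coord_grids(grid_shape, spacing)
    data = np.full(grid_shape, _INTENSITIES["air"], dtype=np.float64)

    _paint(data, _ellipsoid_fraction(coords, center, body_semi, sp), _INTENSITIES["body"])

    # thin rods (1-3 voxels wide) along y, low in the body
    rod_z = center[0] - 0.24 * ext[0]
    u = np.array([0.0, 1.0, 0.0])
    for xoff, r_vox in zip((-0.16, -0.08, 0.0), (0.6, 1.0, 1.4)):
        c = np.array([rod_z, center[1], center[2] + xoff * ext[2]])
        frac = _cylinder_fraction(coords, c, u, r_vox * sp[2], 0.10 * ext[1], sp)
        _paint(data, frac, _INTENSITIES["fine"])

    # rib-analogue shell: band between two scalings of the body ellipsoid,
    # restricted to the upper-z / +y octant away from organs and profiles
    outer = _ellipsoid_fraction(coords, center, 0.86 * body_semi, sp)
    inner = _ellipsoid_fraction(coords, center, 0.80 * body_semi, sp)
    shell = np.clip(outer - inner, 0.0, 1.0)
    region = (coords[0] > center[0] + 0.20 * ext[0]) & (coords[1] > center[1] + 0.06 * ext[1])
    _paint(data, shell * region, _INTENSITIES["fine"])

    _paint(data, _ellipsoid_fraction(coords, liver_c, liver_semi, sp), _INTENSITIES["liver"])
    _paint(
        data,
        _ellipsoid_fraction(coords, brain_c, np.full(3, brain_r), sp),
        _INTENSITIES["brain"],
    )
    return Volume(data=data, spacing=spacing)


# -------------------------------------------------------------- noise


def add_noise(volume: Volume, sigma: float, model: str = "gaussian", seed=None) -> Volume:
    """Add acquisition noise.

    ``gaussian`` adds zero-mean noise of standard deviation ``sigma``;
    ``rician`` returns the magnitude of (signal + complex Gaussian noise
    of per-channel sd ``sigma``), the correct model for magnitude MR
    images.  ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if sigma < 0:
        raise ValueError(f"noise sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return volume.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if model == "gaussian":
        data = volume.data + rng.normal(0.0, sigma, volume.shape)
    elif model == "rician":
        re = volume.data + rng.normal(0.0, sigma, volume.shape)
        im = rng.normal(0.0, sigma, volume.shape)
        data = np.hypot(re, im)
    else:
        raise ValueError(f"unknown noise model {model!r}")
    return volume.with_data(data)
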