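"""Grids, rigid transforms, displacement fields, and spatial primitives.

Every image in the planning chain lives on an axis-aligned right-handed grid:
the physical position (mm) of voxel ``(i, j, k)`` is ``origin + index * spacing``.
Axis ``a`` of the data array corresponds to component ``a`` of ``spacing`` and
``origin``.  Physical millimetre coordinates are the common frame between the
CT grid (sub-millimetre in-plane) and the SPECT grid (3–5 mm cubic voxels);
all geometry below is expressed in that frame.  Oblique or sheared grids are
not supported and must be resampled upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation


class GridMismatchError(ValueError):
    """Two images expected on the same grid are not."""


class DegenerateAxisError(ValueError):
    """An image axis is too short for the requested operation."""


def _triplet(x) -> np.ndarray:
    a = np.atleast_1d(np.asarray(x, dtype=float)).ravel()
    if a.size == 1:
        a = np.repeat(a, 3)
    if a.size != 3:
        raise ValueError(f"expected a scalar or 3-vector, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class Grid:
    """Shape, spacing (mm) and origin (mm) of an axis-aligned voxel lattice."""

    shape: tuple
    spacing: tuple
    origin: tuple

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in _triplet(self.spacing))
        origin = tuple(float(o) for o in _triplet(self.origin))
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be three positive ints, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"grid spacing must be positive, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def spacing_mm(self) -> np.ndarray:
        return np.asarray(self.spacing, dtype=float)

    @property
    def origin_mm(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical coordinates of the last voxel centre."""
        return self.origin_mm + (np.asarray(self.shape) - 1) * self.spacing_mm

    @property
    def center_mm(self) -> np.ndarray:
        return 0.5 * (self.origin_mm + self.extent_mm)

    def index_grid(self) -> np.ndarray:
        """Dense (nx, ny, nz, 3) array of voxel indices as floats."""
        ax = [np.arange(n, dtype=float) for n in self.shape]
        return np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)

    def axes_mm(self) -> list:
        return [self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
                for a in range(3)]

    def physical_points(self) -> np.ndarray:
        """All voxel-centre positions, flattened to (N, 3) mm."""
        pts = self.index_grid() * self.spacing_mm + self.origin_mm
        return pts.reshape(-1, 3)

    def physical_to_index(self, pts_mm: np.ndarray) -> np.ndarray:
        return (np.asarray(pts_mm, dtype=float) - self.origin_mm) / self.spacing_mm

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * self.spacing_mm + self.origin_mm

    def isclose(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=tol)
                and np.allclose(self.origin, other.origin, atol=tol))


@dataclass
class Volume:
    """A 3D scalar image on an axis-aligned grid (CT HU, SPECT counts, doses...)."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got ndim={self.data.ndim}")
        if any(s < 2 for s in self.data.shape):
            raise DegenerateAxisError(
                f"Volume needs >= 2 voxels per axis, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in _triplet(self.spacing))
        self.origin = tuple(float(o) for o in _triplet(self.origin))
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def grid(self) -> Grid:
        return Grid(self.data.shape, self.spacing, self.origin)

    @property
    def spacing_mm(self) -> np.ndarray:
        return np.asarray(self.spacing, dtype=float)

    @property
    def origin_mm(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)

    def same_grid(self, other, tol: float = 1e-6) -> bool:
        return self.grid.isclose(_grid_of(other), tol)

    def astype(self, dtype) -> "Volume":
        return Volume(self.data.astype(dtype), self.spacing, self.origin)

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing, self.origin)

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(np.asarray(data), self.spacing, self.origin)


class LabelMask(Volume):
    """A binary Volume naming one structure (liver, kidney, cord...).

    Stored as uint8 in {0, 1}.  Masks fed to distance/Dice/DVH operations must
    be nonempty; emptiness is checked at the point of use, not construction,
    so that intermediate empty warps can be detected and reported.
    """

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.dtype != np.uint8:
            if data.dtype == bool:
                data = data.astype(np.uint8)
            else:
                vals = np.unique(data)
                if not np.all(np.isin(vals, (0, 1))):
                    raise ValueError("LabelMask values must be in {0, 1}")
                data = data.astype(np.uint8)
        self.data = data
        super().__post_init__()

    @property
    def bool_data(self) -> np.ndarray:
        return self.data.astype(bool)

    def count(self) -> int:
        return int(self.data.sum())

    def centroid_mm(self) -> np.ndarray:
        """Physical centroid of the mask voxels (mm)."""
        if self.count() == 0:
            raise ValueError("centroid of an empty mask is undefined")
        idx = np.argwhere(self.data > 0).mean(axis=0)
        return self.grid.index_to_physical(idx)

    def copy(self) -> "LabelMask":
        return LabelMask(self.data.copy(), self.spacing, self.origin)


@dataclass
class DisplacementField:
    """Dense per-voxel 3-vector field (mm) on the fixed-image grid.

    ``field(x)`` maps the fixed-space point ``x`` to the moving-space point
    ``x + field(x)``: the carrier of the atlas-to-subject mapping produced by
    demons registration.
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError(
                f"DisplacementField data must be (nx,ny,nz,3), got {self.data.shape}")
        self.spacing = tuple(float(s) for s in _triplet(self.spacing))
        self.origin = tuple(float(o) for o in _triplet(self.origin))
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("DisplacementField must be finite everywhere")

    @property
    def grid(self) -> Grid:
        return Grid(self.data.shape[:3], self.spacing, self.origin)

    @property
    def spacing_mm(self) -> np.ndarray:
        return np.asarray(self.spacing, dtype=float)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.data, axis=-1)

    @classmethod
    def zeros(cls, grid: Grid) -> "DisplacementField":
        return cls(np.zeros(tuple(grid.shape) + (3,)), grid.spacing, grid.origin)


@dataclass
class RigidTransform3D:
    """Six-parameter rigid map between SPECT and CT physical space.

    Rotation is three Euler angles in degrees ``(rx, ry, rz)`` applied
    intrinsically Z then Y then X (matrix ``Rz @ Ry @ Rx``); translation is in
    mm; ``center`` is the rotation centre in physical mm.  A point maps as
    ``p' = R (p - center) + center + translation``.
    """

    rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation_deg = _triplet(self.rotation_deg)
        self.translation_mm = _triplet(self.translation_mm)
        self.center_mm = _triplet(self.center_mm)

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "RigidTransform3D":
        return cls(np.zeros(3), np.zeros(3), center)

    @classmethod
    def from_params(cls, params, center=(0.0, 0.0, 0.0)) -> "RigidTransform3D":
        """Build from the optimizer's 6-vector (rx, ry, rz, tx, ty, tz)."""
        p = np.asarray(params, dtype=float).ravel()
        if p.size != 6:
            raise ValueError(f"expected a 6-vector, got size {p.size}")
        return cls(p[:3], p[3:], center)

    @property
    def params(self) -> np.ndarray:
        """The 6-vector (rx, ry, rz, tx, ty, tz) in degrees and mm."""
        return np.concatenate([self.rotation_deg, self.translation_mm])

    def matrix(self) -> np.ndarray:
        rx, ry, rz = np.deg2rad(self.rotation_deg)
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    def apply(self, pts_mm: np.ndarray) -> np.ndarray:
        """Map one point (3,) or many points (N, 3) through the transform."""
        p = np.asarray(pts_mm, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = (p - self.center_mm) @ self.matrix().T + self.center_mm \
            + self.translation_mm
        return out[0] if single else out

    def inverse(self) -> "RigidTransform3D":
        """The exact inverse, re-expressed in the same Euler convention."""
        Rinv = self.matrix().T
        # Rz(a) Ry(b) Rx(c) decomposition of Rinv via intrinsic ZYX angles.
        az, ay, ax = Rotation.from_matrix(Rinv).as_euler("ZYX", degrees=True)
        t_inv = -Rinv @ self.translation_mm
        return RigidTransform3D((ax, ay, az), t_inv, self.center_mm)

    def compose(self, other: "RigidTransform3D") -> "RigidTransform3D":
        """Transform applying ``other`` first, then ``self`` (same centre as self)."""
        R = self.matrix() @ other.matrix()
        az, ay, ax = Rotation.from_matrix(R).as_euler("ZYX", degrees=True)
        # p -> self(other(p)); solve for translation about self.center.
        probe = self.apply(other.apply(self.center_mm))
        t = probe - self.center_mm
        return RigidTransform3D((ax, ay, az), t, self.center_mm)


def apply_rigid(t: RigidTransform3D, pts_mm: np.ndarray) -> np.ndarray:
    """Map physical point(s) through a rigid transform: R (p - c) + c + t."""
    return t.apply(pts_mm)


def _grid_of(ref) -> Grid:
    if isinstance(ref, Grid):
        return ref
    if isinstance(ref, (Volume, DisplacementField)):
        return ref.grid
    raise TypeError(f"expected Grid, Volume or DisplacementField, got {type(ref)}")


_INTERP_ORDER = {"linear": 1, "nearest": 0}


def sample_at_points(vol: Volume, pts_mm: np.ndarray, interp: str = "linear",
                     background: float | None = None) -> np.ndarray:
    """Sample a volume at arbitrary physical points; outside -> background."""
    if interp not in _INTERP_ORDER:
        raise ValueError(f"unknown interpolation mode {interp!r}")
    if background is None:
        background = float(vol.data.min())
    idx = vol.grid.physical_to_index(np.atleast_2d(pts_mm))
    return ndimage.map_coordinates(
        vol.data.astype(float, copy=False), idx.T,
        order=_INTERP_ORDER[interp], mode="constant", cval=background)


def sample_field_at_points(fld: DisplacementField, pts_mm: np.ndarray) -> np.ndarray:
    """Linearly sample a displacement field at physical points (edge-clamped)."""
    idx = fld.grid.physical_to_index(np.atleast_2d(pts_mm)).T
    out = np.empty((idx.shape[1], 3))
    for c in range(3):
        out[:, c] = ndimage.map_coordinates(fld.data[..., c], idx, order=1,
                                            mode="nearest")
    return out


def resample(vol: Volume, ref, transform=None, interp: str = "linear",
             background: float | None = None) -> Volume:
    """Resample ``vol`` onto a reference grid through an optional map.

    The output value at grid point ``p`` is the input sampled at ``map(p)``:
    a :class:`RigidTransform3D`, a :class:`DisplacementField` (sampled at
    ``p``, giving ``p + d(p)``), or the identity when ``transform`` is None.
    Points mapping outside the input extent are filled with ``background``
    (default: the input minimum — air for CT, zero for SPECT).
    """
    if interp not in _INTERP_ORDER:
        raise ValueError(f"unknown interpolation mode {interp!r}")
    grid = _grid_of(ref)
    if background is None:
        background = float(vol.data.min())
    pts = grid.physical_points()
    if transform is None:
        mapped = pts
    elif isinstance(transform, RigidTransform3D):
        mapped = transform.apply(pts)
    elif isinstance(transform, DisplacementField):
        if transform.grid.isclose(grid):
            disp = transform.data.reshape(-1, 3)
        else:
            disp = sample_field_at_points(transform, pts)
        mapped = pts + disp
    else:
        raise TypeError(f"unsupported map type {type(transform)}")
    vals = ndimage.map_coordinates(
        vol.data.astype(float, copy=False), vol.grid.physical_to_index(mapped).T,
        order=_INTERP_ORDER[interp], mode="constant", cval=background)
    return Volume(vals.reshape(grid.shape), grid.spacing, grid.origin)


def gaussian_smooth(vol: Volume, sigma_mm) -> Volume:
    """Spacing-aware Gaussian filtering; sigma given in physical mm per axis."""
    sigma = _triplet(sigma_mm)
    if np.any(sigma < 0):
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if np.all(sigma == 0):
        return vol.copy()
    sigma_vox = sigma / vol.spacing_mm
    out = ndimage.gaussian_filter(vol.data.astype(float, copy=False), sigma_vox)
    return vol.with_data(out)


def gradient_magnitude(vol: Volume) -> Volume:
    """Euclidean norm of the spacing-aware intensity gradient (intensity/mm).

    Central differences in the interior, one-sided at the borders.
    """
    if any(s < 2 for s in vol.data.shape):
        raise DegenerateAxisError(
            f"gradient needs >= 2 voxels per axis, got {vol.data.shape}")
    parts = np.gradient(vol.data.astype(float, copy=False), *vol.spacing)
    mag = np.sqrt(sum(p * p for p in parts))
    return vol.with_data(mag)


def gradient_vector(vol: Volume) -> np.ndarray:
    """Spacing-aware gradient as an (nx, ny, nz, 3) array (intensity/mm)."""
    parts = np.gradient(vol.data.astype(float, copy=False), *vol.spacing)
    return np.stack(parts, axis=-1)


def signed_distance(mask: LabelMask) -> Volume:
    """Signed Euclidean distance (mm) to the mask boundary.

    Negative inside the object, positive outside, spacing-aware.  Requires a
    boundary to exist: the mask must be neither empty nor all-ones.
    """
    inside = mask.data.astype(bool)
    if not inside.any():
        raise ValueError("signed distance of an empty mask is undefined")
    if inside.all():
        raise ValueError("signed distance of an all-ones mask has no boundary")
    sampling = mask.spacing
    d_out = ndimage.distance_transform_edt(~inside, sampling=sampling)
    d_in = ndimage.distance_transform_edt(inside, sampling=sampling)
    return Volume(d_out - d_in, mask.spacing, mask.origin)
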