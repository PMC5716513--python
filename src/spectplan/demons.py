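"""Diffeomorphic demons deformable registration.

Intensity-driven registration with optical-flow-like forces.  A stationary
velocity field is accumulated in the log domain and turned into a
displacement field by scaling-and-squaring exponentiation, which keeps the
mapping invertible (diffeomorphic) even under the large inter-patient
deformations seen in abdominal CT.  A three-level multiresolution pyramid
(downsampling factors 4, 2, 1) registers coarse structure first and refines
at full resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging_core import (DisplacementField, Grid, GridMismatchError,
                           LabelMask, Volume, gradient_vector, resample)

EPS_DENOM = 1e-9


class RegistrationDivergedError(RuntimeError):
    """Non-finite values appeared mid-iteration."""


@dataclass
class DemonsParams:
    """Demons settings: 3 pyramid levels with 50/40/30 iterations, force step
    2, field smoothing sigma 1 voxel, update smoothing sigma 0.2 voxel."""

    levels: int = 3
    iterations: tuple = (50, 40, 30)
    step: float = 2.0
    sigma_field: float = 1.0
    sigma_update: float = 0.2

    def __post_init__(self):
        self.iterations = tuple(int(i) for i in np.atleast_1d(self.iterations))
        if len(self.iterations) != self.levels:
            raise ValueError(
                f"len(iterations)={len(self.iterations)} != levels={self.levels}")
        if self.sigma_field < 0 or self.sigma_update < 0:
            raise ValueError("smoothing sigmas must be >= 0")
        if self.step <= 0:
            raise ValueError("step must be > 0")


def demons_force(fixed: Volume, warped_moving: Volume, step: float,
                 fixed_gradient: np.ndarray | None = None) -> DisplacementField:
    """Classical Thirion force from the fixed-image gradient.

    Per voxel ``u = step * (f - m) * grad f / (|grad f|^2 + (f - m)^2)`` in mm,
    zero where the denominator is below a small epsilon (flat regions with no
    intensity mismatch to act on).  The sign follows from the field
    convention ``warped(x) = moving(x + d(x))``: where the warped moving
    image is still darker than a rising fixed edge, the displacement must
    grow along the fixed gradient.
    """
    if not fixed.same_grid(warped_moving):
        raise GridMismatchError("demons_force requires images on the same grid")
    g = fixed_gradient if fixed_gradient is not None else gradient_vector(fixed)
    diff = fixed.data.astype(float) - warped_moving.data.astype(float)
    denom = np.einsum("...c,...c->...", g, g) + diff * diff
    scale = np.where(denom < EPS_DENOM, 0.0, step * diff / np.maximum(denom, EPS_DENOM))
    return DisplacementField(scale[..., None] * g, fixed.spacing, fixed.origin)


def _compose_data(outer: np.ndarray, inner: np.ndarray, spacing: np.ndarray,
                  base_idx: np.ndarray) -> np.ndarray:
    """(outer o inner)(x) = inner(x) + outer(x + inner(x)); fields in mm."""
    coords = base_idx + inner / spacing
    coord_list = [coords[..., 0], coords[..., 1], coords[..., 2]]
    out = np.empty_like(outer)
    for c in range(3):
        out[..., c] = ndimage.map_coordinates(outer[..., c], coord_list,
                                              order=1, mode="nearest")
    return out + inner


def _exp_data(vel: np.ndarray, spacing: np.ndarray,
              base_idx: np.ndarray) -> np.ndarray:
    vox_norm = np.sqrt(np.einsum("...c,...c->...", vel / spacing, vel / spacing))
    vmax = float(vox_norm.max())
    if vmax == 0.0:
        return vel.copy()
    n = max(0, int(np.ceil(np.log2(vmax / 0.5))))
    while vmax / 2 ** n >= 0.5:
        n += 1
    d = vel / 2 ** n
    for _ in range(n):
        d = _compose_data(d, d, spacing, base_idx)
    return d


def exp_field(velocity: DisplacementField) -> DisplacementField:
    """Exponential of a stationary velocity field by scaling and squaring.

    The field is scaled by 2^-n so that its maximum magnitude is below half a
    voxel, then composed with itself n times.  The result approximates the
    time-1 flow of the velocity field and is invertible in practice
    (``exp(v)`` composed with ``exp(-v)`` leaves sub-voxel residuals).
    """
    if not np.all(np.isfinite(velocity.data)):
        raise ValueError("velocity field must be finite")
    base_idx = velocity.grid.index_grid()
    d = _exp_data(velocity.data, velocity.spacing_mm, base_idx)
    return DisplacementField(d, velocity.spacing, velocity.origin)


def compose_fields(outer: DisplacementField,
                   inner: DisplacementField) -> DisplacementField:
    """Displacement of applying ``inner`` then ``outer`` (both on one grid)."""
    if not outer.grid.isclose(inner.grid):
        raise GridMismatchError("compose_fields requires a shared grid")
    base_idx = inner.grid.index_grid()
    d = _compose_data(outer.data, inner.data, inner.spacing_mm, base_idx)
    return DisplacementField(d, inner.spacing, inner.origin)


def _warp_data(data: np.ndarray, disp: np.ndarray, spacing: np.ndarray,
               base_idx: np.ndarray, background: float) -> np.ndarray:
    coords = base_idx + disp / spacing
    return ndimage.map_coordinates(
        data, [coords[..., 0], coords[..., 1], coords[..., 2]],
        order=1, mode="constant", cval=background)


def _downsample(vol: Volume, factor: int) -> Volume:
    if factor == 1:
        return vol
    sm = ndimage.gaussian_filter(vol.data.astype(float), factor / 2.0)
    data = sm[::factor, ::factor, ::factor]
    return Volume(data, vol.spacing_mm * factor, vol.origin)


def _upsample_velocity(vel: np.ndarray, src: Grid, dst: Grid) -> np.ndarray:
    pts = dst.index_grid() * dst.spacing_mm + dst.origin_mm
    idx = (pts - src.origin_mm) / src.spacing_mm
    coord_list = [idx[..., 0], idx[..., 1], idx[..., 2]]
    out = np.empty(tuple(dst.shape) + (3,))
    for c in range(3):
        out[..., c] = ndimage.map_coordinates(vel[..., c], coord_list, order=1,
                                              mode="nearest")
    return out


def _overlap(a: Volume, b: Volume) -> bool:
    alo, ahi = a.origin_mm, a.grid.extent_mm
    blo, bhi = b.origin_mm, b.grid.extent_mm
    return bool(np.all(ahi >= blo) and np.all(bhi >= alo))


def register_deformable(fixed: Volume, moving: Volume,
                        params: DemonsParams | None = None
                        ) -> tuple[DisplacementField, pd.DataFrame]:
    """Diffeomorphic demons registration of ``moving`` onto ``fixed``.

    Coarse-to-fine over ``params.levels`` pyramid levels.  At each level the
    loop is: warp the moving image through the exponential of the current
    velocity, compute the demons force, smooth the update (``sigma_update``
    voxels), cap its magnitude at ``step`` voxels, add it to the velocity, and
    smooth the velocity (``sigma_field`` voxels).  Returns the exponential of
    the final full-resolution velocity together with the iteration log
    (level, iteration, MSE, max update in voxels).

    Deterministic for fixed inputs; raises if the volumes do not overlap or a
    NaN appears mid-iteration.
    """
    params = params or DemonsParams()
    if not _overlap(fixed, moving):
        raise ValueError("fixed and moving volumes do not overlap in space")
    if not moving.same_grid(fixed):
        moving = resample(moving, fixed.grid, None, "linear")
    background = float(moving.data.min())
    factors = [2 ** (params.levels - 1 - i) for i in range(params.levels)]

    vel = None
    vel_grid = None
    rows = []
    for level, (factor, n_iter) in enumerate(zip(factors, params.iterations)):
        fx = _downsample(fixed, factor)
        mv = _downsample(moving, factor)
        grid = fx.grid
        spacing = fx.spacing_mm
        base_idx = grid.index_grid()
        if vel is None:
            vel = np.zeros(tuple(grid.shape) + (3,))
        else:
            vel = _upsample_velocity(vel, vel_grid, grid)
        vel_grid = grid
        grad = gradient_vector(fx)
        gsq = np.einsum("...c,...c->...", grad, grad)
        fdat = fx.data.astype(float)
        mdat = mv.data.astype(float)
        for it in range(n_iter):
            disp = _exp_data(vel, spacing, base_idx)
            warped = _warp_data(mdat, disp, spacing, base_idx, background)
            diff = fdat - warped
            mse = float(np.mean(diff * diff))
            denom = gsq + diff * diff
            scale = np.where(denom < EPS_DENOM, 0.0,
                             params.step * diff / np.maximum(denom, EPS_DENOM))
            upd = scale[..., None] * grad
            if params.sigma_update > 0:
                for c in range(3):
                    upd[..., c] = ndimage.gaussian_filter(upd[..., c],
                                                          params.sigma_update)
            # cap the per-voxel update magnitude at `step` voxels
            mag_vox = np.sqrt(np.einsum("...c,...c->...", upd / spacing,
                                        upd / spacing))
            over = mag_vox > params.step
            if np.any(over):
                upd[over] *= (params.step / mag_vox[over])[..., None]
            vel = vel + upd
            if params.sigma_field > 0:
                for c in range(3):
                    vel[..., c] = ndimage.gaussian_filter(vel[..., c],
                                                          params.sigma_field)
            if not np.all(np.isfinite(vel)):
                raise RegistrationDivergedError(
                    f"non-finite velocity at level {level}, iteration {it}")
            rows.append({"level": level, "factor": factor, "iteration": it,
                         "mse": mse,
                         "max_update_vox": float(mag_vox.max())})
    final_grid = fixed.grid
    base_idx = final_grid.index_grid()
    disp = _exp_data(vel, fixed.spacing_mm, base_idx)
    warped = _warp_data(moving.data.astype(float), disp, fixed.spacing_mm,
                        base_idx, background)
    final_mse = float(np.mean((warped - fixed.data.astype(float)) ** 2))
    rows.append({"level": params.levels - 1, "factor": 1,
                 "iteration": params.iterations[-1], "mse": final_mse,
                 "max_update_vox": 0.0})
    field = DisplacementField(disp, fixed.spacing, fixed.origin)
    return field, pd.DataFrame(rows)


def warp_volume(vol: Volume, fld: DisplacementField, interp: str = "linear",
                background: float | None = None) -> Volume:
    """Warp a volume through a displacement field defined on the target grid."""
    return resample(vol, fld.grid, fld, interp, background)


def warp_mask(mask: LabelMask, fld: DisplacementField) -> LabelMask:
    """Propagate a binary structure through a displacement field.

    The binary image is warped with linear interpolation and thresholded at
    0.5, giving a strictly binary result on the field's grid.
    """
    warped = warp_mask_fractional(mask, fld)
    return LabelMask((warped.data >= 0.5).astype(np.uint8), fld.spacing,
                     fld.origin)


def warp_mask_fractional(mask: LabelMask, fld: DisplacementField) -> Volume:
    """Linear-interpolated (pre-threshold) warp of a binary structure."""
    return resample(Volume(mask.data.astype(float), mask.spacing, mask.origin),
                    fld.grid, fld, "linear", background=0.0)
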