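"""Synthetic abdominal phantoms: the test bed for the planning chain.

Generates (a) a CT atlas with analytic organ masks — liver as a union of two
overlapping ellipsoids, two kidney ellipsoids, a spinal-cord cylinder ringed
by a vertebral bone shell, all inside a soft-tissue body ellipsoid; (b)
subjects derived from the atlas by a known smooth diffeomorphic deformation
(ground truth for segmentation validation); and (c) SPECT volumes at a known
rigid pose, with activity confined to the liver, mandatory hot spots (the
nonuniform uptake that defeats mutual-information registration), system blur
and Poisson counting noise.  Every generator is a pure function of
(spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .demons import DisplacementField, exp_field, warp_mask, warp_volume
from .imaging_core import (Grid, LabelMask, RigidTransform3D, Volume,
                           gaussian_smooth, resample, signed_distance)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PhantomSpec:
    """Geometry, intensity, and noise model of the synthetic study.

    Defaults emulate a clinical abdominal acquisition: CT at 2 x 2 x 2.5 mm
    on a 128 x 128 x 60 grid, SPECT with cubic 4 mm voxels (valid range
    3.2-4.6 mm), soft-tissue organs of near-uniform HU over a 40 HU body,
    8 mm FWHM system blur and a Poisson level of 200 expected counts in the
    hottest voxel.  ``organ_scale`` shrinks the whole anatomy for fast test
    phantoms without changing its topology.
    """

    ct_shape: tuple = (128, 128, 60)
    ct_spacing: tuple = (2.0, 2.0, 2.5)
    spect_spacing: float = 4.0
    spect_pad_mm: float = 32.0
    organ_scale: float = 1.0
    hu: dict = field(default_factory=lambda: {
        "air": -1000.0, "body": 40.0, "liver": 60.0, "kidney": 45.0,
        "cord": 30.0, "bone": 700.0})
    ct_noise_sigma_hu: float = 10.0
    activity_base: float = 1.0
    hot_spot_count_range: tuple = (2, 4)
    hot_spot_amplitude_range: tuple = (2.0, 4.0)
    hot_spot_sigma_range_mm: tuple = (8.0, 15.0)
    hot_spot_margin_mm: float = 10.0
    blur_fwhm_mm: float = 8.0
    peak_counts: float = 200.0

    def __post_init__(self):
        if not 3.2 <= self.spect_spacing <= 4.6:
            raise ValueError(
                f"SPECT spacing {self.spect_spacing} mm outside the clinical "
                "cubic-voxel range [3.2, 4.6] mm")
        if any(s <= 0 for s in self.ct_shape) or any(
                s <= 0 for s in self.ct_spacing):
            raise ValueError("CT shape and spacing must be positive")
        if self.organ_scale <= 0:
            raise ValueError("organ_scale must be > 0")
        if self.peak_counts <= 0:
            raise ValueError("Poisson count scale must be > 0")


# organ geometry in mm relative to the grid centre (before organ_scale);
# adult-abdomen dimensions: ~1.2 L liver, 11 cm kidneys, T-spine cord
_BODY = ((0.0, 0.0, 0.0), (118.0, 105.0, 110.0))
_LIVER = [((38.0, -18.0, 8.0), (75.0, 62.0, 52.0)),
          ((0.0, 2.0, 22.0), (55.0, 46.0, 38.0))]
_KIDNEYS = {"kidney_left": ((-55.0, 48.0, -20.0), (20.0, 15.0, 45.0)),
            "kidney_right": ((55.0, 48.0, -20.0), (20.0, 15.0, 45.0))}
_CORD_XY = (0.0, 75.0)
_CORD_RADIUS = 9.0
_BONE_RADII = (13.0, 24.0)


def _coords(grid: Grid):
    ax = grid.axes_mm()
    c = grid.center_mm
    return (ax[0][:, None, None] - c[0], ax[1][None, :, None] - c[1],
            ax[2][None, None, :] - c[2])


def _ellipsoid(x, y, z, center, semi, scale):
    cx, cy, cz = (c * scale for c in center)
    ax_, ay, az = (a * scale for a in semi)
    return (((x - cx) / ax_) ** 2 + ((y - cy) / ay) ** 2
            + ((z - cz) / az) ** 2) <= 1.0


def generate_ct_phantom(spec: PhantomSpec | None = None, seed: int = 0
                        ) -> tuple[Volume, dict]:
    """Analytic CT phantom plus its noise-free structure masks.

    Ellipsoid/cylinder rasterization at CT resolution with additive Gaussian
    HU noise; the masks (liver, kidney_left, kidney_right, cord) are the
    analytic shapes, pairwise disjoint and contained in the body.
    """
    spec = spec or PhantomSpec()
    grid = Grid(spec.ct_shape, spec.ct_spacing, (0.0, 0.0, 0.0))
    x, y, z = _coords(grid)
    s = spec.organ_scale

    body = _ellipsoid(x, y, z, *_BODY, s)
    liver = np.zeros(grid.shape, dtype=bool)
    for center, semi in _LIVER:
        liver |= _ellipsoid(x, y, z, center, semi, s)
    organs = {"liver": liver}
    for name, (center, semi) in _KIDNEYS.items():
        organs[name] = _ellipsoid(x, y, z, center, semi, s)
    rho = np.sqrt((x - _CORD_XY[0] * s) ** 2 + (y - _CORD_XY[1] * s) ** 2)
    rho = np.broadcast_to(rho, grid.shape)
    organs["cord"] = rho <= _CORD_RADIUS * s
    bone = (rho >= _BONE_RADII[0] * s) & (rho <= _BONE_RADII[1] * s) & body

    claimed = np.zeros(grid.shape, dtype=bool)
    for name in organs:
        organs[name] = organs[name] & body & ~claimed
        if not organs[name].any():
            raise ValueError(
                f"organ {name!r} rasterized empty; check the phantom geometry")
        claimed |= organs[name]

    hu = np.full(grid.shape, spec.hu["air"])
    hu[body] = spec.hu["body"]
    hu[bone] = spec.hu["bone"]
    hu[organs["liver"]] = spec.hu["liver"]
    hu[organs["kidney_left"] | organs["kidney_right"]] = spec.hu["kidney"]
    hu[organs["cord"]] = spec.hu["cord"]
    rng = np.random.default_rng(seed)
    hu = hu + rng.normal(0.0, spec.ct_noise_sigma_hu, grid.shape)

    ct = Volume(hu, grid.spacing, grid.origin)
    masks = {name: LabelMask(m.astype(np.uint8), grid.spacing, grid.origin)
             for name, m in organs.items()}
    return ct, masks


def liver_union_volume_mm3(spec: PhantomSpec, n_samples: int = 200000,
                           seed: int = 12345) -> float:
    """Monte-Carlo volume of the analytic liver (two-ellipsoid union), mm^3."""
    s = spec.organ_scale
    rng = np.random.default_rng(seed)
    lo = np.array([min(c[i] - a[i] for c, a in _LIVER) for i in range(3)]) * s
    hi = np.array([max(c[i] + a[i] for c, a in _LIVER) for i in range(3)]) * s
    pts = rng.uniform(lo, hi, (n_samples, 3))
    inside = np.zeros(n_samples, dtype=bool)
    for center, semi in _LIVER:
        c = np.asarray(center) * s
        a = np.asarray(semi) * s
        inside |= np.sum(((pts - c) / a) ** 2, axis=1) <= 1.0
    return float(np.prod(hi - lo) * inside.mean())


def _jacobian_positive(fld: DisplacementField) -> bool:
    d = fld.data
    sp = fld.spacing_mm
    J = np.empty(d.shape[:3] + (3, 3))
    for c in range(3):
        parts = np.gradient(d[..., c], *sp)
        for a in range(3):
            J[..., c, a] = parts[a]
    for a in range(3):
        J[..., a, a] += 1.0
    det = (J[..., 0, 0] * (J[..., 1, 1] * J[..., 2, 2] - J[..., 1, 2] * J[..., 2, 1])
           - J[..., 0, 1] * (J[..., 1, 0] * J[..., 2, 2] - J[..., 1, 2] * J[..., 2, 0])
           + J[..., 0, 2] * (J[..., 1, 0] * J[..., 2, 1] - J[..., 1, 1] * J[..., 2, 0]))
    return bool(det.min() > 0)


def deform_phantom(atlas_ct: Volume, masks: dict,
                   max_displacement_mm: float = 8.0,
                   smoothness_mm: float = 20.0, seed: int = 0,
                   max_attempts: int = 5
                   ) -> tuple[Volume, dict, DisplacementField]:
    """Create a synthetic subject by a known smooth diffeomorphic deformation.

    A Gaussian-smoothed white-noise vector field (kernel sigma =
    ``smoothness_mm``) is rescaled to ``max_displacement_mm`` peak norm and
    exponentiated, guaranteeing a fold-free mapping (positive Jacobian
    determinant, verified numerically; on the rare failure the smoothness is
    enlarged and the field regenerated, erroring after ``max_attempts``).
    Returns the subject CT, its ground-truth masks, and the true displacement
    field — defined on the subject grid, mapping subject points into atlas
    space, i.e. the same convention the demons registration must recover.
    """
    grid = atlas_ct.grid
    rng = np.random.default_rng(seed)
    if max_displacement_mm == 0:
        fld = DisplacementField.zeros(grid)
        return (atlas_ct.copy(),
                {n: m.copy() for n, m in masks.items()}, fld)
    smoothness = float(smoothness_mm)
    for attempt in range(max_attempts):
        noise = rng.standard_normal(tuple(grid.shape) + (3,))
        sigma_vox = smoothness / grid.spacing_mm
        vel = np.empty_like(noise)
        for c in range(3):
            vel[..., c] = ndimage.gaussian_filter(noise[..., c],
                                                  sigma_vox)
        mag = np.linalg.norm(vel, axis=-1).max()
        if mag == 0:
            raise RuntimeError("degenerate zero velocity field")
        vel *= max_displacement_mm / mag
        fld = exp_field(DisplacementField(vel, grid.spacing, grid.origin))
        if _jacobian_positive(fld):
            break
        smoothness *= 1.5
    else:
        raise RuntimeError(
            f"could not generate a fold-free field in {max_attempts} attempts")
    subject_ct = warp_volume(atlas_ct, fld)
    subject_masks = {name: warp_mask(mask, fld) for name, mask in masks.items()}
    return subject_ct, subject_masks, fld


def spect_grid_for(ct_grid: Grid, spec: PhantomSpec) -> Grid:
    """Cubic SPECT grid co-centred with the CT, padded on every side."""
    extent = (np.asarray(ct_grid.shape) - 1) * ct_grid.spacing_mm
    span = extent + 2.0 * spec.spect_pad_mm
    shape = np.ceil(span / spec.spect_spacing).astype(int) + 1
    origin = ct_grid.center_mm - (shape - 1) * spec.spect_spacing / 2.0
    return Grid(tuple(shape), (spec.spect_spacing,) * 3, tuple(origin))


def liver_activity(liver_mask: LabelMask, spec: PhantomSpec,
                   seed: int = 0) -> Volume:
    """Nonuniform liver activity: a base level plus 2-4 Gaussian hot spots.

    Hot-spot centres are drawn at least ``hot_spot_margin_mm`` inside the
    liver boundary so the dominant SPECT edge stays at the organ surface;
    activity is exactly zero outside the liver.
    """
    rng = np.random.default_rng(seed)
    sd = signed_distance(liver_mask).data
    interior = np.argwhere(sd <= -spec.hot_spot_margin_mm)
    if interior.shape[0] == 0:  # very small livers: fall back to the deepest half
        interior = np.argwhere(sd <= sd.min() / 2.0)
    k = int(rng.integers(spec.hot_spot_count_range[0],
                         spec.hot_spot_count_range[1] + 1))
    grid = liver_mask.grid
    x, y, z = _coords(grid)
    c = grid.center_mm
    act = np.full(grid.shape, spec.activity_base)
    for _ in range(k):
        centre_idx = interior[rng.integers(interior.shape[0])]
        centre = grid.index_to_physical(centre_idx) - c
        amp = rng.uniform(*spec.hot_spot_amplitude_range)
        sig = rng.uniform(*spec.hot_spot_sigma_range_mm)
        r2 = (x - centre[0]) ** 2 + (y - centre[1]) ** 2 + (z - centre[2]) ** 2
        act += amp * np.exp(-r2 / (2.0 * sig * sig))
    act *= liver_mask.data
    return Volume(act, grid.spacing, grid.origin)


def generate_spect_phantom(liver_mask: LabelMask,
                           true_pose: RigidTransform3D,
                           spec: PhantomSpec | None = None, seed: int = 0,
                           noise: bool = True) -> Volume:
    """SPECT volume of the phantom liver at a known rigid pose.

    The CT-space activity is resampled through the inverse pose onto the
    cubic SPECT grid (so the CT→SPECT transform the registration must find is
    exactly ``true_pose``), blurred with the system FWHM, scaled so the
    hottest voxel expects ``peak_counts`` counts, and Poisson-sampled.
    """
    spec = spec or PhantomSpec()
    act = liver_activity(liver_mask, spec, seed)
    sgrid = spect_grid_for(liver_mask.grid, spec)
    on_spect = resample(act, sgrid, true_pose.inverse(), "linear",
                        background=0.0)
    blurred = gaussian_smooth(on_spect, spec.blur_fwhm_mm * _FWHM_TO_SIGMA)
    peak = blurred.data.max()
    if peak <= 0:
        raise RuntimeError("no activity reached the SPECT grid")
    expected = blurred.data * (spec.peak_counts / peak)
    if not noise:
        return Volume(expected, sgrid.spacing, sgrid.origin)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected).astype(float)
    return Volume(counts, sgrid.spacing, sgrid.origin)


def default_pose(liver_mask: LabelMask,
                 rotation_deg=(2.0, -1.0, 1.0),
                 translation_mm=(8.0, -6.0, 4.0)) -> RigidTransform3D:
    """The study's known CT→SPECT pose, centred on the liver centroid."""
    return RigidTransform3D(rotation_deg, translation_mm,
                            liver_mask.centroid_mm())
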