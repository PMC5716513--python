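"""Geometric primitives: grids, resampling, gradients, distances, rigid maps."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial import cKDTree

from spectplan.imaging_core import (DegenerateAxisError, Grid, LabelMask,
                                    RigidTransform3D, Volume, apply_rigid,
                                    gaussian_smooth, gradient_magnitude,
                                    resample, signed_distance)

from conftest import make_blob_mask, make_sphere_mask, ramp_volume


def rand_volume(shape=(10, 12, 8), spacing=(1.5, 1.0, 2.5), seed=0):
    rng = np.random.default_rng(seed)
    return Volume(rng.normal(size=shape), spacing, (0.0, 0.0, 0.0))


class TestResample:
    def test_identity_map_returns_input(self):
        vol = rand_volume()
        out = resample(vol, vol.grid, None, "linear")
        np.testing.assert_allclose(out.data, vol.data, atol=1e-12)

    def test_one_voxel_translation_shifts_indices(self):
        vol = rand_volume()
        t = RigidTransform3D(translation_mm=(vol.spacing[0], 0, 0))
        out = resample(vol, vol.grid, t, "linear")
        np.testing.assert_allclose(out.data[:-1], vol.data[1:], atol=1e-9)

    def test_half_voxel_translation_hits_linear_midpoint(self):
        data = np.zeros((6, 4, 4))
        data[3:] = 10.0
        vol = Volume(data, (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))
        t = RigidTransform3D(translation_mm=(1.0, 0.0, 0.0))  # half a voxel
        out = resample(vol, vol.grid, t, "linear")
        assert out.data[2, 2, 2] == pytest.approx(5.0)

    def test_nearest_interpolation_preserves_values(self):
        vol = rand_volume()
        t = RigidTransform3D(translation_mm=(0.4 * vol.spacing[0], 0, 0))
        out = resample(vol, vol.grid, t, "nearest")
        assert set(np.unique(out.data)) <= set(np.unique(vol.data)) | {vol.data.min()}

    def test_unknown_interp_mode_rejected(self):
        vol = rand_volume()
        with pytest.raises(ValueError, match="interp"):
            resample(vol, vol.grid, None, "cubic")

    def test_empty_ref_grid_rejected(self):
        with pytest.raises(ValueError):
            Grid((0, 4, 4), (1, 1, 1), (0, 0, 0))

    def test_background_fill_defaults_to_minimum(self):
        vol = rand_volume()
        t = RigidTransform3D(translation_mm=(1000.0, 0.0, 0.0))
        out = resample(vol, vol.grid, t, "linear")
        assert np.all(out.data == vol.data.min())


class TestGaussianSmooth:
    def test_zero_sigma_is_identity(self):
        vol = rand_volume()
        np.testing.assert_array_equal(gaussian_smooth(vol, 0.0).data, vol.data)

    def test_constant_volume_unchanged(self):
        vol = Volume(np.full((8, 8, 8), 7.0), (1, 2, 3))
        np.testing.assert_allclose(gaussian_smooth(vol, 5.0).data, 7.0,
                                   rtol=1e-7)

    def test_delta_spike_spreads_to_unit_mass_kernel(self):
        data = np.zeros((21, 21, 21))
        data[10, 10, 10] = 42.0
        vol = Volume(data, (2.0, 2.0, 2.0))
        out = gaussian_smooth(vol, 4.0)
        assert out.data.sum() == pytest.approx(42.0, abs=1e-6)
        assert np.unravel_index(out.data.argmax(), out.data.shape) == (10, 10, 10)
        # spacing-awareness: sigma of the spread profile matches 4 mm = 2 voxels
        profile = out.data[:, 10, 10]
        x = (np.arange(21) - 10) * 2.0
        sigma_emp = np.sqrt((profile * x ** 2).sum() / profile.sum())
        assert sigma_emp == pytest.approx(4.0, rel=0.02)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(rand_volume(), -1.0)


class TestGradientMagnitude:
    def test_constant_volume_gives_zero(self):
        vol = Volume(np.full((6, 6, 6), 3.0), (1, 1, 1))
        np.testing.assert_allclose(gradient_magnitude(vol).data, 0.0)

    def test_linear_ramp_gives_slope(self):
        vol = ramp_volume(slope=2.0, axis=1)
        mag = gradient_magnitude(vol).data
        np.testing.assert_allclose(mag, 2.0, rtol=1e-12)

    def test_spacing_awareness(self):
        vol = ramp_volume(shape=(8, 8, 8), spacing=(1.0, 1.0, 4.0), slope=3.0,
                          axis=2)
        # data was built in mm so the slope is already per-mm
        np.testing.assert_allclose(gradient_magnitude(vol).data, 3.0,
                                   rtol=1e-12)

    def test_sphere_edge_is_gradient_argmax(self):
        mask = make_sphere_mask(radius_mm=20.0, spacing=(2.0, 2.0, 2.0))
        vol = Volume(100.0 * mask.data.astype(float), mask.spacing, mask.origin)
        vol = gaussian_smooth(vol, 3.0)
        mag = gradient_magnitude(vol).data
        ridge = np.argwhere(mag > 0.9 * mag.max())
        center = (np.asarray(vol.data.shape) - 1) / 2.0
        r = np.linalg.norm((ridge - center) * vol.spacing_mm, axis=1)
        diag = np.linalg.norm(vol.spacing_mm)
        assert np.all(np.abs(r - 20.0) <= diag)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(DegenerateAxisError):
            Volume(np.zeros((1, 5, 5)), (1, 1, 1))


class TestSignedDistance:
    def test_sphere_center_depth(self):
        mask = make_sphere_mask(radius_mm=20.0, spacing=(2.0, 2.0, 2.0))
        sd = signed_distance(mask).data
        center = tuple((np.asarray(mask.data.shape) - 1) // 2)
        diag = np.linalg.norm(mask.spacing_mm)
        assert abs(sd[center] + 20.0) <= diag

    def test_boundary_adjacent_voxels_are_near_zero(self):
        mask = make_sphere_mask()
        sd = signed_distance(mask).data
        from spectplan.validation import boundary_voxels
        diag = np.linalg.norm(mask.spacing_mm)
        assert np.all(np.abs(sd[boundary_voxels(mask)]) <= diag)

    def test_sign_changes_across_boundary(self):
        mask = make_sphere_mask()
        sd = signed_distance(mask).data
        assert np.all(sd[mask.bool_data] < 0)
        assert np.all(sd[~mask.bool_data] > 0)

    def test_matches_exhaustive_nearest_voxel_search(self):
        mask = make_blob_mask(seed=3)
        sd = signed_distance(mask).data
        inside = mask.bool_data
        pts = mask.grid.index_grid() * mask.spacing_mm
        in_tree = cKDTree(pts[inside])
        out_tree = cKDTree(pts[~inside])
        brute = np.where(inside, -out_tree.query(pts)[0], in_tree.query(pts)[0])
        diag = np.linalg.norm(mask.spacing_mm)
        assert np.max(np.abs(sd - brute)) <= 1e-9  # same definition, exact
        assert np.max(np.abs(sd)) > diag  # the blob has interior depth

    def test_distance_map_has_unit_gradient_off_medial_axis(self):
        # planar faces: the distance field is exactly linear, |grad| = 1
        box = np.zeros((24, 24, 24), dtype=np.uint8)
        box[8:16, 8:16, 8:16] = 1
        mask = LabelMask(box, (2.0, 2.0, 2.0))
        sd = signed_distance(mask)
        mag = gradient_magnitude(sd).data
        face = np.zeros_like(box, dtype=bool)
        face[10:14, 10:14, 2:7] = True   # opposite a face, off the boundary
        face[10:14, 10:14, 17:22] = True
        np.testing.assert_allclose(mag[face], 1.0, atol=1e-9)
        # curved surface: unit gradient holds in the bulk up to voxel-centre
        # quantization; hold the typical deviation to 10%
        sphere = make_sphere_mask(radius_mm=20.0, spacing=(2.0, 2.0, 2.0),
                                  margin_mm=12.0)
        sd_s = signed_distance(sphere)
        mag_s = gradient_magnitude(sd_s).data
        center = (np.asarray(sphere.data.shape) - 1) / 2.0
        r = np.linalg.norm((sphere.grid.index_grid() - center)
                           * sphere.spacing_mm, axis=-1)
        diag = np.linalg.norm(sphere.spacing_mm)
        shell = (r > 10.0) & (r < 28.0) & (np.abs(sd_s.data) > diag)
        assert np.percentile(np.abs(mag_s[shell] - 1.0), 90) < 0.1

    def test_empty_and_full_masks_rejected(self):
        zero = np.zeros((4, 4, 4), dtype=np.uint8)
        with pytest.raises(ValueError):
            signed_distance(LabelMask(zero, (1, 1, 1)))
        with pytest.raises(ValueError):
            signed_distance(LabelMask(zero + 1, (1, 1, 1)))


class TestRigidTransform:
    def test_identity_fixes_points(self):
        t = RigidTransform3D.identity()
        p = np.array([3.0, -2.0, 7.0])
        np.testing.assert_allclose(apply_rigid(t, p), p)

    def test_pure_translation(self):
        t = RigidTransform3D(translation_mm=(5.0, 0.0, 0.0))
        np.testing.assert_allclose(apply_rigid(t, [1.0, 2.0, 3.0]),
                                   [6.0, 2.0, 3.0])

    def test_quarter_turn_about_z(self):
        t = RigidTransform3D(rotation_deg=(0.0, 0.0, 90.0))
        np.testing.assert_allclose(apply_rigid(t, [1.0, 0.0, 0.0]),
                                   [0.0, 1.0, 0.0], atol=1e-12)

    def test_rotation_about_noncentral_center(self):
        t = RigidTransform3D((0, 0, 180.0), (0, 0, 0), center_mm=(1.0, 0, 0))
        np.testing.assert_allclose(apply_rigid(t, [2.0, 0.0, 0.0]),
                                   [0.0, 0.0, 0.0], atol=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_inverse_roundtrip_within_nanometre(self, seed):
        rng = np.random.default_rng(seed)
        t = RigidTransform3D(rng.uniform(-30, 30, 3), rng.uniform(-50, 50, 3),
                             rng.uniform(-20, 20, 3))
        pts = rng.uniform(-100, 100, (20, 3))
        back = t.inverse().apply(t.apply(pts))
        assert np.max(np.abs(back - pts)) < 1e-9

    @given(st.integers(0, 2 ** 31 - 1))
    def test_pairwise_distances_preserved(self, seed):
        rng = np.random.default_rng(seed)
        t = RigidTransform3D(rng.uniform(-90, 90, 3), rng.uniform(-50, 50, 3),
                             rng.uniform(-20, 20, 3))
        pts = rng.uniform(-100, 100, (10, 3))
        mapped = t.apply(pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(mapped[:, None] - mapped[None, :], axis=-1)
        np.testing.assert_allclose(d1, d0, rtol=1e-9, atol=1e-9)

    def test_params_roundtrip(self):
        x = np.array([1.0, -2.0, 3.0, 4.0, -5.0, 6.0])
        t = RigidTransform3D.from_params(x, center=(1, 2, 3))
        np.testing.assert_allclose(t.params, x)


class TestDisplacementFieldBasics:
    def test_zero_field_resample_is_identity(self):
        from spectplan.imaging_core import DisplacementField
        vol = rand_volume()
        fld = DisplacementField.zeros(vol.grid)
        out = resample(vol, vol.grid, fld, "linear")
        np.testing.assert_allclose(out.data, vol.data, atol=1e-12)

    def test_nonfinite_field_rejected(self):
        from spectplan.imaging_core import DisplacementField
        bad = np.zeros((4, 4, 4, 3))
        bad[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            DisplacementField(bad, (1, 1, 1))
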