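"""Narrow-band SPECT-CT rigid registration: band, metric, optimizer."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from spectplan.imaging_core import (LabelMask, RigidTransform3D, Volume,
                                    gaussian_smooth, gradient_magnitude)
from spectplan.narrowband_registration import (BandMetric,
                                               DegenerateMetricError,
                                               InsufficientOverlapError,
                                               NarrowBandRegistrar,
                                               RegularStepParams, band_metric,
                                               band_weight, build_narrow_band,
                                               mi_baseline_register,
                                               mutual_information, ncc,
                                               register_rigid_narrowband,
                                               regular_step_descent)
from spectplan.validation import boundary_voxels

from conftest import make_blob_mask, make_sphere_mask


@pytest.fixture(scope="module")
def small_grad(small_spect_pair):
    _, _, spect = small_spect_pair
    return gradient_magnitude(gaussian_smooth(spect, spect.spacing_mm))


class TestBuildNarrowBand:
    def test_sphere_band_membership(self):
        mask = make_sphere_mask(radius_mm=20.0, spacing=(2.0, 2.0, 2.0),
                                margin_mm=20.0)
        band = build_narrow_band(mask, 10.0)
        center = (np.asarray(mask.data.shape) - 1) // 2
        far = tuple(center + np.array([0, 0, int(round(35 / 2.0))]))
        near = tuple(center + np.array([0, 0, int(round(25 / 2.0))]))
        assert band.band_mask.data[far] == 0      # |d| = 15 mm > width
        assert band.band_mask.data[near] == 1     # |d| = 5 mm <= width
        assert np.all(np.abs(band.distance.data[band.band_mask.bool_data])
                      <= 10.0)

    def test_band_contains_the_zero_level_set(self, blob_mask):
        # clear the array border so every surface voxel has a true outside
        # neighbour (a blob clipped by the field of view has no boundary there)
        data = blob_mask.data.copy()
        data[[0, -1], :, :] = 0
        data[:, [0, -1], :] = 0
        data[:, :, [0, -1]] = 0
        mask = LabelMask(data, blob_mask.spacing, blob_mask.origin)
        band = build_narrow_band(mask, 10.0)
        assert np.all(band.band_mask.data[boundary_voxels(mask)] == 1)

    def test_count_matches_exhaustive_distance_search(self):
        mask = make_blob_mask(shape=(32, 32, 32), spacing=(2.0, 2.0, 2.0),
                              seed=6)
        band = build_narrow_band(mask, 10.0)
        pts = mask.grid.index_grid() * mask.spacing_mm
        inside = mask.bool_data
        in_tree = cKDTree(pts[inside])
        out_tree = cKDTree(pts[~inside])
        d = np.where(inside, out_tree.query(pts)[0], in_tree.query(pts)[0])
        brute_count = int((d <= 10.0).sum())
        assert band.band_mask.count() == pytest.approx(brute_count, rel=0.02)

    def test_degenerate_inputs_rejected(self, blob_mask):
        empty = LabelMask(np.zeros_like(blob_mask.data), blob_mask.spacing)
        with pytest.raises(ValueError):
            build_narrow_band(empty, 10.0)
        with pytest.raises(ValueError, match="width"):
            build_narrow_band(blob_mask, 0.5)


class TestBandWeight:
    def test_peaks_at_the_contour(self):
        assert band_weight(0.0, 10.0) == pytest.approx(1.0)

    def test_value_at_band_edge(self):
        assert band_weight(10.0, 10.0) == pytest.approx(np.exp(-4.5), rel=1e-9)
        assert band_weight(-10.0, 10.0) == pytest.approx(np.exp(-4.5), rel=1e-9)

    def test_even_and_monotone_in_absolute_distance(self):
        d = np.linspace(0, 15, 40)
        w = band_weight(d, 10.0)
        np.testing.assert_allclose(band_weight(-d, 10.0), w)
        assert np.all(np.diff(w) < 0)


class TestNcc:
    def test_self_correlation_is_one(self):
        a = np.array([1.0, 5.0, 2.0, 8.0])
        assert ncc(a, a) == pytest.approx(1.0)

    def test_negated_shifted_signal_is_minus_one(self):
        a = np.array([1.0, 5.0, 2.0, 8.0])
        assert ncc(a, -a + 3.0) == pytest.approx(-1.0)

    def test_hand_computed_pearson_value(self):
        assert ncc([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateMetricError):
            ncc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBandMetric:
    def test_bounded_by_ncc_range(self, small_spect_pair, small_grad):
        liver, pose, _ = small_spect_pair
        band = build_narrow_band(liver, 10.0)
        val = band_metric(pose, band, small_grad)
        assert -1.0 <= val <= 1.0

    def test_truth_beats_ten_mm_offsets(self, small_spect_pair, small_grad):
        liver, pose, _ = small_spect_pair
        band = build_narrow_band(liver, 10.0)
        metric = BandMetric(band, small_grad)
        at_truth = metric(pose)
        for axis in range(3):
            off = np.zeros(3)
            off[axis] = 10.0
            shifted = RigidTransform3D(pose.rotation_deg,
                                       pose.translation_mm + off,
                                       pose.center_mm)
            assert at_truth < metric(shifted)

    def test_translation_sweep_minimum_is_near_truth(self, small_spect_pair,
                                                     small_grad):
        liver, pose, _ = small_spect_pair
        band = build_narrow_band(liver, 10.0)
        metric = BandMetric(band, small_grad)
        offsets = np.arange(-20.0, 20.5, 1.0)
        vals = []
        for dx in offsets:
            t = RigidTransform3D(pose.rotation_deg,
                                 pose.translation_mm + np.array([dx, 0, 0]),
                                 pose.center_mm)
            vals.append(metric(t))
        assert abs(offsets[int(np.argmin(vals))]) <= 2.0

    def test_invariant_to_affine_intensity_rescaling(self, small_spect_pair):
        liver, pose, spect = small_spect_pair
        band = build_narrow_band(liver, 10.0)

        def metric_of(vol):
            grad = gradient_magnitude(gaussian_smooth(vol, vol.spacing_mm))
            return BandMetric(band, grad)(pose)

        base = metric_of(spect)
        scaled = metric_of(spect.with_data(3.5 * spect.data + 100.0))
        assert scaled == pytest.approx(base, abs=1e-6)

    def test_insufficient_overlap_raises(self, small_spect_pair, small_grad):
        liver, pose, _ = small_spect_pair
        band = build_narrow_band(liver, 10.0)
        metric = BandMetric(band, small_grad)
        far = RigidTransform3D(pose.rotation_deg, (1000.0, 0.0, 0.0),
                               pose.center_mm)
        with pytest.raises(InsufficientOverlapError):
            metric(far)


class TestRegularStepDescent:
    params = RegularStepParams(max_step=2.0, min_step=0.01, fd_step=0.1)

    def test_solves_a_quadratic_bowl(self):
        target = np.array([1.0, -2.0, 0.5, 3.0, -4.0, 2.0])
        best, _ = regular_step_descent(
            lambda x: float(np.sum((x - target) ** 2)), np.zeros(6),
            self.params)
        assert np.linalg.norm(best - target) <= 10 * self.params.min_step

    def test_start_at_minimum_stays_there(self):
        target = np.array([1.0, -2.0, 0.5, 3.0, -4.0, 2.0])
        best, _ = regular_step_descent(
            lambda x: float(np.sum((x - target) ** 2)), target, self.params)
        np.testing.assert_allclose(best, target, atol=1e-9)

    def test_step_sequence_non_increasing_above_min_step(self):
        rng = np.random.default_rng(0)
        target = rng.uniform(-5, 5, 6)
        _, trace = regular_step_descent(
            lambda x: float(np.sum((x - target) ** 2)), np.zeros(6),
            self.params)
        steps = trace.step.to_numpy()
        assert np.all(np.diff(steps) <= 1e-12)
        assert np.all(steps >= self.params.min_step)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RegularStepParams(max_step=1.0, min_step=2.0)
        with pytest.raises(ValueError):
            RegularStepParams(relaxation=1.5)


class TestRegisterRigidNarrowband:
    def test_recovers_known_pose_from_identity(self, small_spect_pair):
        liver, pose, spect = small_spect_pair
        found, _ = register_rigid_narrowband(liver, spect)
        assert np.abs(found.params[3:] - pose.params[3:]).max() < 1.0
        assert np.abs(found.params[:3] - pose.params[:3]).max() < 1.0

    def test_tolerates_one_voxel_segmentation_error(self, small_spect_pair):
        """The transition zone absorbs erosion/dilation of the liver mask."""
        from scipy import ndimage

        liver, _, spect = small_spect_pair
        base, _ = register_rigid_narrowband(liver, spect)
        for op in (ndimage.binary_erosion, ndimage.binary_dilation):
            perturbed = LabelMask(op(liver.bool_data).astype(np.uint8),
                                  liver.spacing, liver.origin)
            t, _ = register_rigid_narrowband(perturbed, spect)
            assert np.abs(t.params[3:] - base.params[3:]).max() < 1.0

    def test_registrar_restarts_are_deterministic(self, small_spect_pair):
        liver, _, spect = small_spect_pair
        reg = NarrowBandRegistrar(liver, spect)
        x0 = np.array([2.0, -1.0, 0.5, 10.0, -8.0, 6.0])
        t1, _ = reg.register(x0)
        t2, _ = reg.register(x0)
        np.testing.assert_array_equal(t1.params, t2.params)

    def test_zero_activity_rejected(self, small_spect_pair):
        liver, _, spect = small_spect_pair
        dead = spect.with_data(np.zeros_like(spect.data))
        with pytest.raises(ValueError, match="activity"):
            register_rigid_narrowband(liver, dead)


class TestMiBaseline:
    def test_mi_peaks_for_identical_signals(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=5000)
        edges = np.linspace(a.min(), a.max() + 1e-9, 65)
        self_mi = mutual_information(a, a, edges, edges)
        mixed_mi = mutual_information(a, rng.permutation(a), edges, edges)
        assert self_mi > mixed_mi

    def test_mi_is_non_negative(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=2000), rng.normal(size=2000)
        edges = np.linspace(-4, 4, 65)
        assert mutual_information(a, b, edges, edges) >= 0.0

    def test_convergence_spread_recorded_for_both_arms(self, small_spect_pair,
                                                       small_phantom):
        """The comparison arm runs; its restart spread is reported alongside
        the narrow band's, with no ordering asserted."""
        from spectplan.validation import convergence_analysis

        liver, _, spect = small_spect_pair
        ct, _ = small_phantom
        nb = NarrowBandRegistrar(liver, spect)
        res_nb = convergence_analysis(nb.register, n_restarts=3,
                                      translation_bound_mm=15.0,
                                      rotation_bound_deg=3.0, seed=5)
        mi_params = RegularStepParams(max_iterations=60)

        def mi_reg(x0):
            t, _ = mi_baseline_register(ct, spect, mi_params, x0,
                                        n_samples=5000, seed=3)
            return t

        res_mi = convergence_analysis(mi_reg, n_restarts=3,
                                      translation_bound_mm=15.0,
                                      rotation_bound_deg=3.0, seed=5)
        report = pd.DataFrame({"narrow_band": res_nb.ranges,
                               "mutual_information": res_mi.ranges})
        assert report.notna().all().all()
        assert np.all(res_nb.translation_ranges_mm < 5.0)
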