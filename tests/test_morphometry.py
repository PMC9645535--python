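"""Measurements and agreement statistics against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree

from aortaseg import morphometry as mm
from aortaseg.core import LabelMask


def _mask(data, spacing=(1, 1, 1)):
    return LabelMask(np.asarray(data, np.uint8), spacing)


# ----------------------------------------------------------------------
# overlap / volumes
# ----------------------------------------------------------------------


class TestDice:
    def test_identical_nonempty_masks_score_one(self, tube):
        m = tube[3].label_mask
        assert mm.dice_score(m, m, 1) == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((4, 4, 4))
        b = np.zeros((4, 4, 4))
        a[0], b[3] = 1, 1
        assert mm.dice_score(_mask(a), _mask(b), 1) == 0.0

    def test_hand_counted_half_overlap(self):
        a = np.zeros((4, 4, 1))
        b = np.zeros((4, 4, 1))
        a[0:2, 0:2, 0] = 1  # |A| = 4
        b[1:3, 0:2, 0] = 1  # |B| = 4, overlap 2
        assert mm.dice_score(_mask(a), _mask(b), 1) == pytest.approx(0.5)

    def test_both_empty_scores_one_by_convention(self):
        z = _mask(np.zeros((3, 3, 3)))
        assert mm.dice_score(z, z, 1) == 1.0

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            mm.dice_score(_mask(np.zeros((3, 3, 3))),
                          _mask(np.zeros((4, 4, 4))), 1)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = _mask(rng.integers(0, 3, (6, 6, 6)))
        b = _mask(rng.integers(0, 3, (6, 6, 6)))
        for cls in (1, 2, None):
            d = mm.dice_score(a, b, cls)
            assert d == mm.dice_score(b, a, cls)
            # brute force from raw voxel loops
            ba = a.foreground() if cls is None else a.data == cls
            bb = b.foreground() if cls is None else b.data == cls
            inter = sum(1 for i in np.ndindex(a.shape) if ba[i] and bb[i])
            na, nb = int(ba.sum()), int(bb.sum())
            expected = 1.0 if na + nb == 0 else 2 * inter / (na + nb)
            assert d == pytest.approx(expected)


class TestVolumesAndAreas:
    def test_volume_is_count_times_voxel_volume(self):
        data = np.zeros((10, 10, 10))
        data[:10] = 1
        v = mm.class_volumes(_mask(data, (1, 1, 1)))
        assert v["lumen_mm3"] == 1000.0
        assert v["ws_ilt_mm3"] == 0.0

    def test_tube_lumen_volume_close_to_analytic(self, tube):
        spec, _, _, truth = tube
        v = mm.class_volumes(truth.label_mask)
        ext = np.asarray(spec.grid_shape) * np.asarray(spec.spacing)
        assert v["lumen_mm3"] == pytest.approx(
            np.pi * spec.tube_radius**2 * ext[2], rel=0.02)

    def test_max_axial_area_of_cylinder(self, tube):
        spec, _, _, truth = tube
        area = mm.max_axial_area(truth.label_mask, 1)
        assert area == pytest.approx(np.pi * spec.tube_radius**2, rel=0.03)

    def test_empty_mask_area_zero(self):
        assert mm.max_axial_area(_mask(np.zeros((4, 4, 4))), 1) == 0.0

    def test_area_monotone_under_dilation(self, tube):
        from scipy.ndimage import binary_dilation

        m = tube[3].label_mask
        fat = binary_dilation(m.foreground(), iterations=1)
        a0 = mm.max_axial_area(m, None)
        a1 = mm.max_axial_area(_mask(fat.astype(np.uint8), m.spacing), None)
        assert a1 >= a0


# ----------------------------------------------------------------------
# calipers
# ----------------------------------------------------------------------


class TestAxialDiameters:
    def test_cylinder_ap_equals_transverse_equals_diameter(self, tube):
        spec, _, _, truth = tube
        df = mm.axial_diameters(truth.label_mask, 1)
        mid = df.iloc[len(df) // 2]
        assert mid["ap_mm"] == pytest.approx(2 * spec.tube_radius, abs=1.0)
        assert mid["transverse_mm"] == pytest.approx(2 * spec.tube_radius,
                                                     abs=1.0)

    def test_single_voxel_measures_one_spacing_unit(self):
        data = np.zeros((8, 8, 3))
        data[4, 4, 1] = 1
        df = mm.axial_diameters(_mask(data, (0.7, 0.7, 2.0)), 1)
        assert len(df) == 1
        assert df.iloc[0]["ap_mm"] == pytest.approx(0.7)
        assert df.iloc[0]["transverse_mm"] == pytest.approx(0.7)

    def test_oblique_ellipse_matches_index_scan_oracle(self):
        # 45-degree elongated ellipse in one slice
        x, y = np.mgrid[:40, :40]
        u = (x - 20 + y - 20) / np.sqrt(2)
        v = (x - 20 - (y - 20)) / np.sqrt(2)
        el = (u / 15) ** 2 + (v / 5) ** 2 <= 1
        data = np.zeros((40, 40, 1))
        data[:, :, 0] = el
        df = mm.axial_diameters(_mask(data), 1)
        xs, ys = np.nonzero(el)
        assert df.iloc[0]["ap_mm"] == ys.max() - ys.min() + 1
        assert df.iloc[0]["transverse_mm"] == xs.max() - xs.min() + 1


class TestThreeSliceProtocol:
    def test_tube_gives_six_equal_measurements(self, tube):
        spec, _, _, truth = tube
        res = mm.three_slice_protocol(truth.label_mask, 1)
        assert len(res.measurements) == 3 and not res.truncated
        vals = [m["ap_mm"] for m in res.measurements] + \
            [m["transverse_mm"] for m in res.measurements]
        assert max(vals) - min(vals) <= 2 * max(spec.spacing[:2])

    def test_max_ap_slice_at_bulge_apex(self, abdominal):
        _, _, _, truth = abdominal
        res = mm.three_slice_protocol(truth.label_mask, None)
        center = [m for m in res.measurements if m["offset_mm"] == 0.0][0]
        apex_pt = truth.centerline_points[
            np.argmin(np.abs(truth.centerline_arc - truth.bulge_apex_arc))]
        apex_slice = apex_pt[2] / truth.label_mask.spacing[2]
        assert abs(center["slice_z"] - apex_slice) <= 2

    def test_short_mask_flags_truncation(self):
        data = np.zeros((12, 12, 3))
        data[4:8, 4:8, :] = 1
        res = mm.three_slice_protocol(_mask(data, (1, 1, 5.0)), 1)
        assert res.truncated


# ----------------------------------------------------------------------
# centerlines
# ----------------------------------------------------------------------


class TestCenterline:
    def test_straight_cylinder_axis_recovered(self, tube):
        spec, _, _, truth = tube
        cl = mm.extract_centerline(truth.label_mask, None)
        ext = np.asarray(spec.grid_shape) * np.asarray(spec.spacing)
        off = np.hypot(cl.points[:, 0] - ext[0] / 2,
                       cl.points[:, 1] - ext[1] / 2)
        assert off.max() <= max(spec.spacing)  # within one voxel of the axis

    def test_curved_phantom_follows_generating_spline(self, abdominal):
        spec, _, _, truth = abdominal
        cl = mm.extract_centerline(truth.label_mask, None)
        d, _ = cKDTree(truth.centerline_points).query(cl.points)
        assert d.mean() < 1.5 * max(spec.spacing)

    def test_single_voxel_region_is_its_own_centerline(self):
        data = np.zeros((8, 8, 8))
        data[3, 4, 5] = 1
        cl = mm.extract_centerline(_mask(data, (2, 2, 2)), 1)
        np.testing.assert_allclose(cl.points, [[6.0, 8.0, 10.0]])

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mm.extract_centerline(_mask(np.zeros((6, 6, 6))), 1)

    def test_ordered_superior_to_inferior(self, abdominal):
        cl = mm.extract_centerline(abdominal[3].label_mask, None)
        assert cl.points[0, 2] < cl.points[-1, 2]
        assert (np.diff(cl.arc_length) > 0).all()


class TestCenterlineDistances:
    def _line(self, pts):
        return mm.Centerline(np.asarray(pts, float))

    def test_identical_lines_zero(self):
        c = self._line([[0, 0, 0], [0, 0, 10], [0, 0, 20]])
        assert mm.centerline_deviation(c, c) == 0.0
        assert mm.hausdorff_distance(c, c) == 0.0

    def test_parallel_offset_lines(self):
        a = self._line([[0, 0, z] for z in range(0, 50, 2)])
        b = self._line([[3, 0, z] for z in range(0, 50, 2)])
        assert mm.centerline_deviation(a, b) == pytest.approx(3.0)
        assert mm.hausdorff_distance(a, b) == pytest.approx(3.0)

    def test_subsampled_line_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.normal(0, 1, (60, 3)), axis=0)
        a = self._line(pts)
        b = self._line(pts[::2])
        # exhaustive all-pairs nearest-neighbour oracle
        d = np.linalg.norm(a.points[:, None] - b.points[None, :], axis=2)
        expected = 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())
        assert mm.centerline_deviation(a, b) == pytest.approx(expected)
        assert mm.hausdorff_distance(a, b) == pytest.approx(
            max(d.min(axis=1).max(), d.min(axis=0).max()))

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_hausdorff_bounds_mean_deviation(self, seed):
        rng = np.random.default_rng(seed)
        a = self._line(np.cumsum(rng.normal(0, 1, (rng.integers(2, 40), 3)),
                                 axis=0))
        b = self._line(np.cumsum(rng.normal(0, 1, (rng.integers(2, 40), 3)),
                                 axis=0))
        assert mm.hausdorff_distance(a, b) >= mm.centerline_deviation(a, b) - 1e-12


# ----------------------------------------------------------------------
# profiles / straightened views
# ----------------------------------------------------------------------


class TestDiameterProfile:
    def test_straight_cylinder_constant_profile(self, tube):
        spec, _, _, truth = tube
        cl = mm.extract_centerline(truth.label_mask, None)
        prof = mm.orthogonal_diameter_profile(truth.label_mask, cl,
                                              step_mm=2.0, cls=None)
        expected = 2 * (spec.tube_radius + spec.wall_thickness)
        assert np.abs(prof.diameter_mm - expected).max() <= min(spec.spacing[:2]) + 1e-9
        assert (np.diff(prof.arc_mm) > 0).all()

    def test_bulge_profile_maximum_close_to_oracle(self, abdominal):
        spec, _, _, truth = abdominal
        cl = mm.extract_centerline(truth.label_mask, None)
        prof = mm.orthogonal_diameter_profile(truth.label_mask, cl,
                                              step_mm=2.0, cls=None)
        expected = 2 * (spec.bulge_radius + spec.wall_thickness)
        assert prof.max_diameter_mm == pytest.approx(expected, rel=0.05)

    def test_bad_step_rejected(self, tube):
        cl = mm.Centerline(np.array([[0, 0, 0], [0, 0, 10.0]]))
        with pytest.raises(ValueError):
            mm.orthogonal_diameter_profile(tube[3].label_mask, cl, step_mm=0)


class TestCompareProfiles:
    def test_identical_profiles(self):
        p = mm.DiameterProfile(np.arange(5.0), np.full(5, 30.0))
        assert mm.compare_profiles(p, p) == (0.0, 0.0)

    def test_constant_offset_gives_rmse_delta(self):
        a = mm.DiameterProfile(np.arange(10.0), np.full(10, 30.0))
        b = mm.DiameterProfile(np.arange(10.0), np.full(10, 32.5))
        rmse, _ = mm.compare_profiles(a, b)
        assert rmse == pytest.approx(2.5)

    def test_hand_built_three_sample_case(self):
        a = mm.DiameterProfile(np.array([0.0, 1, 2]), np.array([10.0, 12, 14]))
        b = mm.DiameterProfile(np.array([0.0, 1, 2]), np.array([11.0, 12, 13]))
        rmse, pct = mm.compare_profiles(a, b)
        assert rmse == pytest.approx(np.sqrt(2 / 3))
        assert pct == pytest.approx(np.mean([1 / 10.5, 0, 1 / 13.5]) * 100)

    def test_disjoint_ranges_rejected(self):
        a = mm.DiameterProfile(np.array([0.0, 1]), np.array([10.0, 10]))
        b = mm.DiameterProfile(np.array([5.0, 6]), np.array([10.0, 10]))
        with pytest.raises(ValueError, match="overlap"):
            mm.compare_profiles(a, b)


class TestStraightenedView:
    def test_straight_tube_view_matches_original(self, tube):
        from aortaseg.core import Volume

        spec, _, _, truth = tube
        cl = mm.extract_centerline(truth.label_mask, None)
        fg = Volume(truth.label_mask.foreground().astype(np.float32),
                    spec.spacing)
        sv = mm.straightened_view(fg, cl, half_width_mm=15, step_mm=1.0)
        assert sv.shape[2] == int(np.floor(cl.length)) + 1
        agree = []
        for k in range(sv.shape[2]):
            plane = sv.data[:, :, k] > 0.5
            z = int(round((cl.points[0][2] + k) / spec.spacing[2]))
            half = (plane.shape[0] - 1) // 2
            c0 = int(round(cl.points[0][0]))
            oz = truth.label_mask.foreground()[
                c0 - half:c0 + half + 1, c0 - half:c0 + half + 1,
                min(z, spec.grid_shape[2] - 1)]
            agree.append((plane == oz).mean())
        assert np.mean(agree) > 0.95

    def test_curved_tube_lumen_centered_in_every_slice(self, abdominal):
        from aortaseg.core import Volume

        spec, _, _, truth = abdominal
        cl = mm.extract_centerline(truth.label_mask, None)
        fg = Volume(truth.label_mask.foreground().astype(np.float32),
                    spec.spacing)
        sv = mm.straightened_view(fg, cl, half_width_mm=30, step_mm=2.0)
        offsets = []
        for k in range(sv.shape[2]):
            plane = sv.data[:, :, k] > 0.5
            if plane.any():
                xs, ys = np.nonzero(plane)
                offsets.append(np.hypot(xs.mean() - (plane.shape[0] - 1) / 2,
                                        ys.mean() - (plane.shape[1] - 1) / 2))
        assert np.median(offsets) <= 2.0


# ----------------------------------------------------------------------
# agreement statistics
# ----------------------------------------------------------------------


class TestAgreementStats:
    def test_exact_agreement(self):
        st_ = mm.agreement_stats([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])
        assert st_.bias == 0.0
        assert st_.pct_cv == 0.0
        assert st_.spearman_r == 1.0
        assert st_.limits_of_agreement == (0.0, 0.0)

    def test_constant_offset(self):
        st_ = mm.agreement_stats([(2.0, 1.0), (3.0, 2.0), (4.0, 3.0)])
        assert st_.bias == pytest.approx(1.0)
        assert st_.sd_diff == 0.0

    def test_icc_matches_hand_anova(self):
        pairs = [(50.1, 50.0), (62.3, 61.8), (45.0, 45.5), (70.2, 69.0),
                 (55.5, 55.1)]
        st_ = mm.agreement_stats(pairs)
        # two-way ANOVA table evaluated by hand for these five pairs
        assert st_.icc == pytest.approx(0.99773402, abs=1e-6)
        assert st_.bias == pytest.approx(0.34)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            mm.agreement_stats([(1.0, 1.0), (2.0, 2.0)])
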