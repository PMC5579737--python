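"""Foot axis, toe removal, AI thirds, MBL, arch width/height, full pipeline."""

import warnings

import numpy as np
import pytest

from footarch.arch_params import (
    DegenerateAxisError,
    FootAxis,
    align_by_pca,
    boundary_profile,
    compute_ai,
    compute_aw,
    convex_hull_indices,
    detect_heel_center,
    detect_mbl,
    foot_axis,
    heel_center,
    measure,
    segment_toes,
    split_heel_toe,
)
from footarch.io_camera import FootPointCloud
from footarch.preprocess import preprocess_frame


def brute_force_hull(points: np.ndarray) -> set:
    """O(n^3) hull oracle: a point is a hull vertex iff some half-plane
    through it contains all other points."""
    pts = np.asarray(points, float)
    n = len(pts)
    vertices = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            rel = pts - pts[i]
            cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
            if np.all(cross >= -1e-9) or np.all(cross <= 1e-9):
                vertices.add(i)
                vertices.add(j)
    return vertices


def _disk_mask(h, w, cv, cu, r):
    vv, uu = np.mgrid[0:h, 0:w]
    return (vv - cv) ** 2 + (uu - cu) ** 2 <= r * r


def _flat_cloud(shape, z=300.0, mm_per_px=1.0):
    h, w = shape
    vv, uu = np.mgrid[0:h, 0:w].astype(float)
    pts = np.stack([(uu - w / 2) * mm_per_px, (vv - h / 2) * mm_per_px,
                    np.full((h, w), z)], -1)
    return FootPointCloud(points=pts, colors=np.zeros(pts.shape),
                          valid=np.ones((h, w), bool))


class TestAlignByPca:
    def test_axis_aligned_rectangle_unchanged_up_to_ambiguity(self):
        m = np.zeros((60, 40), bool)
        m[10:50, 15:25] = True
        aligned, tf = align_by_pca(m)
        assert np.allclose(np.abs(tf.rotation), np.eye(2), atol=1e-6)

    def test_rotated_rectangle_aligned_back_within_1_degree(self):
        from scipy.ndimage import rotate

        m = np.zeros((120, 120), bool)
        m[20:100, 50:70] = True
        rot = rotate(m.astype(float), 30.0, reshape=True, order=0) > 0.5
        aligned, tf = align_by_pca(rot)
        coords = np.argwhere(aligned).astype(float)
        cov = np.cov((coords - coords.mean(0)).T)
        evals, evecs = np.linalg.eigh(cov)
        angle = np.degrees(np.arctan2(evecs[1, 1], evecs[0, 1]))
        assert min(abs(angle) % 180, 180 - abs(angle) % 180) <= 1.0

    def test_roundtrip_transform_maps_points_back(self):
        m = np.zeros((50, 50), bool)
        m[5:45, 20:30] = True
        aligned, tf = align_by_pca(m)
        p = np.array([10.0, 22.0])
        assert np.allclose(tf.to_original(tf.to_aligned(p)), p, atol=1e-9)

    def test_isotropic_disk_warns(self):
        m = _disk_mask(41, 41, 20, 20, 15)
        with pytest.warns(UserWarning):
            align_by_pca(m)


class TestSplitHeelToe:
    def test_wide_top_t_shape_is_toe_side(self):
        m = np.zeros((40, 30), bool)
        m[2:10, 2:28] = True  # wide bar on top
        m[10:38, 12:18] = True  # narrow stem
        toe, heel = split_heel_toe(m)
        assert toe[3, 5] and heel[30, 14]

    def test_synthetic_foot_forefoot_labelled_toe_side(self, clean_scene,
                                                       clean_measurement):
        aligned, tf = align_by_pca(clean_measurement.contact_mask)
        toe, heel = split_heel_toe(aligned)
        frame, gt = clean_scene
        apex_aligned = tf.to_aligned(gt.heel_apex)
        r = int(round(apex_aligned[0]))
        r = np.clip(r, 0, heel.shape[0] - 1)
        assert heel[max(r - 3, 0): r + 3].any()

    def test_symmetric_rectangle_exercises_tie(self):
        m = np.zeros((40, 20), bool)
        m[5:35, 5:15] = True
        with pytest.warns(UserWarning):
            split_heel_toe(m)


class TestBoundaryProfile:
    def test_circle_centred_at_cn_has_no_salient_points(self):
        m = _disk_mask(61, 61, 30, 30, 22)
        prof = boundary_profile(m, cn=np.array([30.0, 30.0]))
        assert prof.salient.size == 0

    def test_ellipse_salient_points_at_vertices(self):
        vv, uu = np.mgrid[0:81, 0:121].astype(float)
        m = ((uu - 60) / 50) ** 2 + ((vv - 40) / 25) ** 2 <= 1.0
        prof = boundary_profile(m, cn=np.array([40.0, 60.0]))
        cols = prof.boundary[prof.salient][:, 1]
        # the long-axis vertices at u = 10 and u = 110
        assert np.any(np.abs(cols - 10) <= 3)
        assert np.any(np.abs(cols - 110) <= 3)

    def test_profile_arrays_share_the_boundary_length(self):
        m = _disk_mask(41, 41, 20, 20, 12)
        prof = boundary_profile(m)
        n = len(prof.boundary)
        assert len(prof.li) == len(prof.l_hat) == len(prof.l_prime) == n

    def test_short_boundary_reduces_sigma_with_warning(self):
        m = np.zeros((6, 6), bool)
        m[2:4, 2:4] = True
        with pytest.warns(UserWarning):
            boundary_profile(m, sigma=5.0)


class TestHeelCenter:
    def test_rounded_heel_apex_detected(self, clean_scene,
                                        clean_measurement):
        frame, gt = clean_scene
        K = heel_center(clean_measurement.contact_mask)
        assert np.linalg.norm(K - gt.heel_apex) <= 8.0

    def test_max_distance_rule_between_salient_points(self):
        # two bumps at different distances: the farther one wins
        m = np.zeros((60, 80), bool)
        m[10:30, 10:70] = True
        m[30:40, 15:25] = True  # near bump
        m[30:48, 55:65] = True  # far bump
        cn = np.array([20.0, 40.0])
        K = detect_heel_center(m, cn=cn)
        assert np.linalg.norm(K - cn) >= 25.0
        assert K[1] > 40

    def test_half_disk_fallback_returns_farthest_point(self):
        m = _disk_mask(40, 81, 0, 40, 35)
        cn = np.array([0.0, 40.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            K = detect_heel_center(m, cn=cn)
        assert np.linalg.norm(K - cn) >= 33.0


class TestFootAxis:
    def test_vertical_foot_gives_vertical_axis(self, clean_scene,
                                               clean_measurement):
        frame, gt = clean_scene
        axis = clean_measurement.axis
        assert abs(axis.direction[1]) <= 0.06  # nearly pure row direction
        assert axis.direction[0] < 0  # anterior is up (decreasing rows)

    def test_translation_equivariance(self):
        m = np.zeros((80, 60), bool)
        m[20:70, 20:40] = True
        toe2 = np.array([10.0, 30.0])
        a1 = foot_axis(m, toe2, K=np.array([65.0, 30.0]))
        shift = np.array([7.0, -4.0])
        m2 = np.zeros_like(m)
        m2[27:77, 16:36] = True
        a2 = foot_axis(m2, toe2 + shift, K=np.array([72.0, 26.0]))
        assert np.allclose(a2.K - a1.K, shift)
        assert np.allclose(a2.direction, a1.direction, atol=1e-9)

    def test_coincident_toe2_and_heel_rejected(self):
        m = np.ones((10, 10), bool)
        with pytest.raises(DegenerateAxisError):
            foot_axis(m, np.array([5.0, 5.0]), K=np.array([5.0, 5.0]))


class TestSegmentToes:
    def test_toe_gap_edge_recovered_on_synthetic_foot(self, clean_scene,
                                                      clean_measurement):
        frame, gt = clean_scene
        cloud = preprocess_frame(frame)
        body = segment_toes(frame.color.astype(float), cloud.valid,
                            clean_measurement.axis)
        toes_removed = (gt.toe_mask & cloud.valid & ~body).sum()
        assert toes_removed / (gt.toe_mask & cloud.valid).sum() >= 0.95
        body_kept = (gt.body_mask & cloud.valid & body).sum()
        assert body_kept / (gt.body_mask & cloud.valid).sum() >= 0.95

    def test_uniform_color_keeps_whole_mask(self):
        color = np.full((60, 40, 3), 128.0)
        mask = np.zeros((60, 40), bool)
        mask[10:50, 10:30] = True
        axis = FootAxis(K=np.array([45.0, 20.0]), toe2=np.array([5.0, 20.0]),
                        direction=np.array([-1.0, 0.0]))
        body = segment_toes(color, mask, axis)
        assert np.array_equal(body, mask)

    def test_gradient_exactly_at_threshold_is_excluded(self):
        # a step whose Sobel response is exactly 50 must not fire
        color = np.full((60, 40, 3), 100.0)
        color[:20, :, :] = 100.0 + 50.0 / 4.0  # step of 12.5 -> response 50
        mask = np.zeros((60, 40), bool)
        mask[5:55, 10:30] = True
        axis = FootAxis(K=np.array([50.0, 20.0]), toe2=np.array([5.0, 20.0]),
                        direction=np.array([-1.0, 0.0]))
        body = segment_toes(color, mask, axis)
        assert np.array_equal(body, mask)


class TestComputeAI:
    def _vertical_axis(self, K, toe2):
        return FootAxis(K=np.asarray(K, float), toe2=np.asarray(toe2, float),
                        direction=np.array([-1.0, 0.0]))

    def test_solid_rectangle_spanning_lk_gives_one_third(self):
        m = np.zeros((100, 30), bool)
        m[10:91, 5:25] = True
        axis = self._vertical_axis([90.0, 15.0], [2.0, 15.0])
        ai, areas, _ = compute_ai(m, axis, np.ones_like(m))
        assert abs(ai - 100.0 / 3.0) <= 1.5  # one boundary row of slack
        assert sum(areas) == m.sum()

    def test_empty_midfoot_gives_zero(self):
        m = np.zeros((90, 30), bool)
        m[10:30, 5:25] = True  # anterior block
        m[70:90, 5:25] = True  # posterior block
        axis = self._vertical_axis([89.0, 15.0], [2.0, 15.0])
        ai, areas, axis_out = compute_ai(m, axis, np.ones_like(m))
        assert ai == 0.0
        assert areas[1] == 0

    def test_generator_scene_ai_matches_pixel_oracle(self, clean_scene,
                                                     clean_measurement):
        frame, gt = clean_scene
        assert abs(clean_measurement.AI - gt.AI_true) <= 2.0

    def test_areas_conserve_total_exactly(self, clean_measurement):
        ap = clean_measurement
        from footarch.preprocess import largest_component

        body = largest_component(ap.contact_mask & ap.main_body_mask)
        assert sum(ap.areas) == body.sum()

    def test_ai_scale_invariance(self):
        from scipy.ndimage import zoom

        m = np.zeros((120, 60), bool)
        m[10:110, 15:45] = True
        m[45:75, 30:45] = False  # medial cutout
        axis = self._vertical_axis([109.0, 30.0], [2.0, 30.0])
        ai0, _, _ = compute_ai(m, axis, np.ones_like(m))
        for scale in (0.5, 2.0):
            mz = zoom(m.astype(float), scale, order=0) > 0.5
            axz = self._vertical_axis(
                [scale * 109.0, scale * 30.0], [scale * 2.0, scale * 30.0])
            aiz, _, _ = compute_ai(mz, axz, np.ones_like(mz))
            assert abs(aiz - ai0) <= 1.0


class TestMBLAndWidths:
    def _cloud_for(self, shape, mm=1.0):
        return _flat_cloud(shape, mm_per_px=mm)

    def test_convex_blob_warns_depth_zero(self):
        m = _disk_mask(40, 40, 20, 20, 14)
        cloud = self._cloud_for((40, 40))
        with pytest.warns(UserWarning):
            mbl = detect_mbl(m, cloud)
        assert mbl.depth_px <= 3.0

    def test_two_rectangles_with_lateral_bridge(self):
        # 12 px-deep medial indentation between two blocks
        m = np.zeros((90, 40), bool)
        m[5:30, 5:35] = True
        m[60:85, 5:35] = True
        m[30:60, 5:23] = True  # bridge on the low-column (lateral) side
        cloud = self._cloud_for((90, 40))
        mbl = detect_mbl(m, cloud)
        assert abs(mbl.depth_px - 12.0) <= 1.0
        # the MBL spans the indented (high-column) side
        assert mbl.p_start[1] >= 30 and mbl.p_end[1] >= 30

    def test_hull_of_square_is_square(self):
        pts = np.array([[0, 0], [0, 10], [10, 10], [10, 0]], float)
        idx = convex_hull_indices(pts)
        assert sorted(idx) == [0, 1, 2, 3]

    def test_hull_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(4, 31))
            pts = rng.uniform(0, 100, size=(n, 2))
            got = set(int(i) for i in convex_hull_indices(pts))
            assert got == brute_force_hull(pts)

    def test_indented_rectangle_arch_width(self):
        m = np.zeros((90, 40), bool)
        m[5:85, 5:35] = True
        m[30:60, 23:35] = False  # 12 px medial indentation
        cloud = self._cloud_for((90, 40), mm=1.0)
        mbl = detect_mbl(m, cloud)
        aw = compute_aw(mbl, m, cloud, _plane_stub())
        assert abs(aw - 12.0) <= 1.5

    def test_midpoint_on_contact_gives_zero_width(self):
        m = np.zeros((60, 40), bool)
        m[5:55, 5:35] = True
        cloud = self._cloud_for((60, 40))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mbl = detect_mbl(m, cloud)
        assert compute_aw(mbl, m, cloud, _plane_stub()) <= 1.0

    def test_generator_arch_width_recovered(self, clean_measurement,
                                            clean_scene):
        _, gt = clean_scene
        assert abs(clean_measurement.AW - gt.AW_true) <= 2.0

    def test_generator_arch_height_recovered(self, clean_measurement,
                                             clean_scene):
        _, gt = clean_scene
        assert abs(clean_measurement.AH - gt.AH_true) <= 1.0

    def test_flat_foot_height_near_zero(self, flat_scene):
        frame, gt = flat_scene
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ap = measure(frame, gt.toe2_center, seed=0)
        assert ap.AH <= 1.0

    def test_tilt_changes_aw_ah_little(self, clean_measurement,
                                       tilted_scene):
        frame, gt = tilted_scene
        ap = measure(frame, gt.toe2_center, seed=0)
        assert abs(ap.AW - clean_measurement.AW) <= 2.0
        assert abs(ap.AH - clean_measurement.AH) <= 1.0


class TestMeasurePipeline:
    def test_clean_scene_within_stated_tolerances(self, clean_scene,
                                                  clean_measurement):
        frame, gt = clean_scene
        ap = clean_measurement
        assert abs(ap.AI - gt.AI_true) <= 2.0
        assert abs(ap.AW - gt.AW_true) <= 2.0
        assert abs(ap.AH - gt.AH_true) <= 1.0
        assert 0.0 <= ap.AI <= 100.0
        assert ap.AW >= 0.0 and ap.AH >= 0.0

    def test_repeatability_across_noise_seeds(self, noisy_measurements):
        arr = np.array([[m.AI, m.AW, m.AH] for m in noisy_measurements])
        stds = arr.std(axis=0, ddof=1)
        assert stds[0] <= 1.0  # AI points
        assert stds[1] <= 2.0  # AW mm
        assert stds[2] <= 1.0  # AH mm

    def test_report_dict_is_json_serializable(self, clean_measurement):
        import json

        blob = json.dumps(clean_measurement.to_dict())
        assert "AI_percent" in blob


def _plane_stub():
    from footarch.contact_points import Plane

    return Plane(normal=[0.0, 0.0, -1.0], centroid=[0.0, 0.0, 300.0])
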