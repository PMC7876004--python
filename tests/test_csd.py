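"""Cylindrical shape decomposition: skeleton extraction, partitioning,
cross-sectional analysis, reconstruction and the full decomposition."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from wm3dseg.csd import (CrossSectionContour, DecompositionInterval,
                         cross_section_contour, decompose,
                         decomposition_intervals, find_critical_points,
                         normalized_hausdorff, partition_skeleton,
                         reconstruct_gc, skeletonize)

from conftest import straight_tube


def circle_contour(center, r, tangent):
    t = np.asarray(tangent, float)
    t = t / np.linalg.norm(t)
    a = np.array([1.0, 0, 0])
    if abs(t @ a) > 0.9:
        a = np.array([0.0, 1, 0])
    u = np.cross(t, a)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    ang = np.linspace(-np.pi, np.pi, 64, endpoint=False)
    pts = np.stack((r * np.cos(ang), r * np.sin(ang)), axis=1)
    return CrossSectionContour(np.asarray(center, float), t, u, v, pts,
                               np.zeros(2))


def cross_shape(shape=(20, 80, 80), angles=(45, 225, 135, 315), radius=4):
    center = np.array([shape[0] // 2, shape[1] // 2, shape[2] // 2], float)
    mask = np.zeros(shape, bool)
    pts = np.indices(shape).reshape(3, -1).T.astype(float)
    for a in np.deg2rad(angles):
        d = np.array([0, np.cos(a), np.sin(a)])
        t = np.linspace(0, 35, 140)
        seg = center[None, :] + t[:, None] * d[None, :]
        dist, _ = cKDTree(seg).query(pts, workers=1)
        mask |= (dist <= radius).reshape(shape)
    return mask, center


class TestSkeletonize:
    def test_straight_cylinder_single_medial_branch(self):
        mask = straight_tube((100, 24, 24), (50, 12, 12), (1, 0, 0), 5)
        sk = skeletonize(mask)
        assert len(sk.branches) == 1
        assert not sk.junctions
        pts = sk.branches[0].points
        # deviation from the analytic axis (y = x = 12)
        dev = np.abs(pts[:, 1:] - 12.0).max()
        assert dev < 1.0
        # radius along the middle 80%
        n = len(pts)
        mid = sk.branches[0].radius[n // 10: -n // 10]
        assert np.all(np.abs(mid - 5.0) <= 1.0)

    def test_x_shape_four_branches_one_junction(self):
        mask, center = cross_shape()
        sk = skeletonize(mask)
        assert len(sk.branches) == 4
        assert len(sk.junctions) == 1
        jpos = next(iter(sk.node_pos[n] for n in sk.junctions))
        assert np.linalg.norm(jpos - center) <= 2.5

    def test_sphere_has_no_junctions(self):
        zz, yy, xx = np.indices((30, 30, 30))
        ball = (zz - 15) ** 2 + (yy - 15) ** 2 + (xx - 15) ** 2 <= 81
        sk = skeletonize(ball)
        assert not sk.junctions
        assert len(sk.branches) <= 1

    def test_empty_and_disconnected_rejected(self):
        with pytest.raises(ValueError):
            skeletonize(np.zeros((5, 5, 5), bool))
        two = np.zeros((10, 10, 10), bool)
        two[1:3, 1:3, 1:3] = True
        two[7:9, 7:9, 7:9] = True
        with pytest.raises(ValueError):
            skeletonize(two)


class TestPartition:
    def test_x_shape_pairs_collinear_branches(self):
        mask, _ = cross_shape()
        subs = partition_skeleton(skeletonize(mask))
        assert len(subs) == 2
        assert sorted(len(s.branch_ids) for s in subs) == [2, 2]
        # each sub-skeleton is nearly straight
        for s in subs:
            from wm3dseg.morpho import tortuosity
            assert tortuosity(s.points) < 1.1

    def test_y_shape_best_pair_plus_singleton(self):
        mask, _ = cross_shape(angles=(90, 210, 330))
        subs = partition_skeleton(skeletonize(mask))
        assert len(subs) == 2
        assert sorted(len(s.branch_ids) for s in subs) == [1, 2]

    def test_single_branch_is_its_own_subskeleton(self):
        mask = straight_tube((60, 20, 20), (30, 10, 10), (1, 0, 0), 4)
        subs = partition_skeleton(skeletonize(mask))
        assert len(subs) == 1


class TestIntervals:
    def _tube_psi(self):
        mask = straight_tube((100, 24, 24), (50, 12, 12), (1, 0, 0), 5)
        sk = skeletonize(mask)
        return partition_skeleton(sk)[0], sk

    def test_interval_arithmetic(self):
        psi, sk = self._tube_psi()
        # fabricate a junction in the middle with r_j = 5
        mid = psi.length / 2
        nid = 999
        sk.node_pos[nid] = psi.at_arc(mid)
        sk.node_radius[nid] = 5.0
        sk.junctions[nid] = []
        psi.junction_nodes.append(nid)
        ivs = decomposition_intervals(psi, sk, alpha_s=5, alpha_e=1.5)
        prox = [iv for iv in ivs if iv.side == "proximal"][0]
        dist = [iv for iv in ivs if iv.side == "distal"][0]
        assert prox.s_near == pytest.approx(mid - 1.5 * 5, abs=0.5)
        assert prox.s_far == pytest.approx(mid - 5 * 5, abs=0.5)
        assert dist.s_near == pytest.approx(mid + 1.5 * 5, abs=0.5)
        assert dist.s_far == pytest.approx(mid + 5 * 5, abs=0.5)

    def test_interval_clipped_at_subskeleton_end(self):
        psi, sk = self._tube_psi()
        nid = 998
        sk.node_pos[nid] = psi.at_arc(2.0)   # junction close to the end
        sk.node_radius[nid] = 5.0
        sk.junctions[nid] = []
        psi.junction_nodes.append(nid)
        ivs = decomposition_intervals(psi, sk, alpha_s=10, alpha_e=1.5)
        # proximal window [alpha_e*r, alpha_s*r] falls off the end: empty
        assert all(iv.side == "distal" for iv in ivs)

    def test_no_junction_no_intervals(self):
        psi, sk = self._tube_psi()
        assert decomposition_intervals(psi, sk) == []


class TestCrossSections:
    def test_perpendicular_circle(self):
        mask = straight_tube((60, 60, 60), (30, 30, 30), (1, 0, 0), 5)
        c = cross_section_contour(mask, (30, 30, 30), (1, 0, 0))
        r = np.linalg.norm(c.points2d, axis=1)
        assert np.abs(r - 5.0).max() < 0.75

    def test_tilted_plane_gives_elongated_ellipse(self):
        mask = straight_tube((60, 60, 60), (30, 30, 30), (1, 0, 0), 5)
        tang = np.array([np.cos(np.deg2rad(60)), 0, np.sin(np.deg2rad(60))])
        c = cross_section_contour(mask, (30, 30, 30), tang)
        r = np.linalg.norm(c.points2d, axis=1)
        assert r.max() / r.min() == pytest.approx(2.0, abs=0.4)

    def test_in_plane_connectivity_excludes_second_tube(self):
        shape = (40, 40, 40)
        a = straight_tube(shape, (20, 12, 20), (1, 0, 0), 4)
        b = straight_tube(shape, (20, 30, 20), (1, 0, 0), 4)
        c = cross_section_contour(a | b, (20, 12, 20), (1, 0, 0))
        # contour stays on tube A: no point reaches tube B's centre
        pts = c.points3d()
        assert np.abs(pts[:, 1] - 12).max() < 10

    def test_outside_point_rejected(self):
        mask = straight_tube((40, 40, 40), (20, 20, 20), (1, 0, 0), 4)
        with pytest.raises(ValueError):
            cross_section_contour(mask, (20, 2, 2), (1, 0, 0))


class TestNormalizedHausdorff:
    def test_identical_contours_zero(self):
        c = circle_contour((0, 0, 0), 5, (1, 0, 0))
        assert normalized_hausdorff(c, c) == 0.0

    def test_concentric_circles_closed_form(self):
        c1 = circle_contour((0, 0, 0), 5, (1, 0, 0))
        c2 = circle_contour((0, 0, 0), 10, (1, 0, 0))
        assert normalized_hausdorff(c2, c1) == pytest.approx(1.0, abs=1e-9)

    def test_translation_invariance(self):
        c1 = circle_contour((0, 0, 0), 5, (1, 0, 0))
        c2 = circle_contour((7, 3, -2), 5, (1, 0, 0))
        assert normalized_hausdorff(c2, c1) == pytest.approx(0.0, abs=1e-9)


class TestCriticalPoints:
    def test_uniform_cylinder_has_none(self):
        mask = straight_tube((100, 24, 24), (50, 12, 12), (1, 0, 0), 5)
        sk = skeletonize(mask)
        psi = partition_skeleton(sk)[0]
        iv = DecompositionInterval(0, 0, psi.length / 2, "proximal",
                                   s_near=psi.length / 2 - 5,
                                   s_far=max(psi.length / 2 - 45, 2))
        assert find_critical_points(mask, psi, iv) is None

    def test_stepped_tube_detected_near_step(self):
        shape = (120, 40, 40)
        zz, yy, xx = np.indices(shape)
        rr = (yy - 20) ** 2 + (xx - 20) ** 2
        mask = (rr <= 16) & (zz < 60) | (rr <= 144) & (zz >= 60)
        sk = skeletonize(mask)
        psi = max(partition_skeleton(sk), key=lambda s: s.length)
        d = np.linalg.norm(psi.points - np.array([60, 20, 20]), axis=1)
        step_arc = psi.arc[int(np.argmin(d))]
        # walk from the thin side: the running mean is the small contour, so
        # the jump to radius 3r scores H_rho ~ 2 > theta_h
        thin_arc = psi.arc[int(np.argmin(
            np.linalg.norm(psi.points - np.array([30, 20, 20]), axis=1)))]
        if thin_arc > step_arc:
            iv = DecompositionInterval(0, 0, step_arc, "distal",
                                       s_near=step_arc - 4,
                                       s_far=min(step_arc + 40, psi.length))
        else:
            iv = DecompositionInterval(0, 0, step_arc, "proximal",
                                       s_near=step_arc + 4,
                                       s_far=max(step_arc - 40, 1))
        res = find_critical_points(mask, psi, iv, theta_h=0.85)
        assert res is not None
        s_crit, _ = res
        crit_pos = psi.at_arc(s_crit)
        assert abs(crit_pos[0] - 60) <= 4


class TestReconstruct:
    def test_cylinder_volume(self):
        c1 = circle_contour((4, 32, 32), 5, (1, 0, 0))
        c2 = circle_contour((34, 32, 32), 5, (1, 0, 0))
        zeta = np.stack((np.linspace(4, 34, 50), np.full(50, 32.0),
                         np.full(50, 32.0)), axis=1)
        m = reconstruct_gc(c1, c2, zeta, (40, 64, 64))
        assert m.sum() == pytest.approx(np.pi * 25 * 30, rel=0.05)

    def test_frustum_volume(self):
        c1 = circle_contour((4, 32, 32), 3, (1, 0, 0))
        c2 = circle_contour((34, 32, 32), 6, (1, 0, 0))
        zeta = np.stack((np.linspace(4, 34, 50), np.full(50, 32.0),
                         np.full(50, 32.0)), axis=1)
        m = reconstruct_gc(c1, c2, zeta, (40, 64, 64))
        expected = np.pi * 30 * (9 + 18 + 36) / 3
        assert m.sum() == pytest.approx(expected, rel=0.05)

    def test_bent_tube_contains_center_curve(self):
        th = np.linspace(0, np.pi, 60)
        zeta = np.stack((np.full(60, 32.0), 30 + 20 * np.cos(th),
                         30 + 20 * np.sin(th)), axis=1)
        c1 = circle_contour(zeta[0], 4, zeta[1] - zeta[0])
        c2 = circle_contour(zeta[-1], 4, zeta[-1] - zeta[-2])
        m = reconstruct_gc(c1, c2, zeta, (64, 70, 70))
        idx = np.rint(zeta).astype(int)
        assert m[idx[:, 0], idx[:, 1], idx[:, 2]].all()

    def test_zero_length_curve_rejected(self):
        c = circle_contour((10, 10, 10), 3, (1, 0, 0))
        with pytest.raises(ValueError):
            reconstruct_gc(c, c, np.array([[10.0, 10, 10], [10, 10, 10]]),
                           (20, 20, 20))


class TestDecompose:
    def test_single_tube_identity(self):
        mask = straight_tube((64, 24, 24), (32, 12, 12), (1, 0, 0), 5)
        res = decompose(mask)
        assert res.n_components == 1
        assert np.sum(res.masks[0] & mask) / mask.sum() >= 0.99

    def test_two_merged_tubes_recovered(self, merged_two_tube_phantom):
        _, _, truth = merged_two_tube_phantom
        obj = (truth.axon_labels.data > 0) | (truth.mito_labels.data > 0)
        res = decompose(obj)
        assert res.n_components == 2
        for m in res.masks:
            dice = max(2 * np.sum(m & am) / (m.sum() + am.sum())
                       for am in truth.axon_masks)
            assert dice >= 0.9

    def test_voxel_conservation_and_bounded_overlap(self,
                                                    merged_two_tube_phantom):
        _, _, truth = merged_two_tube_phantom
        obj = (truth.axon_labels.data > 0) | (truth.mito_labels.data > 0)
        res = decompose(obj)
        union = np.zeros_like(obj)
        overlap = np.zeros(obj.shape, np.int16)
        for m in res.masks:
            union |= m
            overlap += m
        assert (obj & ~union).sum() == 0          # every voxel labeled
        assert (overlap > 1).sum() <= 0.08 * obj.sum()

    def test_label_count_equals_subskeleton_count(self):
        mask, _ = cross_shape()
        res = decompose(mask)
        assert res.n_components == len(res.sub_skeletons) == 2
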