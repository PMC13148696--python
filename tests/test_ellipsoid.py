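import itertools
import math

import numpy as np
import pytest

from nichescape import (ClimateStack, Ellipsoid, GridTransform, constrain_range,
                        fit_mve, mahalanobis2, mcp_buffer, predict_presence)
from nichescape.ellipsoid import unit_ball_volume
from conftest import make_occ


def brute_force_mve_volume(points, h):
    """Independent oracle: enumerate every h-subset, build the ellipsoid from
    the subset mean/covariance with radius^2 = h-th smallest squared
    Mahalanobis distance over all points, return the minimum volume."""
    n, d = points.shape
    best = np.inf
    for idx in itertools.combinations(range(n), h):
        sub = points[list(idx)]
        mu = sub.mean(axis=0)
        cov = (sub - mu).T @ (sub - mu) / h
        if np.linalg.det(cov) <= 1e-14:
            continue
        inv = np.linalg.inv(cov)
        d2 = np.sort([float((p - mu) @ inv @ (p - mu)) for p in points])
        r2 = d2[h - 1]
        vol = unit_ball_volume(d) * math.sqrt(np.linalg.det(cov)) * r2 ** (d / 2)
        best = min(best, vol)
    return best


class TestMahalanobis:
    def test_zero_at_centroid(self):
        e = Ellipsoid(np.array([1.0, 2.0]), np.array([[2.0, 0.3], [0.3, 1.0]]), 4.0)
        assert mahalanobis2(np.array([1.0, 2.0]), e) == pytest.approx(0.0)

    def test_identity_covariance_reduces_to_euclidean(self):
        e = Ellipsoid(np.zeros(3), np.eye(3), 1.0)
        p = np.array([1.0, 2.0, 2.0])
        assert mahalanobis2(p, e) == pytest.approx(9.0)

    def test_matches_independent_linear_solve(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(3, 3))
        cov = A @ A.T + np.eye(3)
        mu = rng.normal(size=3)
        e = Ellipsoid(mu, cov, 2.0)
        p = rng.normal(size=3)
        expected = float((p - mu) @ np.linalg.solve(cov, p - mu))
        assert mahalanobis2(p, e) == pytest.approx(expected, rel=1e-10)

    def test_dimension_mismatch_raises(self):
        e = Ellipsoid(np.zeros(2), np.eye(2), 1.0)
        with pytest.raises(ValueError):
            mahalanobis2(np.zeros(3), e)


class TestFitMVE:
    def test_symmetric_cross_centroid(self):
        pts = np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]])
        e = fit_mve(pts, coverage=1.0, seed=0)
        np.testing.assert_allclose(e.centroid, [0, 0], atol=1e-9)

    def test_exact_coverage_count(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(100, 2))
        e = fit_mve(pts, coverage=0.95, seed=1)
        d2 = e.mahalanobis2(pts)
        assert int((d2 <= e.radius2).sum()) == 95

    def test_volume_recovery_uniform_rotated_ellipse(self):
        # 1000 points uniform in an ellipse with semi-axes 3 and 1 at 30 deg
        rng = np.random.default_rng(7)
        n = 1000
        r = np.sqrt(rng.random(n))
        th = rng.uniform(0, 2 * np.pi, n)
        xy = np.column_stack([3 * r * np.cos(th), r * np.sin(th)])
        rot = np.array([[np.cos(np.pi / 6), -np.sin(np.pi / 6)],
                        [np.sin(np.pi / 6), np.cos(np.pi / 6)]])
        pts = xy @ rot.T
        e = fit_mve(pts, coverage=1.0, seed=2)
        assert e.volume == pytest.approx(3 * np.pi, rel=0.10)

    def test_agrees_with_exhaustive_subset_enumeration(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(12, 2))
        h = 9
        oracle = brute_force_mve_volume(pts, h)
        e = fit_mve(pts, coverage=h / 12, seed=5, n_starts=200)
        assert e.volume == pytest.approx(oracle, rel=1e-8)

    def test_volume_monotone_in_coverage(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(60, 2))
        vols = [fit_mve(pts, c, seed=1).volume for c in (1.0, 0.95, 0.9)]
        assert vols[0] >= vols[1] >= vols[2]

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="too few"):
            fit_mve(np.zeros((3, 2)) + np.arange(6).reshape(3, 2), seed=0)

    def test_rank_deficient_points_raise(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="rank|dimension"):
            fit_mve(pts, seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(21)
        pts = rng.normal(size=(50, 3))
        a = fit_mve(pts, 0.95, seed=9)
        b = fit_mve(pts, 0.95, seed=9)
        np.testing.assert_array_equal(a.centroid, b.centroid)
        assert a.radius2 == b.radius2


class TestPredictPresence:
    def pc_stack(self):
        rng = np.random.default_rng(1)
        layers = {"pc1": rng.normal(0, 1, (8, 8)), "pc2": rng.normal(0, 1, (8, 8))}
        return ClimateStack(layers=layers, transform=GridTransform(0, 8, 1.0))

    def test_centroid_cell_present(self):
        stack = self.pc_stack()
        mu = np.array([stack.layers["pc1"][3, 3], stack.layers["pc2"][3, 3]])
        e = Ellipsoid(mu, np.eye(2), 0.5)
        assert predict_presence(e, stack)[3, 3] == 1

    def test_huge_radius_saturates(self):
        stack = self.pc_stack()
        e = Ellipsoid(np.zeros(2), np.eye(2), 1e6)
        pres = predict_presence(e, stack)
        assert (pres == 1).all()

    def test_count_matches_cell_loop_oracle(self):
        stack = self.pc_stack()
        e = Ellipsoid(np.array([0.2, -0.1]), np.array([[1.0, 0.2], [0.2, 0.8]]), 1.5)
        pres = predict_presence(e, stack)
        inv = np.linalg.inv(e.covariance)
        count = 0
        for r in range(8):
            for c in range(8):
                v = np.array([stack.layers["pc1"][r, c], stack.layers["pc2"][r, c]])
                if float((v - e.centroid) @ inv @ (v - e.centroid)) <= e.radius2:
                    count += 1
        assert int((pres == 1).sum()) == count

    def test_nodata_stays_nodata(self):
        stack = self.pc_stack()
        stack.nodata_mask[0, 0] = True
        e = Ellipsoid(np.zeros(2), np.eye(2), 1e6)
        assert np.isnan(predict_presence(e, stack)[0, 0])

    def test_dimension_mismatch_raises(self):
        stack = self.pc_stack()
        e = Ellipsoid(np.zeros(3), np.eye(3), 1.0)
        with pytest.raises(ValueError, match="dimension"):
            predict_presence(e, stack)

    def test_full_coverage_fit_contains_fitting_points(self):
        stack = self.pc_stack()
        pts = np.column_stack([stack.layers["pc1"].ravel()[:20],
                               stack.layers["pc2"].ravel()[:20]])
        e = fit_mve(pts, coverage=1.0, seed=0)
        pres = predict_presence(e, stack)
        flat = pres.ravel()
        assert (flat[:20] == 1).all()


class TestMCPBuffer:
    def test_right_triangle_zero_buffer_area(self):
        occ = make_occ([(0, 0), (1, 0), (0, 1)])
        poly = mcp_buffer(occ, buffer_km=0)
        assert poly.area == pytest.approx(0.5)

    def test_single_point_buffer_is_disk(self):
        occ = make_occ([(5, 5)])
        poly = mcp_buffer(occ, buffer_km=3.0)
        assert poly.area == pytest.approx(np.pi * 9, rel=0.01)

    def test_hull_vertices_match_gift_wrapping_oracle(self):
        rng = np.random.default_rng(17)
        pts = [tuple(p) for p in rng.uniform(0, 10, (30, 2))]
        occ = make_occ(pts)
        poly = mcp_buffer(occ, buffer_km=0)

        def gift_wrap(points):
            pts_ = sorted(set(points))
            start = min(pts_)
            hull, p = [], start
            while True:
                hull.append(p)
                q = pts_[0] if pts_[0] != p else pts_[1]
                for r in pts_:
                    cross = ((q[0] - p[0]) * (r[1] - p[1])
                             - (q[1] - p[1]) * (r[0] - p[0]))
                    if r != p and (cross < 0 or (cross == 0 and
                                   np.hypot(r[0] - p[0], r[1] - p[1])
                                   > np.hypot(q[0] - p[0], q[1] - p[1]))):
                        q = r
                p = q
                if p == start:
                    return set(hull)

        oracle = gift_wrap(pts)
        got = {(round(x, 9), round(y, 9)) for x, y in poly.exterior.coords}
        expected = {(round(x, 9), round(y, 9)) for x, y in oracle}
        assert got == expected


class TestConstrainRange:
    def grid(self):
        layers = {"pc1": np.zeros((6, 6))}
        return ClimateStack(layers=layers, transform=GridTransform(0, 6, 1.0))

    def test_full_extent_is_identity(self):
        from shapely.geometry import box
        stack = self.grid()
        presence = np.ones((6, 6))
        rm = constrain_range(presence, box(-1, -1, 7, 7), stack, "sp")
        assert len(rm.cells) == 36

    def test_disjoint_constraint_empties_range(self):
        from shapely.geometry import box
        stack = self.grid()
        rm = constrain_range(np.ones((6, 6)), box(10, 10, 12, 12), stack, "sp")
        assert rm.cells == set()

    def test_matches_containment_oracle(self):
        from shapely.geometry import Point, box
        stack = self.grid()
        rng = np.random.default_rng(23)
        presence = (rng.random((6, 6)) < 0.6).astype(float)
        poly = box(0.7, 1.3, 4.9, 5.2)
        rm = constrain_range(presence, poly, stack, "sp")
        oracle = set()
        for r in range(6):
            for c in range(6):
                x, y = stack.transform.cell_center(r, c)
                if presence[r, c] == 1 and poly.contains(Point(x, y)):
                    oracle.add((r, c))
        assert rm.cells == oracle
        assert rm.cells <= {(r, c) for r, c in zip(*np.nonzero(presence == 1))}


def test_volume_invariant_under_rotation():
    rng = np.random.default_rng(29)
    pts = rng.normal(size=(80, 2)) @ np.diag([2.0, 0.5])
    th = 0.7
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    v1 = fit_mve(pts, 0.95, seed=4).volume
    v2 = fit_mve(pts @ rot.T, 0.95, seed=4).volume
    assert v2 == pytest.approx(v1, rel=1e-6)
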