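"""Geometric primitives against hand values and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from auriclometry.errors import ArgumentError, DegenerateGeometryError
from auriclometry import geometry as g
from tests.conftest import random_rotation


# ---------------------------------------------------------------- oracles


def svd_plane_oracle(points):
    """Smallest right-singular-vector of the centered coordinate matrix."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c)
    n = vt[2]
    return n, float(np.dot(n, c))


def brute_nn_distances(source, target):
    """O(n*m) nearest-neighbour scan without a spatial index."""
    d = np.linalg.norm(source[:, None, :] - target[None, :, :], axis=-1)
    return d.min(axis=1)


def moller_trumbore_scalar(origin, direction, triangles, eps=1e-12):
    """Per-triangle scalar Möller–Trumbore scan; returns sorted t values."""
    hits = []
    for v0, v1, v2 in triangles:
        e1, e2 = v1 - v0, v2 - v0
        pvec = np.cross(direction, e2)
        det = float(np.dot(e1, pvec))
        if abs(det) < eps:
            continue
        tvec = origin - v0
        u = float(np.dot(tvec, pvec)) / det
        qvec = np.cross(tvec, e1)
        v = float(np.dot(direction, qvec)) / det
        if u < -eps or v < -eps or u + v > 1 + eps:
            continue
        hits.append(float(np.dot(e2, qvec)) / det)
    return np.sort(hits)


def gift_wrap_hull(points):
    """O(nh) gift-wrapping convex hull, CCW vertex indices."""
    n = len(points)
    start = min(range(n), key=lambda i: (points[i][0], points[i][1]))
    hull = [start]
    while True:
        cur = hull[-1]
        cand = (cur + 1) % n
        for i in range(n):
            if i == cur:
                continue
            a = points[cand] - points[cur]
            b = points[i] - points[cur]
            cross = a[0] * b[1] - a[1] * b[0]
            if cross < -1e-12 or (
                abs(cross) < 1e-12
                and np.linalg.norm(points[i] - points[cur])
                > np.linalg.norm(points[cand] - points[cur])
            ):
                cand = i
        if cand == start:
            break
        hull.append(cand)
    return np.array(hull)


# ---------------------------------------------------------------- plane fit


class TestFitPlane:
    def test_exact_plane(self):
        plane = g.fit_plane_lsq(
            [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)], orientation_hint=(0, 0, 1)
        )
        np.testing.assert_allclose(plane.normal, [0, 0, 1], atol=1e-12)
        assert abs(plane.offset) < 1e-12
        assert np.allclose(plane.signed_distance([(0.3, 0.7, 0)]), 0, atol=1e-12)

    def test_matches_svd_oracle_on_noisy_plane(self, rng):
        xy = rng.uniform(-5, 5, size=(200, 2))
        z = 0.5 * xy[:, 0] + 2.0 + rng.normal(0, 0.1, 200)
        pts = np.column_stack([xy, z])
        plane = g.fit_plane_lsq(pts, orientation_hint=(0, 0, 1))
        n_oracle, off_oracle = svd_plane_oracle(pts)
        if n_oracle[2] < 0:
            n_oracle, off_oracle = -n_oracle, -off_oracle
        np.testing.assert_allclose(plane.normal, n_oracle, atol=1e-9)
        assert abs(plane.offset - off_oracle) < 1e-9

    def test_collinear_raises(self):
        with pytest.raises(DegenerateGeometryError):
            g.fit_plane_lsq([(0, 0, 0), (1, 1, 1), (2, 2, 2)])

    def test_rigid_invariance(self, rng):
        pts = rng.uniform(-10, 10, size=(50, 2))
        pts3 = np.column_stack([pts, 0.2 * pts[:, 0] - 0.1 * pts[:, 1] + 3])
        R = random_rotation(rng)
        t = rng.uniform(-5, 5, 3)
        p1 = g.fit_plane_lsq(pts3, orientation_hint=(0, 0, 1))
        p2 = g.fit_plane_lsq(pts3 @ R.T + t, orientation_hint=R @ np.array([0, 0, 1.0]))
        np.testing.assert_allclose(p2.normal, R @ p1.normal, atol=1e-9)
        # transformed in-plane point must satisfy the transformed plane
        q = p1.project(np.zeros(3))[0]
        assert abs(p2.signed_distance((R @ q + t)[None])[0]) < 1e-9


# --------------------------------------------------- trimmed NN distance


class TestTrimmedNN:
    def test_self_distance_is_zero(self, rng):
        pts = rng.normal(size=(40, 3))
        assert g.trimmed_mean_nn_distance(pts, pts) == 0.0

    def test_hand_computed_trimming(self):
        # per-point NN distances {1,1,1,1,10}: mean 2.8, population SD 3.6,
        # cutoff 4.6 excludes the 10 -> trimmed mean 1.0
        source = np.array([[0, 0, 0], [2, 0, 0], [4, 0, 0], [6, 0, 0], [100, 0, 0]], float)
        target = np.array([[1, 0, 0], [3, 0, 0], [5, 0, 0], [7, 0, 0], [110, 0, 0]], float)
        assert g.trimmed_mean_nn_distance(source, target) == pytest.approx(1.0)
        # same exclusion holds under the sample-SD convention
        assert g.trimmed_mean_nn_distance(source, target, sd_mode="sample") == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        a = rng.uniform(-3, 3, size=(50, 3))
        b = rng.uniform(-3, 3, size=(50, 3))
        d = brute_nn_distances(a, b)
        expected = g.trimmed_mean(d)
        assert g.trimmed_mean_nn_distance(a, b) == pytest.approx(expected, abs=0)

    def test_trimmed_le_untrimmed(self, rng):
        a = rng.uniform(-3, 3, size=(80, 3))
        b = rng.uniform(-3, 3, size=(60, 3))
        untrimmed = brute_nn_distances(a, b).mean()
        assert g.trimmed_mean_nn_distance(a, b) <= untrimmed + 1e-12

    def test_empty_raises(self):
        with pytest.raises(ArgumentError):
            g.trimmed_mean_nn_distance(np.zeros((0, 3)), np.zeros((3, 3)))


# ------------------------------------------------------- ray-mesh intersect


class TestRayMesh:
    def test_closed_cube_two_hits(self, unit_cube):
        hits = g.intersect_line_with_mesh([-5, 0.1, 0.2], [1, 0, 0], unit_cube, (0, 100))
        assert len(hits) == 2
        assert hits[0][0] == pytest.approx(4.0)
        assert hits[1][0] == pytest.approx(6.0)

    def test_matches_brute_force_scan(self, rng):
        mesh = trimesh.creation.icosphere(2, radius=3.0)  # 320 faces
        assert len(mesh.faces) >= 300
        tri = mesh.triangles
        for _ in range(30):
            origin = rng.uniform(-6, 6, 3)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            hits = g.intersect_line_with_mesh(origin, direction, mesh, (-50, 50))
            t_pkg = np.array([t for t, _ in hits])
            t_oracle = moller_trumbore_scalar(origin, direction, tri)
            # oracle does not deduplicate shared-edge hits
            keep = np.concatenate([[True], np.diff(t_oracle) > 1e-6]) if t_oracle.size else np.array([], bool)
            np.testing.assert_allclose(t_pkg, t_oracle[keep], atol=1e-9)

    def test_parallel_miss(self):
        tri = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]], faces=[[0, 1, 2]], process=False
        )
        hits = g.intersect_line_with_mesh([0, 0, 1], [1, 0, 0], tri, (-10, 10))
        assert hits == []

    def test_even_parity_on_closed_mesh(self, rng):
        mesh = trimesh.creation.icosphere(3, radius=2.0)
        for _ in range(20):
            origin = rng.uniform(-5, -4, 3)
            target = rng.uniform(-1, 1, 3)
            d = target - origin
            d /= np.linalg.norm(d)
            hits = g.intersect_line_with_mesh(origin, d, mesh, (-100, 100))
            assert len(hits) % 2 == 0


# --------------------------------------------------------------- 2-D ops


class TestHullDiameter:
    def test_square_hull(self, rng):
        corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        pts = np.vstack([corners, rng.uniform(0.05, 0.95, size=(50, 2))])
        hull = g.convex_hull_2d(pts)
        assert sorted(hull) == [0, 1, 2, 3]

    def test_matches_gift_wrapping(self, rng):
        pts = rng.normal(size=(300, 2))
        assert sorted(g.convex_hull_2d(pts)) == sorted(gift_wrap_hull(pts))

    def test_triangle(self):
        assert sorted(g.convex_hull_2d(np.array([[0, 0], [2, 0], [1, 1.5]]))) == [0, 1, 2]

    def test_collinear_raises(self):
        with pytest.raises(DegenerateGeometryError):
            g.convex_hull_2d(np.array([[0, 0], [1, 1], [2, 2], [3, 3.0]]))

    def test_rectangle_diameter_tie_break(self):
        pts = np.array([[0, 0], [4, 0], [0, 3], [4, 3.0]])
        length, i, j = g.diameter_2d(pts)
        assert length == pytest.approx(5.0)
        assert (i, j) == (0, 3)  # lexicographically smallest of the tied diagonals

    def test_diameter_matches_brute_force(self, rng):
        pts = rng.normal(size=(1000, 2)) * [3, 1]
        length, i, j = g.diameter_2d(pts)
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        assert length == pytest.approx(np.sqrt(d2.max()), abs=0)

    def test_two_points(self):
        length, i, j = g.diameter_2d(np.array([[0, 0], [3, 4.0]]))
        assert length == pytest.approx(5.0) and (i, j) == (0, 1)

    def test_diameter_endpoints_are_hull_vertices(self, rng):
        pts = rng.normal(size=(400, 2))
        _, i, j = g.diameter_2d(pts)
        hull = set(g.convex_hull_2d(pts).tolist())
        assert i in hull and j in hull


class TestExtents:
    def test_rectangle_perpendicular_extent(self):
        pts = np.array([[0, 0], [4, 0], [0, 3], [4, 3.0]])
        width, line = g.perpendicular_extent_2d(pts, np.array([4, 3]) / 5.0)
        assert width == pytest.approx(4.8)
        lo, hi = line
        assert np.linalg.norm(hi - lo) == pytest.approx(4.8)

    def test_points_on_axis_zero_width(self):
        pts = np.array([[0, 0], [1, 0], [2, 0.0]])
        width, _ = g.perpendicular_extent_2d(pts, np.array([1.0, 0]))
        assert width == pytest.approx(0.0, abs=1e-12)

    def test_ellipse_minor_extent(self):
        th = np.radians(np.arange(360))
        pts = np.column_stack([30 * np.cos(th), 17.5 * np.sin(th)])
        width, _ = g.perpendicular_extent_2d(pts, np.array([1.0, 0]))
        assert width == pytest.approx(35.0, abs=0.02)

    def test_rectangle_bounding_extents(self):
        pts = np.array([[0, 0], [4, 0], [0, 3], [4, 3.0]])
        ext = g.bounding_extents_along_axes(pts, (np.array([1.0, 0]), np.array([0, 1.0])))
        assert ext == pytest.approx((4.0, 3.0))

    def test_repeated_point_extents_zero(self):
        pts = np.zeros((5, 2))
        ext = g.bounding_extents_along_axes(pts, (np.array([1.0, 0]), np.array([0, 1.0])))
        assert ext == (0.0, 0.0)


class TestInertiaAxes:
    def test_rectangle_axes(self):
        pts = np.array([[2, 1.5], [-2, 1.5], [2, -1.5], [-2, -1.5]])
        length_axis, width_axis, evals, iso = g.inertia_axes_2d(pts)
        # moment about the u axis (sum v^2 = 9) < about v (sum u^2 = 16)
        np.testing.assert_allclose(evals, [9.0, 16.0])
        np.testing.assert_allclose(np.abs(length_axis), [1, 0], atol=1e-12)
        assert not iso

    def test_circle_isotropic(self):
        th = np.radians(np.arange(0, 360, 5))
        pts = np.column_stack([np.cos(th), np.sin(th)])
        length_axis, width_axis, _, iso = g.inertia_axes_2d(pts)
        assert iso
        np.testing.assert_allclose(length_axis, [1, 0])
        np.testing.assert_allclose(width_axis, [0, 1])

    def test_dense_ellipse_major_axis(self):
        th = np.radians(np.arange(360))
        pts = np.column_stack([30 * np.cos(th), 17.5 * np.sin(th)])
        R = np.array(
            [
                [np.cos(np.radians(25)), -np.sin(np.radians(25))],
                [np.sin(np.radians(25)), np.cos(np.radians(25))],
            ]
        )
        length_axis, _, _, _ = g.inertia_axes_2d(pts @ R.T)
        major = R @ np.array([1.0, 0])
        ang = np.degrees(np.arccos(min(abs(float(np.dot(length_axis, major))), 1.0)))
        assert ang < 0.5

    def test_extents_rotation_invariant(self, rng):
        pts = rng.normal(size=(200, 2)) * [4, 1.5]
        la, wa, _, _ = g.inertia_axes_2d(pts)
        e1 = g.bounding_extents_along_axes(pts, (la, wa))
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rpts = pts @ R.T
        la2, wa2, _, _ = g.inertia_axes_2d(rpts)
        e2 = g.bounding_extents_along_axes(rpts, (la2, wa2))
        np.testing.assert_allclose(e1, e2, atol=1e-9)

    def test_collinear_raises(self):
        with pytest.raises(DegenerateGeometryError):
            g.inertia_axes_2d(np.column_stack([np.arange(5.0), np.arange(5.0) * 2]))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_trimmed_nn_never_exceeds_mean(seed):
    """Property: trimming can only lower the mean NN distance."""
    r = np.random.default_rng(seed)
    a = r.normal(size=(30, 3))
    b = r.normal(size=(25, 3))
    assert g.trimmed_mean_nn_distance(a, b) <= brute_nn_distances(a, b).mean() + 1e-12
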