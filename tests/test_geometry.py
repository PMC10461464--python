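"""Hull construction, point-triangle distances, face-distance profiles, and
the analytic sphere reference formulas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from insideoutside import (PointCloud, build_hull, equidistant_sphere_points,
                           face_distance_profile, point_triangle_distance,
                           sphere_min_distance, sphere_variance,
                           sphere_variance_vs_min_distance)
from insideoutside import test_points_along_radius as radial_probe_points
from insideoutside.geometry import (DegenerateGeometryError,
                                    InsufficientPointsError,
                                    cloud_distance_profiles,
                                    points_triangles_distance)

TRI = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])


# ---------------------------------------------------------------------------
# hulls
# ---------------------------------------------------------------------------

class TestBuildHull:
    def test_tetrahedron_is_own_hull(self, tetrahedron):
        hull = build_hull(tetrahedron)
        assert len(hull.vertices) == 4
        assert hull.n_faces == 4

    def test_cube_face_count_follows_euler_relation(self, unit_cube):
        # triangulated convex polytope: F = 2V - 4
        hull = build_hull(unit_cube)
        assert len(hull.vertices) == 8
        assert hull.n_faces == 2 * 8 - 4

    def test_sphere_points_all_in_convex_position(self, sphere_cloud):
        hull = build_hull(sphere_cloud)
        assert len(hull.vertices) == 100
        assert hull.n_faces == 2 * 100 - 4

    def test_all_points_inside_or_on_hull(self, blastocyst_shape):
        from scipy.spatial import Delaunay
        hull = build_hull(blastocyst_shape.points)
        tri = Delaunay(blastocyst_shape.points.coords)
        assert np.all(tri.find_simplex(blastocyst_shape.points.coords) >= 0)
        assert hull.n_faces == 2 * len(hull.vertices) - 4

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientPointsError, match="insufficient"):
            build_hull(np.eye(3))

    def test_coplanar_points_rejected(self):
        flat = np.column_stack([np.random.default_rng(0).random((10, 2)), np.zeros(10)])
        with pytest.raises(DegenerateGeometryError, match="degenerate"):
            build_hull(flat)


class TestPointCloud:
    def test_nonfinite_coordinates_rejected(self):
        bad = np.array([[0.0, 0, 0], [1, np.nan, 0], [0, 1, 0]])
        with pytest.raises(ValueError, match="row 1"):
            PointCloud(bad)

    def test_shape_checked(self):
        with pytest.raises(ValueError):
            PointCloud(np.zeros((3, 2)))


# ---------------------------------------------------------------------------
# point-triangle distance
# ---------------------------------------------------------------------------

class TestPointTriangleDistance:
    @pytest.mark.parametrize("p, expected", [
        ((0, 0, 1), 1.0),                      # perpendicular drop onto interior
        ((1, 0, 0), 0.0),                      # p is a vertex
        ((2, 2, 0), np.sqrt(4.5)),             # closest point is (0.5, 0.5, 0)
        ((0.25, 0.25, 0), 0.0),                # p in triangle interior
        ((-1, -1, 0), np.sqrt(2)),             # closest point is vertex (0,0,0)
    ])
    def test_known_distances(self, p, expected):
        assert point_triangle_distance(p, TRI) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_triangle_rejected(self):
        collinear = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError, match="degenerate face"):
            point_triangle_distance((0, 1, 0), collinear)

    def test_against_dense_barycentric_oracle(self):
        """Min distance over a dense sampling of the triangle bounds the
        exact distance from above and converges to it."""
        rng = np.random.default_rng(21)
        u = np.linspace(0, 1, 250)
        uu, vv = np.meshgrid(u, u)
        keep = uu + vv <= 1
        w = np.stack([1 - uu[keep] - vv[keep], uu[keep], vv[keep]], axis=1)
        for _ in range(20):
            tri = rng.standard_normal((3, 3))
            p = rng.standard_normal(3) * 2
            exact = point_triangle_distance(p, tri)
            sampled = np.linalg.norm(w @ tri - p, axis=1).min()
            assert exact <= sampled + 1e-12
            assert sampled == pytest.approx(exact, abs=2e-2)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_under_vertex_permutation_and_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        tri = rng.standard_normal((3, 3))
        p = rng.standard_normal(3)
        d0 = point_triangle_distance(p, tri)
        for perm in ((1, 2, 0), (2, 1, 0)):
            assert point_triangle_distance(p, tri[list(perm)]) == pytest.approx(d0, abs=1e-12)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        t = rng.standard_normal(3)
        assert point_triangle_distance(p @ q.T + t, tri @ q.T + t) == pytest.approx(
            d0, abs=1e-9)
        assert d0 >= 0.0

    def test_matches_trimesh_closest_point(self):
        """Cross-check the vectorized distances against an independent mesh
        library on random triangles and query points."""
        import trimesh.triangles as tt
        rng = np.random.default_rng(5)
        tris = rng.standard_normal((40, 3, 3))
        pts = rng.standard_normal((25, 3)) * 2
        ours = points_triangles_distance(pts, tris)
        for j, tri in enumerate(tris):
            closest = tt.closest_point(np.repeat(tri[None], len(pts), axis=0), pts)
            ref = np.linalg.norm(pts - closest, axis=1)
            np.testing.assert_allclose(ours[:, j], ref, rtol=1e-9, atol=1e-9)


# ---------------------------------------------------------------------------
# face-distance profiles
# ---------------------------------------------------------------------------

class TestFaceDistanceProfile:
    def test_tetrahedron_centroid_equidistant_from_faces(self, tetrahedron):
        hull = build_hull(tetrahedron)
        prof = face_distance_profile(tetrahedron.coords.mean(axis=0), hull)
        assert prof.v == pytest.approx(0.0, abs=1e-24)
        assert np.ptp(prof.face_distances) == pytest.approx(0.0, abs=1e-12)

    def test_hull_vertex_lies_on_boundary(self, sphere_cloud):
        hull = build_hull(sphere_cloud)
        prof = face_distance_profile(sphere_cloud.coords[0], hull)
        assert prof.m == pytest.approx(0.0, abs=1e-12)
        assert prof.on_boundary(scale=sphere_cloud.diameter)

    def test_cube_centre_equidistant_from_all_triangles(self, unit_cube):
        # each square face's centre lies on the shared edge of its two triangles
        hull = build_hull(unit_cube)
        prof = face_distance_profile([0.5, 0.5, 0.5], hull)
        np.testing.assert_allclose(prof.face_distances, 0.5, atol=1e-12)
        assert prof.m == pytest.approx(0.5)
        assert prof.v == pytest.approx(0.0, abs=1e-24)

    def test_profile_invariant_under_rigid_motion(self, blastocyst_shape,
                                                  random_rigid_motion):
        R, t = random_rigid_motion
        cloud = blastocyst_shape.points
        moved = cloud.transformed(rotation=R, translation=t)
        m0, v0 = cloud_distance_profiles(cloud, build_hull(cloud))
        m1, v1 = cloud_distance_profiles(moved, build_hull(moved))
        np.testing.assert_allclose(m1, m0, atol=1e-9)
        np.testing.assert_allclose(v1, v0, atol=1e-9)

    def test_profile_covariant_under_uniform_scaling(self, blastocyst_shape):
        s = 3.7
        cloud = blastocyst_shape.points
        scaled = cloud.transformed(scale=s)
        m0, v0 = cloud_distance_profiles(cloud, build_hull(cloud))
        m1, v1 = cloud_distance_profiles(scaled, build_hull(scaled))
        np.testing.assert_allclose(m1, s * m0, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(v1, s**2 * v0, rtol=1e-9, atol=1e-12)


# ---------------------------------------------------------------------------
# analytic sphere reference
# ---------------------------------------------------------------------------

def variance_by_quadrature(x, r):
    """Independent oracle: E[d^2] - E[d]^2 with d(phi) from the law of
    cosines, integrated against the uniform surface measure sin(phi)/2."""
    d = lambda phi: np.sqrt(r**2 + x**2 - 2 * r * x * np.cos(phi))
    e1, _ = quad(lambda phi: d(phi) * np.sin(phi) / 2, 0, np.pi)
    e2, _ = quad(lambda phi: d(phi)**2 * np.sin(phi) / 2, 0, np.pi)
    return e2 - e1**2


class TestSphereFormulas:
    @pytest.mark.parametrize("x, r, expected", [(0, 1, 1), (1, 1, 0), (0.3, 2, 1.7)])
    def test_min_distance(self, x, r, expected):
        assert sphere_min_distance(x, r) == pytest.approx(expected)

    @pytest.mark.parametrize("x, r", [(0, 1), (0.25, 1), (0.5, 1), (1, 1),
                                      (0.3, 2), (1.9, 2)])
    def test_variance_matches_quadrature_oracle(self, x, r):
        assert sphere_variance(x, r) == pytest.approx(variance_by_quadrature(x, r),
                                                      abs=1e-6)

    def test_variance_landmark_values(self):
        assert sphere_variance(0, 1) == 0.0
        assert sphere_variance(1, 1) == pytest.approx(2 / 9)
        assert sphere_variance(0.5, 1) == pytest.approx(0.0764, abs=5e-5)

    def test_variance_monotone_decreasing_in_min_distance(self):
        m = np.linspace(0, 2, 400)
        v = sphere_variance_vs_min_distance(m, r=2.0)
        assert v[0] == pytest.approx(2 * 4 / 9)
        assert v[-1] == 0.0
        assert np.all(np.diff(v) <= 1e-15)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sphere_variance(1.5, 1)
        with pytest.raises(ValueError):
            sphere_min_distance(-0.1, 1)
        with pytest.raises(ValueError):
            sphere_variance_vs_min_distance([1.01], r=1)


class TestDiscreteContinuousConvergence:
    def test_discrete_profile_converges_to_analytic_curve(self):
        """(m, v) against the hull of n equidistant sphere points approaches
        the analytic sphere curve as n grows."""
        probes = radial_probe_points(50)
        devs = {}
        for n in (100, 400):
            hull = build_hull(equidistant_sphere_points(n))
            m, v = cloud_distance_profiles(probes, hull)
            x = np.linalg.norm(probes.coords, axis=1)
            devs[n] = max(np.abs(m - (1 - x)).max(), np.abs(v - sphere_variance(x, 1)).max())
        assert devs[100] < 0.05
        assert devs[400] < devs[100]
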