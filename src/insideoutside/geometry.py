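"""Computational-geometry core: convex hulls, point-to-triangle distances,
per-point face-distance profiles, and analytic sphere reference formulas.

The central quantities are, for a query point ``P`` and the triangulated
convex hull ``H`` of a point cloud, the distances from ``P`` to every
triangular face of ``H``.  Their minimum ``m`` and their variance ``v`` form
the decision space of the inside/outside classifier: interior points have
large ``m`` and small ``v``, points on the hull boundary have ``m = 0`` and
the largest spread of face distances.

For the ideal continuous case — a point at radius ``x`` inside a sphere of
radius ``r`` — both quantities have closed forms (:func:`sphere_min_distance`,
:func:`sphere_variance`) against which the discrete face-distance profiles
converge as the surface discretization is refined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "PointCloud",
    "TriangulatedHull",
    "DistanceProfile",
    "build_hull",
    "point_triangle_distance",
    "points_triangles_distance",
    "face_distance_profile",
    "sphere_min_distance",
    "sphere_variance",
    "sphere_variance_vs_min_distance",
]

#: A point counts as lying "on" the hull boundary if its minimum face
#: distance is below this fraction of the cloud diameter.
ON_HULL_RTOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Input cloud is degenerate (coplanar/collinear) — no 3D hull exists."""


class InsufficientPointsError(ValueError):
    """Too few points for the requested operation."""


@dataclass(frozen=True)
class PointCloud:
    """An ordered set of n points in 3D Cartesian space.

    Parameters
    ----------
    coords
        (n, 3) array of finite coordinates, arbitrary length units.
    ids
        Optional per-point labels, length n.
    """

    coords: np.ndarray
    ids: tuple | None = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {coords.shape}")
        if coords.shape[0] < 1:
            raise InsufficientPointsError("point cloud must contain at least one point")
        if not np.all(np.isfinite(coords)):
            bad = np.flatnonzero(~np.all(np.isfinite(coords), axis=1))[0]
            raise ValueError(f"non-finite coordinate at row {bad}")
        object.__setattr__(self, "coords", coords)
        if self.ids is not None:
            ids = tuple(self.ids)
            if len(ids) != len(coords):
                raise ValueError("ids length must match number of points")
            object.__setattr__(self, "ids", ids)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def diameter(self) -> float:
        """Diameter of the axis-aligned bounding box (cheap upper-bound scale)."""
        span = self.coords.max(axis=0) - self.coords.min(axis=0)
        return float(np.linalg.norm(span))

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    scale: float = 1.0) -> "PointCloud":
        """Return a rigidly moved and/or uniformly scaled copy."""
        out = self.coords * scale
        if rotation is not None:
            out = out @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            out = out + np.asarray(translation, dtype=float)
        return PointCloud(out, ids=self.ids)


@dataclass(frozen=True)
class TriangulatedHull:
    """Convex hull of a point cloud, triangulated into faces.

    ``vertices`` are indices into ``source.coords`` of the points that lie on
    the hull; ``faces`` is an (F, 3) array of vertex-index triples.  For a
    triangulated convex polytope with V vertices Euler's relation gives
    F = 2V − 4, which holds by construction.
    """

    vertices: np.ndarray
    faces: np.ndarray
    source: PointCloud

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def face_triangles(self) -> np.ndarray:
        """(F, 3, 3) array of the face corner coordinates."""
        return self.source.coords[self.faces]


@dataclass(frozen=True)
class DistanceProfile:
    """Distances from one query point to every face of a hull."""

    face_distances: np.ndarray
    m: float = field(init=False)
    v: float = field(init=False)

    def __post_init__(self):
        d = np.asarray(self.face_distances, dtype=float)
        object.__setattr__(self, "face_distances", d)
        object.__setattr__(self, "m", float(d.min()))
        # population variance: the profile is a descriptive feature of the
        # fixed face set, not a sample estimate
        object.__setattr__(self, "v", float(d.var()))

    def on_boundary(self, scale: float) -> bool:
        """True if the point lies on the hull boundary at the given scale."""
        return self.m <= ON_HULL_RTOL * scale


def build_hull(points: PointCloud | np.ndarray) -> TriangulatedHull:
    """Triangulated convex hull via the hull of the Delaunay triangulation.

    The hull is taken from the Delaunay triangulation of the cloud rather
    than from a direct hull algorithm; the two give identical face sets for
    points in general position.

    Raises
    ------
    InsufficientPointsError
        Fewer than 4 points.
    DegenerateGeometryError
        All points coplanar or collinear.
    """
    if not isinstance(points, PointCloud):
        points = PointCloud(points)
    if len(points) < 4:
        raise InsufficientPointsError(
            f"insufficient points: hull needs >= 4 non-coplanar points, got {len(points)}"
        )
    try:
        tri = Delaunay(points.coords)
    except Exception as exc:  # qhull raises QhullError on flat input
        raise DegenerateGeometryError(f"degenerate geometry: {exc}") from exc
    if tri.simplices.shape[0] == 0:
        raise DegenerateGeometryError("degenerate geometry: coplanar input")
    faces = tri.convex_hull
    vertices = np.unique(faces)
    return TriangulatedHull(vertices=vertices, faces=faces, source=points)


def point_triangle_distance(p: Sequence[float], tri: np.ndarray) -> float:
    """Euclidean distance from point ``p`` to the closed triangle ``tri``.

    ``tri`` is a (3, 3) array of corner coordinates.  The closest point may
    fall in the triangle interior, on an edge, or at a vertex; all regions
    are handled exactly.
    """
    tri = np.asarray(tri, dtype=float)
    e1 = tri[1] - tri[0]
    e2 = tri[2] - tri[0]
    if np.linalg.norm(np.cross(e1, e2)) == 0.0:
        raise ValueError("degenerate face: triangle has zero area")
    d = points_triangles_distance(np.asarray(p, dtype=float)[None, :], tri[None, :, :])
    return float(d[0, 0])


def points_triangles_distance(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Distances from n points to f triangles, vectorized: returns (n, f).

    The closest point on each triangle is found by orthogonal projection
    onto the triangle's plane; when the projection's barycentric coordinates
    fall outside the triangle, the minimum over the three edge segments is
    used instead (the closest point then lies on the silhouette edge or a
    vertex, which segment distances cover).
    """
    p = np.asarray(points, dtype=float)          # (n, 3)
    t = np.asarray(triangles, dtype=float)       # (f, 3, 3)
    a, b, c = t[:, 0], t[:, 1], t[:, 2]          # (f, 3)

    # plane projection via barycentric coordinates
    ab = b - a
    ac = c - a
    d00 = np.einsum("fi,fi->f", ab, ab)
    d01 = np.einsum("fi,fi->f", ab, ac)
    d11 = np.einsum("fi,fi->f", ac, ac)
    denom = d00 * d11 - d01 * d01                # (f,)

    ap = p[:, None, :] - a[None, :, :]           # (n, f, 3)
    d20 = np.einsum("nfi,fi->nf", ap, ab)
    d21 = np.einsum("nfi,fi->nf", ap, ac)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    inside = (v >= 0.0) & (w >= 0.0) & (v + w <= 1.0)

    foot = a[None, :, :] + v[..., None] * ab[None, :, :] + w[..., None] * ac[None, :, :]
    d_plane = np.linalg.norm(p[:, None, :] - foot, axis=-1)

    d_edges = np.minimum(
        _points_segments_distance(p, a, b),
        np.minimum(_points_segments_distance(p, b, c),
                   _points_segments_distance(p, a, c)),
    )
    return np.where(inside, d_plane, d_edges)


def _points_segments_distance(p: np.ndarray, s0: np.ndarray, s1: np.ndarray) -> np.ndarray:
    """Distance from n points to f segments (s0[i] -> s1[i]); returns (n, f)."""
    d = s1 - s0                                  # (f, 3)
    len2 = np.einsum("fi,fi->f", d, d)
    sp = p[:, None, :] - s0[None, :, :]          # (n, f, 3)
    t = np.einsum("nfi,fi->nf", sp, d) / np.where(len2 > 0, len2, 1.0)
    t = np.clip(t, 0.0, 1.0)
    closest = s0[None, :, :] + t[..., None] * d[None, :, :]
    return np.linalg.norm(p[:, None, :] - closest, axis=-1)


def face_distance_profile(p: Sequence[float], hull: TriangulatedHull) -> DistanceProfile:
    """Distance profile of one query point against every face of ``hull``."""
    d = points_triangles_distance(np.asarray(p, dtype=float)[None, :],
                                  hull.face_triangles())
    return DistanceProfile(face_distances=d[0])


def cloud_distance_profiles(points: PointCloud, hull: TriangulatedHull) -> tuple[np.ndarray, np.ndarray]:
    """Per-point (m, v) of face distances for a whole cloud; returns two (n,) arrays."""
    d = points_triangles_distance(points.coords, hull.face_triangles())
    return d.min(axis=1), d.var(axis=1)


# ---------------------------------------------------------------------------
# Analytic sphere reference
# ---------------------------------------------------------------------------

def _check_sphere_args(x, r):
    x = np.asarray(x, dtype=float)
    if r <= 0:
        raise ValueError("sphere radius must be positive")
    if np.any(x < 0) or np.any(x > r):
        raise ValueError("point not on/inside sphere: require 0 <= x <= r")
    return x


def sphere_min_distance(x: float, r: float) -> float:
    """Minimum distance from a point at radius ``x`` inside a sphere of
    radius ``r`` to the sphere surface: ``m = r - x``."""
    x = _check_sphere_args(x, r)
    return r - x if x.ndim else float(r - x)


def sphere_variance(x, r: float):
    """Variance of distances from a point at radius ``x`` to the uniform
    measure on the sphere of radius ``r``.

    With the point on the z-axis and a surface point at polar angle φ, the
    law of cosines gives d(φ) = sqrt(r² + x² − 2 r x cos φ); under the
    uniform surface measure cos φ is uniform on [−1, 1], whence
    E[d] = r + x²/(3r), E[d²] = r² + x², and

        v(x) = x² (3 r² − x²) / (9 r²).

    This vanishes at the centre (all distances equal r) and is maximal,
    2r²/9, for a point on the surface.
    """
    x = _check_sphere_args(x, r)
    v = x**2 * (3.0 * r**2 - x**2) / (9.0 * r**2)
    return v if v.ndim else float(v)


def sphere_variance_vs_min_distance(m_values, r: float):
    """Sphere distance-variance expressed as a function of the minimum
    distance ``m = r − x``; strictly non-increasing on m ∈ [0, r]."""
    m = np.asarray(m_values, dtype=float)
    if np.any(m < 0) or np.any(m > r):
        raise ValueError("minimum distance must lie in [0, r]")
    return sphere_variance(r - m, r)
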