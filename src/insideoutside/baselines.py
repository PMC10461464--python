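"""Competitor classifiers: Naive Ellipsoidal, RANSAC Ellipsoidal, Convex Hull.

The ellipsoidal methods fit an ellipsoid to the centroid cloud — either a
single least-squares fit (naive) or a RANSAC consensus fit — and call a
point exterior when its distance from the ellipsoid centre exceeds 0.95
times the distance from the centre to the nearest point of the ellipsoid
surface.  The convex-hull method simply labels every vertex of the cloud's
convex hull as outside.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import ConvexHull

from .classifier import ClassificationResult
from .geometry import DegenerateGeometryError, InsufficientPointsError, PointCloud

__all__ = [
    "Ellipsoid",
    "RansacConfig",
    "fit_ellipsoid_naive",
    "fit_ellipsoid_ransac",
    "classify_ellipsoid",
    "classify_convex_hull",
]


class EllipsoidFitError(RuntimeError):
    """The fitted quadric is not an ellipsoid, or fitting failed."""


@dataclass(frozen=True)
class Ellipsoid:
    """An ellipsoid as centre + orthonormal axes + semi-axis lengths."""

    centre: np.ndarray
    orientation: np.ndarray  # rows are unit axis directions
    radii: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "centre", np.asarray(self.centre, dtype=float))
        object.__setattr__(self, "orientation", np.asarray(self.orientation, dtype=float))
        object.__setattr__(self, "radii", np.asarray(self.radii, dtype=float))
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")

    def to_body_frame(self, points: np.ndarray) -> np.ndarray:
        """Map world coordinates into the ellipsoid's principal-axis frame."""
        return (np.asarray(points, dtype=float) - self.centre) @ self.orientation.T


@dataclass(frozen=True)
class RansacConfig:
    """RANSAC settings: minimal-sample refits with inlier counting by
    algebraic distance.  ``inlier_tolerance`` is in units of the normalized
    algebraic residual |Q(p)| of the fitted quadric; if None it is set to
    0.05 x the cloud diameter at fit time."""

    n_iterations: int = 500
    sample_size: int = 9
    inlier_tolerance: float | None = None
    rng_seed: int | None = 0

    def __post_init__(self):
        if self.sample_size < 9:
            raise ValueError("sample_size must be >= 9 (a quadric has 9 dof)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def _fit_quadric(coords: np.ndarray) -> np.ndarray:
    """Least-squares coefficients (a,b,c,d,e,f,g,h,i) of the quadric
    a x² + b y² + c z² + d xy + e xz + f yz + g x + h y + i z = 1."""
    x, y, z = coords.T
    D = np.column_stack([x * x, y * y, z * z, x * y, x * z, y * z, x, y, z])
    coef, *_ = np.linalg.lstsq(D, np.ones(len(coords)), rcond=None)
    return coef


def _quadric_to_ellipsoid(coef: np.ndarray) -> Ellipsoid:
    a, b, c, d, e, f, g, h, i = coef
    A = np.array([[a, d / 2, e / 2],
                  [d / 2, b, f / 2],
                  [e / 2, f / 2, c]])
    if abs(np.linalg.det(A)) < 1e-300:
        raise EllipsoidFitError("fit is not an ellipsoid: singular quadratic form")
    centre = np.linalg.solve(A, -0.5 * np.array([g, h, i]))
    # centred form: (p-c)ᵀA(p-c) = 1 + cᵀAc; an ellipsoid needs A/k positive
    # definite (the =1 normalization can make both A and k negative)
    k = 1.0 + centre @ A @ centre
    if k == 0:
        raise EllipsoidFitError("fit is not an ellipsoid: degenerate centred form")
    evals, evecs = np.linalg.eigh(A / k)
    if np.any(evals <= 0):
        raise EllipsoidFitError("fit is not an ellipsoid: quadratic form not positive definite")
    radii = 1.0 / np.sqrt(evals)
    orientation = evecs.T
    if np.linalg.det(orientation) < 0:
        orientation = orientation * np.array([[1.0], [1.0], [-1.0]])
    return Ellipsoid(centre=centre, orientation=orientation, radii=radii)


def _algebraic_residuals(coef: np.ndarray, coords: np.ndarray) -> np.ndarray:
    x, y, z = coords.T
    D = np.column_stack([x * x, y * y, z * z, x * y, x * z, y * z, x, y, z])
    return np.abs(D @ coef - 1.0)


def fit_ellipsoid_naive(points: PointCloud | np.ndarray) -> Ellipsoid:
    """Single least-squares algebraic fit of an ellipsoid to the cloud.

    Fits a general quadric (9 degrees of freedom) by linear least squares
    and decomposes it into centre, orientation, and semi-axes; a fit whose
    quadratic form is not positive definite is rejected.
    """
    if not isinstance(points, PointCloud):
        points = PointCloud(points)
    if len(points) < 9:
        raise InsufficientPointsError(
            f"underdetermined: ellipsoid fit needs >= 9 points, got {len(points)}"
        )
    return _quadric_to_ellipsoid(_fit_quadric(points.coords))


def fit_ellipsoid_ransac(points: PointCloud | np.ndarray,
                         config: RansacConfig = RansacConfig()) -> Ellipsoid:
    """Consensus ellipsoid fit by random sample consensus.

    Each iteration fits a quadric to a random minimal sample and counts
    points with algebraic residual below the tolerance as inliers; the
    final ellipsoid is refit on the largest consensus set.
    """
    if not isinstance(points, PointCloud):
        points = PointCloud(points)
    coords = points.coords
    if len(points) < config.sample_size:
        raise InsufficientPointsError(
            f"need >= {config.sample_size} points for RANSAC, got {len(points)}"
        )
    tol = config.inlier_tolerance
    if tol is None:
        tol = 0.05 * points.diameter
    rng = np.random.default_rng(config.rng_seed)
    best_inliers: np.ndarray | None = None
    for _ in range(config.n_iterations):
        idx = rng.choice(len(points), size=config.sample_size, replace=False)
        coef = _fit_quadric(coords[idx])
        try:
            _quadric_to_ellipsoid(coef)
        except EllipsoidFitError:
            continue
        inliers = _algebraic_residuals(coef, coords) <= tol
        if best_inliers is None or inliers.sum() > best_inliers.sum():
            best_inliers = inliers
    if best_inliers is None or best_inliers.sum() < 9:
        raise EllipsoidFitError("RANSAC failed: no iteration produced an ellipsoidal fit")
    return _quadric_to_ellipsoid(_fit_quadric(coords[best_inliers]))


def _closest_surface_distance(e: Ellipsoid, points: np.ndarray) -> np.ndarray:
    """Distance from the ellipsoid centre to the surface point closest to
    each query point (NOT the distance from the query point itself).

    The closest surface point q of a point p (body frame) satisfies
    q_i = a_i² p_i / (a_i² + t) with Σ q_i²/a_i² = 1; the scalar t is found
    by bracketed root-finding on that constraint (t > -min(a_i²) for points
    outside the degenerate core).  Non-convergence falls back to radial
    projection with a warning.
    """
    body = e.to_body_frame(points)
    a2 = e.radii**2
    out = np.empty(len(body))
    for j, p in enumerate(body):
        if np.allclose(p, 0.0):
            out[j] = e.radii.min()
            continue
        def f(t):
            return np.sum(a2 * p**2 / (a2 + t) ** 2) - 1.0
        lo = -a2.min() + 1e-12 * a2.max()
        # f is decreasing in t; bracket the root by expanding upward
        hi = max(np.linalg.norm(p) * e.radii.max(), a2.max())
        tries = 0
        while f(hi) > 0 and tries < 60:
            hi *= 2.0
            tries += 1
        try:
            t = brentq(f, lo, hi, xtol=1e-10, maxiter=100)
            q = a2 * p / (a2 + t)
        except (ValueError, RuntimeError):
            warnings.warn("closest-point root-finding failed; using radial projection")
            q = p / np.sqrt(np.sum(p**2 / a2))
        out[j] = np.linalg.norm(q)
    return out


def classify_ellipsoid(points: PointCloud | np.ndarray, e: Ellipsoid,
                       threshold: float = 0.95) -> ClassificationResult:
    """Label points outside when further than ``threshold`` x the centre-to-
    surface distance along the nearest-surface-point direction.

    A point is outside iff |centre→point| > threshold * |centre→closest
    surface point|; equality counts as inside.
    """
    if not isinstance(points, PointCloud):
        points = PointCloud(points)
    centre_dist = np.linalg.norm(points.coords - e.centre, axis=1)
    surf_dist = _closest_surface_distance(e, points.coords)
    # small relative tolerance so a point exactly at the threshold stays
    # inside despite root-finding round-off
    labels = (centre_dist > threshold * surf_dist * (1 + 1e-9)).astype(int)
    return ClassificationResult(labels=labels, features=None, method="ellipsoid")


def classify_convex_hull(points: PointCloud | np.ndarray) -> ClassificationResult:
    """Label exactly the vertices of the cloud's convex hull as outside."""
    if not isinstance(points, PointCloud):
        points = PointCloud(points)
    if len(points) < 5:
        raise InsufficientPointsError("need at least 5 points")
    try:
        hull = ConvexHull(points.coords)
    except Exception as exc:
        raise DegenerateGeometryError(f"degenerate geometry: {exc}") from exc
    labels = np.zeros(len(points), dtype=int)
    labels[hull.vertices] = 1
    return ClassificationResult(labels=labels, features=None, method="convexhull")
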