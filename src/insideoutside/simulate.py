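"""Synthetic embryo-like test shapes and sphere-discretization utilities.

The benchmark shape mimics a late blastocyst, whose 100–150 cells are
roughly 60–70% trophectoderm (the outside layer): by default 100 uniform
random points on the unit sphere (outside) plus 50 uniform random points in
a concentric ball (inside).  The inner-ball radius controls how close the
interior population comes to the surface; a scalar noise factor adds
isotropic Gaussian jitter to the surface points to emulate local surface
concavities from biology or segmentation error.

Ground-truth labels are fixed at construction — a noisy surface point stays
"outside" no matter where the jitter puts it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import PointCloud

__all__ = [
    "ShapeSpec",
    "LabelledShape",
    "sample_sphere_uniform",
    "sample_ball_uniform",
    "equidistant_sphere_points",
    "test_points_along_radius",
    "make_test_shape",
    "add_surface_noise",
]


@dataclass(frozen=True)
class ShapeSpec:
    """Parameters of one synthetic test shape.

    ``noise_factor`` is the per-coordinate standard deviation of the
    Gaussian perturbation applied to the outside (surface) points, in the
    same length units as the radii.  ``radial_noise`` switches to a purely
    radial perturbation of the same s.d. instead of the default isotropic one.
    """

    n_outside: int = 100
    n_inside: int = 50
    inner_radius: float = 0.5
    outer_radius: float = 1.0
    noise_factor: float = 0.0
    radial_noise: bool = False
    rng_seed: int | None = None

    def __post_init__(self):
        if self.n_outside < 0 or self.n_inside < 0:
            raise ValueError("point counts must be non-negative")
        if not (0.0 < self.inner_radius <= self.outer_radius):
            raise ValueError("require 0 < inner_radius <= outer_radius")
        if self.noise_factor < 0:
            raise ValueError("noise_factor must be non-negative")


@dataclass(frozen=True)
class LabelledShape:
    """A simulated shape with construction ground truth (0 inside, 1 outside)."""

    points: PointCloud
    truth: np.ndarray
    spec: ShapeSpec | None = None

    def __post_init__(self):
        truth = np.asarray(self.truth, dtype=int)
        if len(truth) != len(self.points):
            raise ValueError("truth length must match point count")
        object.__setattr__(self, "truth", truth)

    def __len__(self) -> int:
        return len(self.points)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_sphere_uniform(n: int, r: float = 1.0, seed=None) -> PointCloud:
    """n i.i.d. uniform points on the radius-r sphere (normalized isotropic
    Gaussian method)."""
    if r <= 0:
        raise ValueError("radius must be positive")
    if n == 0:
        return _empty_cloud()
    g = _rng(seed).standard_normal((n, 3))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    return PointCloud(r * g)


def sample_ball_uniform(n: int, r: float = 1.0, seed=None) -> PointCloud:
    """n i.i.d. uniform points in the closed radius-r ball (radius ∝ U^{1/3})."""
    if r <= 0:
        raise ValueError("radius must be positive")
    if n == 0:
        return _empty_cloud()
    rng = _rng(seed)
    g = rng.standard_normal((n, 3))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    radii = r * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return PointCloud(radii * g)


def _empty_cloud() -> PointCloud:
    cloud = object.__new__(PointCloud)
    object.__setattr__(cloud, "coords", np.empty((0, 3)))
    object.__setattr__(cloud, "ids", None)
    return cloud


def equidistant_sphere_points(n: int, r: float = 1.0) -> PointCloud:
    """Deterministic, approximately equal-area points on the radius-r sphere.

    Uses an offset Fibonacci (generalized-spiral) lattice: latitudes are
    chosen so each point owns an equal band of area, longitudes advance by
    the golden angle.  ``n = 2`` returns the two poles.
    """
    if n < 2:
        raise ValueError("need at least 2 points")
    if n == 2:
        return PointCloud(np.array([[0.0, 0.0, -r], [0.0, 0.0, r]]))
    i = np.arange(n)
    # offset 0.36 improves the minimum pairwise distance over the plain lattice
    eps = 0.36
    z = 1.0 - 2.0 * (i + eps) / (n - 1.0 + 2.0 * eps)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return PointCloud(r * np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z]))


def test_points_along_radius(n: int = 50, r: float = 1.0,
                             direction=(0.0, 0.0, 1.0)) -> PointCloud:
    """n equally spaced points from the origin to the surface point
    ``r * direction`` (both endpoints included)."""
    if n < 1:
        raise ValueError("need at least 1 point")
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("direction must be a non-zero vector")
    d = d / norm
    t = np.array([0.0]) if n == 1 else np.linspace(0.0, r, n)
    return PointCloud(t[:, None] * d[None, :])


def add_surface_noise(points: PointCloud, noise_factor: float, seed=None,
                      radial: bool = False) -> PointCloud:
    """Perturb every point by i.i.d. Gaussian displacement with
    per-coordinate s.d. ``noise_factor`` (or a radial displacement of the
    same s.d. if ``radial``)."""
    if noise_factor < 0:
        raise ValueError("noise_factor must be non-negative")
    if noise_factor == 0 or len(points) == 0:
        return points
    rng = _rng(seed)
    coords = points.coords
    if radial:
        units = coords / np.linalg.norm(coords, axis=1, keepdims=True)
        out = coords + noise_factor * rng.standard_normal((len(points), 1)) * units
    else:
        out = coords + noise_factor * rng.standard_normal(coords.shape)
    return PointCloud(out, ids=points.ids)


def make_test_shape(spec: ShapeSpec) -> LabelledShape:
    """Simulate one labelled test shape per its spec.

    Outside points are drawn first, then inside points, from a single
    seeded stream; surface noise (if any) is applied to the outside points
    only, after the truth labels are fixed.
    """
    rng = _rng(spec.rng_seed)
    outside = sample_sphere_uniform(spec.n_outside, spec.outer_radius, seed=rng)
    inside = sample_ball_uniform(spec.n_inside, spec.inner_radius, seed=rng)
    if spec.noise_factor > 0:
        outside = add_surface_noise(outside, spec.noise_factor, seed=rng,
                                    radial=spec.radial_noise)
    coords = np.vstack([outside.coords, inside.coords])
    truth = np.concatenate([np.ones(spec.n_outside, dtype=int),
                            np.zeros(spec.n_inside, dtype=int)])
    return LabelledShape(points=PointCloud(coords), truth=truth, spec=spec)
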