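"""The insideOutside classifier.

For every point of a 3D cloud we compute the minimum ``m`` and variance
``v`` of its distances to all triangular faces of the cloud's own convex
hull, and split the 2D feature space ``[log10(m + eps), v]`` (default
``eps = 0.01``) into two groups by unsupervised clustering (Ward-linkage
hierarchical clustering by default).  The group sitting deeper in the hull
— larger mean transformed minimum distance — is labelled inside (0), the
other outside (1).

Coordinates are first normalized to a canonical frame (centroid at the
origin, half the cloud diameter = 1), so the features are dimensionless, the
log-offset ``eps`` is a fixed fraction of the cloud's size regardless of
units, and the labels are exactly invariant to rigid motion and uniform
scaling of the input.

The log transform matters in the hard regime where the interior points
fill the whole hull: it stretches the small-``m`` end of the axis so that
boundary and near-boundary points stay separable, which the raw minimum
distance does not (see the radius sweeps in :mod:`insideoutside.evaluate`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import DBSCAN, KMeans, SpectralClustering

from .geometry import PointCloud, build_hull, cloud_distance_profiles

__all__ = [
    "ClassifierConfig",
    "FeatureMatrix",
    "ClassificationResult",
    "compute_features",
    "cluster_features",
    "assign_inside_outside",
    "classify",
]

Transform = Literal["log10", "raw"]
Clustering = Literal["hierarchical", "kmeans", "spectral", "dbscan"]
FeatureMode = Literal["bivariate", "m-only", "v-only"]
Scaling = Literal["none", "minmax"]


class ConstantFeatureError(ValueError):
    """A feature is constant across points; min-max scaling is undefined."""


class ClusteringError(RuntimeError):
    """The clustering step failed to produce two usable groups."""


@dataclass(frozen=True)
class ClassifierConfig:
    """Configuration of the classifier.

    Defaults reproduce the published algorithm: bivariate feature space
    ``[log10(m + 0.01), v]`` in normalized-coordinate units with Ward
    hierarchical clustering.  ``scale_features="minmax"`` additionally
    min-max rescales each feature to [0, 1] before clustering (a variant
    that reweights the two axes per sample; see the methods note for why
    it is not the default).

    ``dbscan_eps`` / ``dbscan_min_samples`` only apply when
    ``clustering="dbscan"`` and are measured in feature units.  ``rng_seed``
    seeds k-means and spectral initialization.
    """

    epsilon: float = 0.01
    transform: Transform = "log10"
    clustering: Clustering = "hierarchical"
    feature_mode: FeatureMode = "bivariate"
    scale_features: Scaling = "none"
    dbscan_eps: float = 0.1
    dbscan_min_samples: int = 4
    rng_seed: int | None = 0

    def __post_init__(self):
        if not (0.0 < self.epsilon < 1.0):
            raise ValueError("epsilon must lie in (0, 1)")
        if self.transform not in ("log10", "raw"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.clustering not in ("hierarchical", "kmeans", "spectral", "dbscan"):
            raise ValueError(f"unknown clustering {self.clustering!r}")
        if self.feature_mode not in ("bivariate", "m-only", "v-only"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")
        if self.scale_features not in ("none", "minmax"):
            raise ValueError(f"unknown scale_features {self.scale_features!r}")


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-point decision-space coordinates.

    Column ``f1`` is the (optionally log-transformed) minimum face distance
    and ``f2`` the variance of face distances, both in normalized-coordinate
    units (min-max rescaled to [0, 1] when the config asked for it).
    ``matrix`` is the (n, k) array handed to the clustering step (k = 1 for
    the univariate feature modes).
    """

    f1: np.ndarray
    f2: np.ndarray
    epsilon: float
    mode: FeatureMode = "bivariate"
    matrix: np.ndarray = field(init=False)

    def __post_init__(self):
        cols = {"bivariate": (self.f1, self.f2),
                "m-only": (self.f1,),
                "v-only": (self.f2,)}[self.mode]
        object.__setattr__(self, "matrix", np.column_stack(cols))

    def __len__(self) -> int:
        return len(self.f1)


@dataclass(frozen=True)
class ClassificationResult:
    """Per-point binary labels: 0 = inside, 1 = outside."""

    labels: np.ndarray
    features: FeatureMatrix | None
    method: str

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        if not np.all(np.isin(labels, (0, 1))):
            raise ValueError("labels must be 0 (inside) or 1 (outside)")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)


def _minmax(values: np.ndarray, name: str) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        raise ConstantFeatureError(
            f"constant feature: {name} is identical for all points; scaling undefined"
        )
    return (values - lo) / (hi - lo)


def normalize_cloud(points: PointCloud) -> PointCloud:
    """Canonical frame: centroid at the origin, half-diameter 1.

    The scale is half the maximum pairwise distance, so a cloud whose
    surface points lie on a sphere of radius r is mapped (almost exactly)
    onto the unit sphere regardless of where its interior points sit.  The
    frame is invariant to rigid motion and absorbs uniform scaling.
    """
    centred = points.coords - points.coords.mean(axis=0)
    # the diameter is attained between convex-hull vertices; for small n
    # just use all points
    scale = _half_diameter(centred)
    if scale == 0:
        raise ValueError("all points coincide; cloud has no extent")
    return PointCloud(centred / scale, ids=points.ids)


def _half_diameter(coords: np.ndarray) -> float:
    from scipy.spatial.distance import pdist
    if len(coords) > 30:
        try:
            from scipy.spatial import ConvexHull
            coords = coords[ConvexHull(coords).vertices]
        except Exception:
            pass
    return float(pdist(coords).max()) / 2.0


def compute_features(points: PointCloud | np.ndarray,
                     config: ClassifierConfig = ClassifierConfig()) -> FeatureMatrix:
    """Build the per-point decision-space features against the cloud's own hull.

    Pipeline: normalize coordinates → (m, v) per point against the hull →
    ``f1 = log10(m + eps)`` (or ``m`` itself for ``transform="raw"``),
    ``f2 = v`` → optional per-feature min-max rescale.  A hull vertex has
    m = 0 and hence f1 = log10(eps) = −2 at the default eps.
    """
    if not isinstance(points, PointCloud):
        points = PointCloud(points)
    if len(points) < 5:
        raise ValueError("need at least 5 points: 4 for the hull plus one to classify")
    normed = normalize_cloud(points)
    hull = build_hull(normed)
    m, v = cloud_distance_profiles(normed, hull)
    f1 = np.log10(m + config.epsilon) if config.transform == "log10" else m
    f2 = v
    if config.scale_features == "minmax":
        f1 = _minmax(f1, "transformed minimum distance")
        f2 = _minmax(f2, "variance of face distances")
    return FeatureMatrix(f1=f1, f2=f2, epsilon=config.epsilon, mode=config.feature_mode)


def cluster_features(features: FeatureMatrix,
                     config: ClassifierConfig = ClassifierConfig()) -> np.ndarray:
    """Split the feature space into exactly two groups; returns ids in {0, 1}.

    Hierarchical clustering uses Ward linkage on Euclidean distances with
    the tree cut at two clusters.  DBSCAN is density-based and may find any
    number of clusters; runs not yielding exactly two are an error, and its
    noise points are attached to the nearest cluster centroid.
    """
    X = features.matrix
    if len(np.unique(X, axis=0)) < 2:
        raise ClusteringError("cannot split: fewer than 2 distinct feature rows")

    if config.clustering == "hierarchical":
        groups = fcluster(linkage(X, method="ward"), t=2, criterion="maxclust") - 1
    elif config.clustering == "kmeans":
        km = KMeans(n_clusters=2, n_init=10, random_state=config.rng_seed)
        groups = km.fit_predict(X)
    elif config.clustering == "spectral":
        sc = SpectralClustering(n_clusters=2, random_state=config.rng_seed,
                                assign_labels="discretize")
        groups = sc.fit_predict(X)
    else:  # dbscan
        db = DBSCAN(eps=config.dbscan_eps, min_samples=config.dbscan_min_samples)
        groups = db.fit_predict(X)
        core = groups >= 0
        n_clusters = len(np.unique(groups[core]))
        if n_clusters != 2:
            raise ClusteringError(
                f"clustering failed, adjust parameters: DBSCAN found {n_clusters} clusters"
            )
        if np.any(~core):
            centroids = np.stack([X[groups == g].mean(axis=0) for g in (0, 1)])
            d = np.linalg.norm(X[~core][:, None, :] - centroids[None], axis=-1)
            groups[~core] = d.argmin(axis=1)

    if len(np.unique(groups)) != 2:
        raise ClusteringError("clustering failed: did not produce two groups")
    return np.asarray(groups, dtype=int)


def assign_inside_outside(groups: np.ndarray, features: FeatureMatrix,
                          method: str = "insideoutside") -> ClassificationResult:
    """Label the two groups: deeper group (larger mean f1) = inside (0).

    The assignment depends only on the features, so the arbitrary numbering
    of cluster ids never affects the labels.  An exact tie in group means is
    broken by putting the group containing the globally deepest point (max
    f1) inside.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(uniq)}")
    mean_f1 = [features.f1[groups == g].mean() for g in uniq]
    if mean_f1[0] != mean_f1[1]:
        inside_group = uniq[int(np.argmax(mean_f1))]
    else:
        inside_group = groups[int(np.argmax(features.f1))]
    labels = np.where(groups == inside_group, 0, 1)
    return ClassificationResult(labels=labels, features=features, method=method)


def classify(points: PointCloud | np.ndarray,
             config: ClassifierConfig = ClassifierConfig()) -> ClassificationResult:
    """Full insideOutside pipeline: features → 2-group clustering → labels."""
    features = compute_features(points, config)
    groups = cluster_features(features, config)
    method = f"insideoutside[{config.transform},{config.clustering},{config.feature_mode}]"
    return assign_inside_outside(groups, features, method=method)
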