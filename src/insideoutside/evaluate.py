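"""Accuracy designations and rates, benchmark parameter sweeps, leave-K-out
subsampling, and a 1D Gaussian-mixture thresholding utility for deriving
ground truth from a marker signal.

Every point of a classified, ground-truthed cloud receives one of four
designations — true inside, misclassified inside, true outside,
misclassified outside — from which the class-conditional correct-
classification rates (True Inside rate, True Outside rate) are computed.
The sweep routines repeat simulate-and-classify over grids of inner-ball
radius, log-offset epsilon, and surface-noise factor, reporting mean ± s.d.
rates per grid cell as tidy tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .baselines import (RansacConfig, classify_convex_hull, classify_ellipsoid,
                        fit_ellipsoid_naive, fit_ellipsoid_ransac)
from .classifier import ClassificationResult, ClassifierConfig, classify
from .simulate import LabelledShape, ShapeSpec, make_test_shape

__all__ = [
    "TRUE_INSIDE", "MISCLASSIFIED_INSIDE", "TRUE_OUTSIDE", "MISCLASSIFIED_OUTSIDE",
    "SweepResult",
    "designate",
    "true_inside_rate",
    "true_outside_rate",
    "classify_with_method",
    "radius_sweep",
    "epsilon_sweep",
    "noise_sweep",
    "leave_k_out_subsample",
    "benchmark_methods",
    "gmm_threshold",
]

TRUE_INSIDE = "true inside"
MISCLASSIFIED_INSIDE = "misclassified inside"
TRUE_OUTSIDE = "true outside"
MISCLASSIFIED_OUTSIDE = "misclassified outside"

METHODS = ("insideoutside", "convexhull", "ellipsoid-naive", "ellipsoid-ransac")


class RateUndefinedError(ValueError):
    """No ground-truth points of the requested class exist."""


@dataclass(frozen=True)
class SweepResult:
    """Gridded sweep output.

    ``table`` is tidy: one row per grid cell (and method, where several were
    run) with columns for each axis plus ``mean_<rate>``, ``sd_<rate>``, and
    ``n`` (replicates contributing).  ``axes`` names the grid columns.
    """

    table: pd.DataFrame
    axes: tuple[str, ...]
    n_replicates: int
    seed: int | None
    n_failures: int = 0

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def pivot(self, value: str, index: str, columns: str) -> pd.DataFrame:
        """Reshape a tidy column into a (index x columns) grid, e.g. for a heatmap."""
        return self.table.pivot_table(values=value, index=index, columns=columns)


def designate(truth, predicted) -> np.ndarray:
    """Four-way designation of each point from its (truth, predicted) pair.

    Truth and prediction are bits (0 inside, 1 outside).  "Misclassified
    inside" means a ground-truth-inside point that was classified outside,
    and symmetrically for "misclassified outside".
    """
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    lut = np.array([[TRUE_INSIDE, MISCLASSIFIED_INSIDE],
                    [MISCLASSIFIED_OUTSIDE, TRUE_OUTSIDE]], dtype=object)
    return lut[truth, predicted]


def _class_rate(designations, hit: str, miss: str, label: str) -> float:
    d = np.asarray(designations, dtype=object)
    n_hit = int(np.sum(d == hit))
    n_total = n_hit + int(np.sum(d == miss))
    if n_total == 0:
        raise RateUndefinedError(f"rate undefined: no ground-truth {label} points")
    return n_hit / n_total


def true_inside_rate(designations) -> float:
    """Fraction of ground-truth inside points classified inside."""
    return _class_rate(designations, TRUE_INSIDE, MISCLASSIFIED_INSIDE, "inside")


def true_outside_rate(designations) -> float:
    """Fraction of ground-truth outside points classified outside."""
    return _class_rate(designations, TRUE_OUTSIDE, MISCLASSIFIED_OUTSIDE, "outside")


def classify_with_method(points, method: str,
                         config: ClassifierConfig | None = None,
                         ransac_config: RansacConfig | None = None,
                         threshold: float = 0.95) -> ClassificationResult:
    """Dispatch a cloud to one of the four classifiers by name."""
    if method == "insideoutside":
        return classify(points, config or ClassifierConfig())
    if method == "convexhull":
        return classify_convex_hull(points)
    if method == "ellipsoid-naive":
        return classify_ellipsoid(points, fit_ellipsoid_naive(points), threshold)
    if method == "ellipsoid-ransac":
        e = fit_ellipsoid_ransac(points, ransac_config or RansacConfig())
        return classify_ellipsoid(points, e, threshold)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def _replicate_rates(spec: ShapeSpec, method: str, config, rep_seeds) -> tuple[list, list, int]:
    """Rates over seeded replicates of one grid cell; failed replicates are
    dropped (counted), since a classifier may legitimately error on a
    pathological draw."""
    ti, to, failures = [], [], 0
    for s in rep_seeds:
        shape = make_test_shape(ShapeSpec(**{**spec.__dict__, "rng_seed": int(s)}))
        try:
            result = classify_with_method(shape.points, method, config=config)
            d = designate(shape.truth, result.labels)
            ti.append(true_inside_rate(d))
            to.append(true_outside_rate(d))
        except Exception:
            failures += 1
    return ti, to, failures


def _summarize(rows: list[dict], axes: tuple[str, ...], n_replicates: int,
               seed, n_failures: int) -> SweepResult:
    return SweepResult(table=pd.DataFrame(rows), axes=axes,
                       n_replicates=n_replicates, seed=seed, n_failures=n_failures)


def _cell_row(ti: list, to: list) -> dict:
    row = {}
    for name, vals in (("true_inside", ti), ("true_outside", to)):
        arr = np.asarray(vals, dtype=float)
        row[f"mean_{name}"] = arr.mean() if len(arr) else np.nan
        row[f"sd_{name}"] = arr.std() if len(arr) else np.nan
    row["n"] = len(ti)
    return row


def radius_sweep(radii, n_replicates: int = 100,
                 config: ClassifierConfig = ClassifierConfig(),
                 seed: int | None = 0, method: str = "insideoutside",
                 n_outside: int = 100, n_inside: int = 50) -> SweepResult:
    """Mean ± s.d. classification rates as the inner-ball radius varies.

    Each grid cell simulates ``n_replicates`` fresh shapes (default 100
    sphere points outside + 50 ball points inside) and classifies them.
    """
    rng = np.random.default_rng(seed)
    rows, failures = [], 0
    for radius in radii:
        rep_seeds = rng.integers(2**31, size=n_replicates)
        spec = ShapeSpec(n_outside=n_outside, n_inside=n_inside, inner_radius=float(radius))
        ti, to, nf = _replicate_rates(spec, method, config, rep_seeds)
        failures += nf
        rows.append({"inner_radius": float(radius), **_cell_row(ti, to)})
    return _summarize(rows, ("inner_radius",), n_replicates, seed, failures)


def first_breakdown_radius(sweep: SweepResult, rate_threshold: float = 0.99,
                           rate: str = "mean_true_inside") -> float:
    """Smallest inner-ball radius whose mean rate falls below the threshold."""
    t = sweep.table.sort_values("inner_radius")
    below = t[t[rate] < rate_threshold]
    if below.empty:
        return float("nan")
    return float(below["inner_radius"].iloc[0])


def epsilon_sweep(radii, epsilons, n_replicates: int = 100,
                  seed: int | None = 0,
                  base_config: ClassifierConfig = ClassifierConfig()) -> SweepResult:
    """Grid of mean True Inside rates over (inner radius, log-offset epsilon).

    The tidy table carries one row per (epsilon, radius) cell; the per-
    epsilon worst case over radii is ``worst_case_by_epsilon(sweep)``.
    """
    rng = np.random.default_rng(seed)
    rows, failures = [], 0
    for eps in epsilons:
        config = ClassifierConfig(**{**base_config.__dict__, "epsilon": float(eps),
                                     "transform": "log10"})
        for radius in radii:
            rep_seeds = rng.integers(2**31, size=n_replicates)
            spec = ShapeSpec(inner_radius=float(radius))
            ti, to, nf = _replicate_rates(spec, "insideoutside", config, rep_seeds)
            failures += nf
            rows.append({"epsilon": float(eps), "inner_radius": float(radius),
                         **_cell_row(ti, to)})
    return _summarize(rows, ("epsilon", "inner_radius"), n_replicates, seed, failures)


def worst_case_by_epsilon(sweep: SweepResult) -> pd.DataFrame:
    """Per-epsilon minimum (over radii) of the mean True Inside rate, with
    the radius at which it is attained."""
    idx = sweep.table.groupby("epsilon")["mean_true_inside"].idxmin()
    out = sweep.table.loc[idx, ["epsilon", "inner_radius", "mean_true_inside"]]
    return out.rename(columns={"inner_radius": "worst_radius",
                               "mean_true_inside": "worst_rate"}).reset_index(drop=True)


def noise_sweep(radii, noise_factors, methods=("convexhull", "insideoutside"),
                n_replicates: int = 100, seed: int | None = 0,
                config: ClassifierConfig = ClassifierConfig()) -> SweepResult:
    """Rates over the (inner radius, surface-noise factor) grid per method.

    Gaussian noise on the outside points emulates local surface concavities;
    the convex-hull method degrades uniformly with noise because perturbed
    surface points fall inside the hull of their neighbours, while the
    decision-space classifier keeps outside points separable.
    """
    rng = np.random.default_rng(seed)
    rows, failures = [], 0
    for radius in radii:
        for noise in noise_factors:
            rep_seeds = rng.integers(2**31, size=n_replicates)
            spec = ShapeSpec(inner_radius=float(radius), noise_factor=float(noise))
            for method in methods:
                ti, to, nf = _replicate_rates(spec, method, config, rep_seeds)
                failures += nf
                rows.append({"inner_radius": float(radius), "noise_factor": float(noise),
                             "method": method, **_cell_row(ti, to)})
    return _summarize(rows, ("inner_radius", "noise_factor", "method"),
                      n_replicates, seed, failures)


def leave_k_out_subsample(shape: LabelledShape, k: int, n_samples: int = 100,
                          seed: int | None = 0) -> list[LabelledShape]:
    """Subsampled copies of a labelled cloud emulating segmentation error.

    ``k = 1`` enumerates all n leave-one-out subsets; ``k > 1`` draws
    ``n_samples`` random subsets of size n − k (subsets drawn with
    replacement; points within each subset without replacement).
    """
    n = len(shape)
    if not 1 <= k < n:
        raise ValueError(f"require 1 <= k < n; got k={k}, n={n}")
    coords = shape.points.coords
    if k == 1:
        keep_sets = [np.delete(np.arange(n), i) for i in range(n)]
    else:
        rng = np.random.default_rng(seed)
        keep_sets = [np.sort(rng.choice(n, size=n - k, replace=False))
                     for _ in range(n_samples)]
    from .geometry import PointCloud
    return [LabelledShape(points=PointCloud(coords[keep]), truth=shape.truth[keep],
                          spec=shape.spec) for keep in keep_sets]


def benchmark_methods(shape: LabelledShape, methods=METHODS,
                      config: ClassifierConfig = ClassifierConfig(),
                      ransac_config: RansacConfig | None = None) -> pd.DataFrame:
    """Run several classifiers on one labelled cloud; one row of rates each.

    Works on simulated shapes or any user-provided cloud with ground truth
    (e.g. marker-derived labels from :func:`gmm_threshold`).
    """
    rows = []
    for method in methods:
        row = {"method": method}
        try:
            result = classify_with_method(shape.points, method, config=config,
                                          ransac_config=ransac_config)
            d = designate(shape.truth, result.labels)
            row["true_inside_rate"] = true_inside_rate(d)
            row["true_outside_rate"] = true_outside_rate(d)
        except Exception as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def gmm_threshold(values, volumes=None, log: bool = True, seed: int | None = 0):
    """Binarize a per-point signal by a two-component 1D Gaussian mixture.

    Normalization: divide by per-point volume when given, then log10
    (skipped when ``log=False`` for signals already on a linear scale),
    then min-max rescale to [0, 1].  Each point is assigned to its higher-
    posterior component; the component with the larger mean is positive (1).
    Intended for marker-intensity ground truthing (e.g. a nuclear
    transcription factor marking the inside population).

    Returns
    -------
    labels : (n,) int array of 0/1
    mixture : dict with keys ``means``, ``sds``, ``weights`` (positive
        component last) and ``normalized`` values.
    """
    values = np.asarray(values, dtype=float)
    if volumes is not None:
        values = values / np.asarray(volumes, dtype=float)
    if log:
        if np.any(values <= 0):
            raise ValueError("values must be positive for the log10 normalization")
        x = np.log10(values)
    else:
        x = values
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("degenerate input: all normalized values identical")
    x = (x - lo) / (hi - lo)
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
    comp = gm.fit_predict(x[:, None])
    means = gm.means_.ravel()
    positive = int(np.argmax(means))
    labels = (comp == positive).astype(int)
    order = np.argsort(means)
    mixture = {
        "means": means[order],
        "sds": np.sqrt(gm.covariances_.ravel())[order],
        "weights": gm.weights_[order],
        "normalized": x,
    }
    return labels, mixture
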