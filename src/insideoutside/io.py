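"""Reading centroid tables and writing classification results.

The external format is a delimited table (CSV/TSV) of nuclear centroids as
exported by segmentation pipelines: one row per nucleus with x/y/z columns
and optional id/volume/intensity/truth columns.  Coordinates are treated as
dimensionless Cartesian values (microns by convention); none of the
classifiers depend on the absolute scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import ClassificationResult
from .evaluate import designate
from .geometry import PointCloud
from .simulate import LabelledShape

__all__ = ["ColumnMap", "read_centroids", "write_results", "write_shape"]

#: Default column names follow common segmentation-export conventions;
#: override any of them via ColumnMap.
DEFAULT_COLUMNS = {"id": "id", "x": "x", "y": "y", "z": "z",
                   "volume": "volume", "intensity": "intensity", "truth": "truth"}


class MissingColumnError(ValueError):
    pass


class DuplicateIdError(ValueError):
    pass


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from table headers to the roles the reader understands."""

    x: str = "x"
    y: str = "y"
    z: str = "z"
    id: str = "id"
    volume: str = "volume"
    intensity: str = "intensity"
    truth: str = "truth"


def _sep(path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "tsv" if str(path).endswith((".tsv", ".txt")) else "csv"
    return {"csv": ",", "tsv": "\t"}[fmt]


def read_centroids(path, fmt: str | None = None, columns: ColumnMap = ColumnMap()):
    """Read a centroid table into a :class:`PointCloud` (+ metadata).

    Returns ``(cloud, meta)`` where ``meta`` is a DataFrame of any optional
    columns present (volume, intensity, truth) in file order.  If a truth
    column is present the cloud is wrapped into a :class:`LabelledShape`.
    """
    df = pd.read_csv(path, sep=_sep(path, fmt))
    for role in ("x", "y", "z"):
        name = getattr(columns, role)
        if name not in df.columns:
            raise MissingColumnError(f"missing column {name!r} (role {role}) in {path}")
    coords = df[[columns.x, columns.y, columns.z]].apply(
        pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.all(np.isfinite(coords), axis=1)
    if bad.any():
        raise ValueError(f"non-finite coordinate at row {int(np.flatnonzero(bad)[0])}")
    ids = None
    if columns.id in df.columns:
        ids = tuple(df[columns.id])
        if len(set(ids)) != len(ids):
            raise DuplicateIdError(f"duplicate ids in {path}")
    cloud = PointCloud(coords, ids=ids)
    meta_cols = [c for c in (columns.volume, columns.intensity, columns.truth)
                 if c in df.columns]
    meta = df[meta_cols].copy() if meta_cols else None
    if meta is not None and columns.truth in meta.columns:
        return LabelledShape(points=cloud,
                             truth=meta[columns.truth].to_numpy(dtype=int)), meta
    return cloud, meta


def write_results(result: ClassificationResult, points: PointCloud, path,
                  truth=None, fmt: str | None = None) -> None:
    """Write ``id, x, y, z, label`` (+ truth and 4-way designation when
    ground truth is known) as a delimited table that round-trips through
    :func:`read_centroids`."""
    n = len(points)
    ids = points.ids if points.ids is not None else list(range(n))
    df = pd.DataFrame({"id": list(ids),
                       "x": points.coords[:, 0],
                       "y": points.coords[:, 1],
                       "z": points.coords[:, 2],
                       "label": result.labels})
    if truth is not None:
        df["truth"] = np.asarray(truth, dtype=int)
        df["designation"] = designate(truth, result.labels)
    df.to_csv(path, sep=_sep(path, fmt), index=False)


def write_shape(shape: LabelledShape, path, fmt: str | None = None) -> None:
    """Write a simulated labelled shape as an ``x,y,z,truth`` table."""
    df = pd.DataFrame({"x": shape.points.coords[:, 0],
                       "y": shape.points.coords[:, 1],
                       "z": shape.points.coords[:, 2],
                       "truth": shape.truth})
    df.to_csv(path, sep=_sep(path, fmt), index=False)
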