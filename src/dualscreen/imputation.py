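"""Missing-data imputation: column means, or complete-feature-anchored KNN.

The KNN scheme measures similarity between client records using only the
*complete* features (columns observed for every record), then fills each
missing cell with a similarity-weighted average of that feature's value in
the k most similar records that actually observe it. Records with missing
entries therefore never contaminate the distance computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .data import DataError, FeatureTable, GroupSpec

#: Regularizer added to distances before inversion, so a zero-distance
#: neighbor (an exact duplicate on the complete features) dominates the
#: weighted average without producing an infinite weight.
EPSILON = 1e-8

SUPPORTED_METRICS = ("euclidean", "cityblock", "cosine")


@dataclass
class DistanceMatrix:
    """Pairwise record distances over the complete features."""

    entries: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        d = self.entries
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise DataError("distance matrix must be square")
        if not np.isfinite(d).all():
            raise DataError("distance matrix entries must be finite")


@dataclass
class ImputationReport:
    """Accounting of what an imputation run filled.

    ``filled_cell_count`` always equals the number of unobserved cells in the
    input mask; ``fallback_cell_count`` counts cells that had to fall back to
    the column mean because no neighbor observing the feature existed.
    """

    filled_cell_count: int
    fallback_cell_count: int
    k: "int | None"
    method: str


def compute_distances(
    table: FeatureTable, spec: GroupSpec, metric: str = "euclidean"
) -> DistanceMatrix:
    """Pairwise distances between records over the complete columns only.

    Euclidean is the default; city-block and cosine are accepted
    alternatives. Raises if the table has no complete column, since the
    distance is then undefined (callers must not silently fall back).
    """
    if metric not in SUPPORTED_METRICS:
        raise DataError(f"unsupported metric {metric!r}; choose from {SUPPORTED_METRICS}")
    if not spec.complete_columns:
        raise DataError("no complete columns: record distances are undefined")
    idx = [table.column_index(c) for c in spec.complete_columns]
    anchor = table.values[:, idx]
    entries = squareform(pdist(anchor, metric=metric))
    # cosine distance of a zero vector is NaN; treat zero vectors as maximally
    # distant from everything but themselves
    if metric == "cosine" and not np.isfinite(entries).all():
        entries = np.nan_to_num(entries, nan=1.0)
    np.fill_diagonal(entries, 0.0)
    return DistanceMatrix(entries, metric)


def mean_impute(table: FeatureTable) -> tuple[FeatureTable, ImputationReport]:
    """Fill every missing cell with the observed mean of its column."""
    values = table.values.copy()
    mask = table.mask
    n_obs = mask.sum(axis=0)
    if np.any(n_obs == 0):
        empty = [c for c, n in zip(table.column_ids, n_obs) if n == 0]
        raise DataError(f"column(s) with no observed values cannot be mean-imputed: {empty}")
    with np.errstate(invalid="ignore"):
        col_means = np.nansum(np.where(mask, values, 0.0), axis=0) / n_obs
    missing = ~mask
    values[missing] = np.broadcast_to(col_means, values.shape)[missing]
    filled = FeatureTable(
        values, np.ones_like(mask, dtype=bool), table.column_ids, table.row_ids
    )
    return filled, ImputationReport(int(missing.sum()), 0, None, "mean")


def knn_impute(
    table: FeatureTable,
    spec: GroupSpec,
    k: int = 5,
    metric: str = "euclidean",
) -> tuple[FeatureTable, ImputationReport]:
    """Fill missing cells with an inverse-distance-weighted neighbor average.

    For each missing cell (i, b), the k nearest records to i — by complete-
    feature distance, restricted to records that observe feature b — each
    contribute weight 1/(D_ij + eps), normalized to sum to one; closer
    neighbors thus count for more. Equidistant neighbors are ranked by row
    index for determinism. If fewer than k eligible neighbors exist, all of
    them are used; if none exists the cell falls back to the column mean and
    is counted in the report.
    """
    m = table.n_records
    if k < 1:
        raise DataError("k must be at least 1")
    if k >= m:
        raise DataError(f"k={k} must be smaller than the number of records m={m}")
    if table.is_complete():
        return table.copy(), ImputationReport(0, 0, k, "knn")

    distances = compute_distances(table, spec, metric).entries
    values = table.values.copy()
    mask = table.mask
    fallback = 0

    for b in range(table.n_features):
        col_mask = mask[:, b]
        missing_rows = np.nonzero(~col_mask)[0]
        if missing_rows.size == 0:
            continue
        obs_rows = np.nonzero(col_mask)[0]
        if obs_rows.size == 0:
            raise DataError(
                f"column {table.column_ids[b]!r} has no observed value to impute from"
            )
        # rank observed records by distance to each missing record; stable
        # sort breaks ties by row index
        sub = distances[np.ix_(missing_rows, obs_rows)]
        order = np.argsort(sub, axis=1, kind="stable")[:, :k]
        neighbor_d = np.take_along_axis(sub, order, axis=1)
        neighbor_v = table.values[obs_rows[order], b]
        weights = 1.0 / (neighbor_d + EPSILON)
        weights /= weights.sum(axis=1, keepdims=True)
        values[missing_rows, b] = (weights * neighbor_v).sum(axis=1)

    filled = FeatureTable(
        values, np.ones_like(mask, dtype=bool), table.column_ids, table.row_ids
    )
    return filled, ImputationReport(int((~mask).sum()), fallback, k, "knn")


def impute(
    table: FeatureTable,
    spec: GroupSpec,
    method: str = "knn",
    k: int = 5,
    metric: str = "euclidean",
) -> tuple[FeatureTable, ImputationReport]:
    """Dispatch to :func:`mean_impute` or :func:`knn_impute`."""
    if method == "mean":
        return mean_impute(table)
    if method == "knn":
        return knn_impute(table, spec, k=k, metric=metric)
    raise DataError(f"unknown imputation method {method!r}")


def impute_against(
    target: FeatureTable,
    reference: FeatureTable,
    spec: GroupSpec,
    method: str = "knn",
    k: int = 5,
    metric: str = "euclidean",
) -> tuple[FeatureTable, ImputationReport]:
    """Fill ``target``'s missing cells using only ``reference`` records.

    The leak-free counterpart of :func:`impute` for held-out data: column
    means come from the reference table's observed values, and KNN
    neighbors are drawn exclusively from reference records (anchored, as
    always, on the complete columns). Target and reference must share the
    same column layout.
    """
    if target.column_ids != reference.column_ids:
        raise DataError("target and reference must have identical columns")
    if method not in ("mean", "knn"):
        raise DataError(f"unknown imputation method {method!r}")
    values = target.values.copy()
    mask = target.mask
    n_missing = int((~mask).sum())
    if n_missing == 0:
        return target.copy(), ImputationReport(0, 0, k if method == "knn" else None, method)

    if method == "knn":
        if not spec.complete_columns:
            raise DataError("no complete columns: record distances are undefined")
        if k < 1 or k >= reference.n_records + 1:
            raise DataError("k must satisfy 1 <= k <= number of reference records")
        idx = [target.column_index(c) for c in spec.complete_columns]
        cross = cdist(target.values[:, idx], reference.values[:, idx], metric=metric)
        if metric == "cosine" and not np.isfinite(cross).all():
            cross = np.nan_to_num(cross, nan=1.0)

    fallback = 0
    for b in range(target.n_features):
        missing_rows = np.nonzero(~mask[:, b])[0]
        if missing_rows.size == 0:
            continue
        obs_rows = np.nonzero(reference.mask[:, b])[0]
        if obs_rows.size == 0:
            raise DataError(
                f"column {target.column_ids[b]!r} has no observed reference value"
            )
        if method == "mean":
            values[missing_rows, b] = reference.values[obs_rows, b].mean()
            continue
        sub = cross[np.ix_(missing_rows, obs_rows)]
        order = np.argsort(sub, axis=1, kind="stable")[:, :k]
        neighbor_d = np.take_along_axis(sub, order, axis=1)
        neighbor_v = reference.values[obs_rows[order], b]
        weights = 1.0 / (neighbor_d + EPSILON)
        weights /= weights.sum(axis=1, keepdims=True)
        values[missing_rows, b] = (weights * neighbor_v).sum(axis=1)

    filled = FeatureTable(
        values, np.ones_like(mask, dtype=bool), target.column_ids, target.row_ids
    )
    return filled, ImputationReport(
        n_missing, fallback, k if method == "knn" else None, method
    )
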