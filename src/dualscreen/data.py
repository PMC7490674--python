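"""Data model and I/O for grouped, partially observed tabular health records.

Records are elderly clients of community primary-care services; columns are
numeric health features split into two groups:

* ``profile``    — demographics, bio-measurements, medical history;
* ``assessment`` — items from health-assessment questionnaires.

Missing entries are first-class: every table carries an explicit boolean
observation mask, and any column with at least one unobserved cell is an
*incomplete* feature. The binary outcome is derived from the MMSE cognitive
screen: a score below 24 marks a high-risk case.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

PROFILE = "profile"
ASSESSMENT = "assessment"
LABEL = "label"

_VALID_ROLES = {PROFILE, ASSESSMENT, LABEL}

MMSE_CUTOFF = 24
MMSE_MAX = 30


class DataError(ValueError):
    """Raised for malformed tables, configs, or label inputs."""


@dataclass
class FeatureTable:
    """A record-by-feature numeric matrix with an explicit observation mask.

    Parameters
    ----------
    values : (m, n) float array
        Feature values. Entries where ``mask`` is False are meaningless and
        must be excluded from every statistic.
    mask : (m, n) bool array
        True where the value is observed.
    column_ids : sequence of str
        Unique feature names, length n.
    row_ids : sequence of str
        Unique record identifiers, length m.
    """

    values: np.ndarray
    mask: np.ndarray
    column_ids: tuple[str, ...]
    row_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.column_ids = tuple(str(c) for c in self.column_ids)
        self.row_ids = tuple(str(r) for r in self.row_ids)
        m, n = self.values.shape if self.values.ndim == 2 else (0, 0)
        if self.values.ndim != 2 or m < 1 or n < 1:
            raise DataError("values must be a 2-D matrix with m >= 1, n >= 1")
        if self.mask.shape != self.values.shape:
            raise DataError("mask and values must have identical shape")
        if len(self.column_ids) != n:
            raise DataError("column_ids length must equal number of columns")
        if len(self.row_ids) != m:
            raise DataError("row_ids length must equal number of rows")
        if len(set(self.column_ids)) != n:
            raise DataError("column_ids must be unique")
        if len(set(self.row_ids)) != m:
            raise DataError("row_ids must be unique")
        if not np.isfinite(self.values[self.mask]).all():
            raise DataError("observed values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column_index(self, column_id: str) -> int:
        return self.column_ids.index(column_id)

    def is_complete(self) -> bool:
        return bool(self.mask.all())

    def observed_matrix(self) -> np.ndarray:
        """Values with unobserved cells replaced by NaN."""
        out = self.values.copy()
        out[~self.mask] = np.nan
        return out

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.values.copy(), self.mask.copy(), self.column_ids, self.row_ids
        )


@dataclass(frozen=True)
class GroupSpec:
    """Partition of columns into profile/assessment and complete/incomplete.

    ``complete_columns`` are fully observed across all records; every
    ``incomplete_columns`` member has at least one unobserved cell. Both
    partitions cover all columns and are disjoint, so
    ``n == n_p + n_q == n_c + n_s``.
    """

    profile_columns: tuple[str, ...]
    assessment_columns: tuple[str, ...]
    complete_columns: tuple[str, ...]
    incomplete_columns: tuple[str, ...]

    def __post_init__(self) -> None:
        p, q = set(self.profile_columns), set(self.assessment_columns)
        c, s = set(self.complete_columns), set(self.incomplete_columns)
        if p & q:
            raise DataError("profile and assessment groups overlap")
        if c & s:
            raise DataError("complete and incomplete sets overlap")
        if p | q != c | s:
            raise DataError("group partition and completeness partition cover different columns")

    @property
    def n_p(self) -> int:
        return len(self.profile_columns)

    @property
    def n_q(self) -> int:
        return len(self.assessment_columns)

    @property
    def n_c(self) -> int:
        return len(self.complete_columns)

    @property
    def n_s(self) -> int:
        return len(self.incomplete_columns)

    @property
    def n(self) -> int:
        return self.n_p + self.n_q

    @staticmethod
    def from_table(
        table: FeatureTable,
        profile_columns: "list[str] | tuple[str, ...]",
        assessment_columns: "list[str] | tuple[str, ...]",
    ) -> "GroupSpec":
        """Build a spec with the complete/incomplete split computed from the mask."""
        observed = table.mask.all(axis=0)
        complete = tuple(c for c, full in zip(table.column_ids, observed) if full)
        incomplete = tuple(c for c, full in zip(table.column_ids, observed) if not full)
        return GroupSpec(tuple(profile_columns), tuple(assessment_columns), complete, incomplete)


@dataclass
class LabelVector:
    """Binary outcome per record: 1 = high risk (MMSE < 24), 0 = normal."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise DataError("labels must be a 1-D vector")
        if not np.isin(self.labels, (0, 1)).all():
            raise DataError("labels must be binary (0/1)")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int(len(self.labels) - self.labels.sum())


def derive_labels(mmse_scores) -> LabelVector:
    """Binarize MMSE scores: 1 (high risk) iff score < 24, else 0 (normal).

    Scores must lie in the instrument's range [0, 30].
    """
    scores = np.asarray(mmse_scores)
    if scores.size and (np.any(scores < 0) or np.any(scores > MMSE_MAX)):
        raise DataError(f"MMSE scores must lie in [0, {MMSE_MAX}]")
    return LabelVector((scores < MMSE_CUTOFF).astype(int))


def _dialect(path: str) -> str:
    return "\t" if os.path.splitext(str(path))[1].lower() in (".tsv", ".tab") else ","


def read_group_config(path: str) -> dict[str, str]:
    """Read a column -> role (profile|assessment|label) mapping from YAML."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict) or not config:
        raise DataError("group config must be a non-empty column -> role mapping")
    config = {str(k): str(v) for k, v in config.items()}
    bad = {v for v in config.values() if v not in _VALID_ROLES}
    if bad:
        raise DataError(f"unknown role(s) in group config: {sorted(bad)}")
    if sum(1 for v in config.values() if v == LABEL) > 1:
        raise DataError("group config declares more than one label column")
    return config


def load_table(
    path: str,
    group_config: str,
    missing_token: str = "",
) -> tuple[FeatureTable, GroupSpec, "LabelVector | None"]:
    """Load a delimited table and its feature-group configuration.

    The config file (YAML mapping) assigns every data column a role of
    ``profile``, ``assessment`` or ``label``. Cells equal to ``missing_token``
    (default: empty) are unobserved; everything else must parse as a number.
    The label column, if configured and present, is returned separately —
    imputation does not need it, training and evaluation do.
    """
    config = read_group_config(group_config)
    sep = _dialect(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    columns = [str(c) for c in df.columns]

    unknown = [c for c in config if c not in columns and config[c] != LABEL]
    if unknown:
        raise DataError(f"config names column(s) absent from the data: {unknown}")
    missing_cfg = [c for c in columns if c not in config]
    if missing_cfg:
        raise DataError(f"data column(s) absent from the config: {missing_cfg}")

    label_col = next((c for c, v in config.items() if v == LABEL), None)
    feature_cols = [c for c in columns if c != label_col]

    raw = df[feature_cols].to_numpy(dtype=object)
    mask = raw != missing_token
    values = np.zeros(raw.shape, dtype=float)
    rows, cols = np.nonzero(mask)
    for i, j in zip(rows, cols):
        try:
            values[i, j] = float(raw[i, j])
        except ValueError:
            raise DataError(
                f"non-numeric cell at row {i}, column {feature_cols[j]!r}: {raw[i, j]!r}"
            ) from None

    table = FeatureTable(
        values, mask, tuple(feature_cols), tuple(str(i) for i in range(len(df)))
    )
    spec = GroupSpec.from_table(
        table,
        [c for c in feature_cols if config[c] == PROFILE],
        [c for c in feature_cols if config[c] == ASSESSMENT],
    )

    labels = None
    if label_col is not None and label_col in columns:
        lab_raw = df[label_col].to_numpy(dtype=object)
        if np.any(lab_raw == missing_token):
            raise DataError("label column contains missing entries")
        labels = LabelVector(np.array([int(float(v)) for v in lab_raw]))
    return table, spec, labels


def write_table(
    table: FeatureTable,
    path: str,
    labels: "LabelVector | None" = None,
    label_column: str = "label",
    missing_token: str = "",
) -> None:
    """Write a table in the CSV/TSV dialect implied by the file extension.

    Unobserved cells are written as ``missing_token`` so that a subsequent
    :func:`load_table` round-trips values, mask, and groups exactly.
    """
    sep = _dialect(path)
    out = pd.DataFrame(table.values, columns=list(table.column_ids))
    out = out.astype(object).where(table.mask, other=missing_token)
    if labels is not None:
        if len(labels) != table.n_records:
            raise DataError("labels length must match record count")
        out[label_column] = labels.labels
    out.to_csv(path, sep=sep, index=False)


def write_group_config(
    spec: GroupSpec,
    path: str,
    label_column: "str | None" = "label",
) -> None:
    """Write the column -> role mapping consumed by :func:`load_table`."""
    config: dict[str, str] = {}
    for c in spec.profile_columns:
        config[c] = PROFILE
    for c in spec.assessment_columns:
        config[c] = ASSESSMENT
    if label_column is not None:
        config[label_column] = LABEL
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def group_indices(table: FeatureTable, spec: GroupSpec) -> tuple[np.ndarray, np.ndarray]:
    """Column indices of the profile and assessment groups, in table order."""
    profile = set(spec.profile_columns)
    assessment = set(spec.assessment_columns)
    p_idx = np.array([i for i, c in enumerate(table.column_ids) if c in profile], dtype=int)
    q_idx = np.array([i for i, c in enumerate(table.column_ids) if c in assessment], dtype=int)
    return p_idx, q_idx
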