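import numpy as np
import pytest

from dualscreen.data import FeatureTable, GroupSpec, LabelVector


def table_from_nan(values, profile=None, column_ids=None):
    """Build a FeatureTable (+GroupSpec) from a matrix with NaN = missing."""
    values = np.asarray(values, dtype=float)
    mask = ~np.isnan(values)
    filled = np.where(mask, values, 0.0)
    m, n = values.shape
    cols = tuple(column_ids) if column_ids else tuple(f"c{j}" for j in range(n))
    table = FeatureTable(filled, mask, cols, tuple(f"r{i}" for i in range(m)))
    if profile is None:
        profile = cols[: max(1, n // 2)]
    assessment = tuple(c for c in cols if c not in set(profile))
    spec = GroupSpec.from_table(table, tuple(profile), assessment)
    return table, spec


def random_masked_table(rng, m, n, missing_frac=0.3, n_complete=None):
    """Random table with a random MCAR mask; >=1 complete column guaranteed."""
    values = rng.normal(size=(m, n))
    mask = rng.random((m, n)) >= missing_frac
    mask[:, 0] = True  # anchor: at least one complete column
    if n_complete is not None:
        mask[:, :n_complete] = True
    # no fully-missing columns (mean imputation precondition)
    for j in range(n):
        if not mask[:, j].any():
            mask[rng.integers(m), j] = True
    nan_values = np.where(mask, values, np.nan)
    return table_from_nan(nan_values)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def tiny_incomplete():
    """3x2 table with one missing cell in column b."""
    return table_from_nan(
        [[1.0, 2.0], [4.0, np.nan], [7.0, 8.0]],
        profile=("a",),
        column_ids=("a", "b"),
    )


def separable_dataset(rng, m=40, n_p=2, n_q=2, gap=4.0):
    """Linearly separable two-group toy with balanced classes."""
    y = np.arange(m) % 2
    shift = gap * (2.0 * y - 1.0)
    P = rng.normal(size=(m, n_p)) + shift[:, None]
    Q = rng.normal(size=(m, n_q)) - shift[:, None]
    values = np.concatenate([P, Q], axis=1)
    cols = tuple(f"p{j}" for j in range(n_p)) + tuple(f"q{j}" for j in range(n_q))
    table = FeatureTable(
        values, np.ones_like(values, dtype=bool), cols, tuple(f"r{i}" for i in range(m))
    )
    spec = GroupSpec.from_table(table, cols[:n_p], cols[n_p:])
    return table, spec, LabelVector(y)
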