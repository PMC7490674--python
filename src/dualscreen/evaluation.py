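"""10-fold cross-validation, screening metrics, and paired significance tests.

Records are randomly split into 10 near-equal folds; each fold serves once
as the test set while the other nine train. Four metrics summarize each
test fold: AUC (probability a random high-risk case outscores a random
normal case, ties counting one half), average precision (recall-increment-
weighted precision over the PR curve), sensitivity (recall of high-risk
cases) and specificity (recall of normal cases). Algorithms are compared to
a reference by one-sided paired t-tests across the fold-wise metric values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .baselines import BaselineSpec, FCLVariant, fit_baseline
from .data import DataError, FeatureTable, GroupSpec, LabelVector
from .imputation import impute, impute_against
from .network import TrainConfig

N_FOLDS = 10
METRICS = ("auc", "ap", "sensitivity", "specificity")


@dataclass(frozen=True)
class FoldAssignment:
    """Fold index (0..9) per record, derived from a seeded permutation."""

    fold_index: np.ndarray
    seed: int

    def test_rows(self, fold: int) -> np.ndarray:
        return np.nonzero(self.fold_index == fold)[0]

    def train_rows(self, fold: int) -> np.ndarray:
        return np.nonzero(self.fold_index != fold)[0]


def make_folds(
    m: int,
    seed: int,
    n_folds: int = N_FOLDS,
    stratify_labels: "LabelVector | None" = None,
) -> FoldAssignment:
    """Randomly partition m records into folds whose sizes differ by <= 1.

    The split is unstratified by default, matching a plain random split;
    pass ``stratify_labels`` to balance class proportions across folds.
    """
    if m < n_folds:
        raise DataError(f"need at least {n_folds} records, got {m}")
    rng = np.random.default_rng(seed)
    fold_index = np.empty(m, dtype=int)
    if stratify_labels is None:
        order = rng.permutation(m)
        for fold, chunk in enumerate(np.array_split(order, n_folds)):
            fold_index[chunk] = fold
    else:
        y = stratify_labels.labels
        for cls in (0, 1):
            rows = np.nonzero(y == cls)[0]
            rows = rng.permutation(rows)
            fold_index[rows] = np.arange(rows.size) % n_folds
    return FoldAssignment(fold_index, seed)


@dataclass(frozen=True)
class Metrics:
    auc: float
    ap: float
    sensitivity: float
    specificity: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.auc, self.ap, self.sensitivity, self.specificity)


def compute_metrics(scores, classes, labels) -> Metrics:
    """The four screening metrics on one test set.

    ``scores`` rank the records (higher = more likely high risk), ``classes``
    are the thresholded predictions, ``labels`` the ground truth. Both
    classes must be present in ``labels``, otherwise AUC/AP are undefined.
    """
    scores = np.asarray(scores, dtype=float)
    classes = np.asarray(classes, dtype=int)
    y = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels, dtype=int)
    if y.min() == y.max():
        raise DataError("test labels contain a single class; AUC/AP are undefined")
    auc = float(roc_auc_score(y, scores))
    ap = float(average_precision_score(y, scores))
    tp = int(((classes == 1) & (y == 1)).sum())
    fn = int(((classes == 0) & (y == 1)).sum())
    tn = int(((classes == 0) & (y == 0)).sum())
    fp = int(((classes == 1) & (y == 0)).sum())
    return Metrics(auc, ap, tp / (tp + fn), tn / (tn + fp))


@dataclass
class CVResult:
    """Per-fold metrics for each algorithm, with means, SDs and p-values."""

    per_fold: dict[str, np.ndarray]  # label -> (n_folds, 4) array
    folds: FoldAssignment
    seed: int
    resampled_folds: int = 0

    def mean(self, label: str) -> Metrics:
        return Metrics(*self.per_fold[label].mean(axis=0))

    def sd(self, label: str) -> Metrics:
        return Metrics(*self.per_fold[label].std(axis=0, ddof=1))

    def to_frame(self, decimals: "int | None" = None) -> pd.DataFrame:
        rows = []
        for label, vals in self.per_fold.items():
            mean, sd = vals.mean(axis=0), vals.std(axis=0, ddof=1)
            row = {"algorithm": label}
            for j, metric in enumerate(METRICS):
                if decimals is None:
                    row[f"{metric}_mean"], row[f"{metric}_sd"] = mean[j], sd[j]
                else:
                    row[f"{metric}_mean"] = round(mean[j], decimals)
                    row[f"{metric}_sd"] = round(sd[j], decimals)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairedTest:
    p_value: float
    mean_difference: float
    degenerate: bool = False


def compare_to_reference(cv: CVResult, reference: str) -> dict[str, dict[str, PairedTest]]:
    """One-sided paired t-tests: does the reference exceed each competitor?

    Pairs the 10 fold-wise values of each metric. Zero-variance differences
    are reported as degenerate with p = 0.5 (no difference), 0 (reference
    uniformly higher) or 1 (uniformly lower).
    """
    if reference not in cv.per_fold:
        raise DataError(f"reference algorithm {reference!r} not in results")
    ref = cv.per_fold[reference]
    out: dict[str, dict[str, PairedTest]] = {}
    for label, vals in cv.per_fold.items():
        if label == reference:
            continue
        tests = {}
        for j, metric in enumerate(METRICS):
            diff = ref[:, j] - vals[:, j]
            if np.allclose(diff.std(ddof=1), 0.0):
                mu = float(diff.mean())
                p = 0.5 if np.isclose(mu, 0.0) else (0.0 if mu > 0 else 1.0)
                tests[metric] = PairedTest(p, mu, degenerate=True)
            else:
                res = stats.ttest_rel(ref[:, j], vals[:, j], alternative="greater")
                tests[metric] = PairedTest(float(res.pvalue), float(diff.mean()))
        out[label] = tests
    return out


def cross_validate(
    table: FeatureTable,
    spec: GroupSpec,
    labels: LabelVector,
    algorithms: "list[BaselineSpec]",
    seed: int = 0,
    train_cfg: "TrainConfig | None" = None,
    variant: FCLVariant = FCLVariant(),
    threshold: float = 0.5,
    n_folds: int = N_FOLDS,
    stratified: bool = False,
    max_resample: int = 20,
    fold_imputation: "dict | None" = None,
) -> CVResult:
    """Evaluate every algorithm on one shared fold assignment.

    All grid entries see identical folds, so pairwise comparisons are
    paired by construction. If an unstratified split happens to produce a
    single-class test fold (possible on small imbalanced samples), the
    split is redrawn with a shifted seed and a warning is issued.

    By default the table must already be complete (imputed once up front,
    the evaluated pipeline's stage order). Passing ``fold_imputation``
    (e.g. ``{"method": "knn", "k": 5}``) switches to the leak-free mode:
    each training fold is imputed on its own records only, and the test
    fold is filled against the training records.
    """
    if fold_imputation is None and not table.is_complete():
        raise DataError(
            "cross-validation requires a complete (imputed) table unless "
            "fold_imputation is given"
        )
    y = labels.labels
    folds = None
    resampled = 0
    for attempt in range(max_resample):
        candidate = make_folds(
            table.n_records,
            seed + attempt,
            n_folds,
            stratify_labels=labels if stratified else None,
        )
        ok = all(
            len(np.unique(y[candidate.test_rows(f)])) == 2 for f in range(n_folds)
        )
        if ok:
            folds = candidate
            resampled = attempt
            break
    if folds is None:
        raise DataError("could not draw folds with both classes in every test fold")
    if resampled:
        warnings.warn(
            f"fold split redrawn {resampled} time(s) to avoid single-class test folds",
            stacklevel=2,
        )

    def subset(rows: np.ndarray) -> tuple[FeatureTable, LabelVector]:
        sub = FeatureTable(
            table.values[rows],
            table.mask[rows],
            table.column_ids,
            tuple(table.row_ids[r] for r in rows),
        )
        return sub, LabelVector(y[rows])

    per_fold = {alg.label: np.zeros((n_folds, 4)) for alg in algorithms}
    for f in range(n_folds):
        train_tab, train_lab = subset(folds.train_rows(f))
        test_tab, test_lab = subset(folds.test_rows(f))
        if fold_imputation is not None:
            raw_train = train_tab
            train_tab, _ = impute(train_tab, spec, **fold_imputation)
            test_tab, _ = impute_against(test_tab, raw_train, spec, **fold_imputation)
        for alg in algorithms:
            model = fit_baseline(
                alg,
                train_tab,
                spec,
                train_lab,
                seed=seed + f,
                train_cfg=train_cfg,
                variant=variant,
                threshold=threshold,
            )
            metrics = compute_metrics(
                model.scores(test_tab), model.classes(test_tab), test_lab
            )
            per_fold[alg.label][f] = metrics.as_tuple()
    return CVResult(per_fold, folds, seed, resampled)
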