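"""The comparison grid: conventional learners, with and without cost weighting.

Eight model families — logistic regression, decision tree, random forest,
three SVM kernels, the single neural network, and the dual network — each
run plain and with cost-sensitive learning (CSL), giving the 16-entry grid.
For the non-neural learners CSL is realized as class weighting with the
same majority/minority ratio w = m^n/m^d used in the neural loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data import DataError, FeatureTable, GroupSpec, LabelVector
from .network import (
    DualNetClassifier,
    FCLVariant,
    SingleNetClassifier,
    TrainConfig,
    cost_weight,
)

BASE_NAMES = ("LR", "DT", "RF", "SVM_linear", "SVM_poly", "SVM_rbf", "SNN", "DNN")

RF_N_TREES = 100
RF_MAX_DEPTH = 3


@dataclass(frozen=True)
class BaselineSpec:
    """One grid entry: a model family plus the cost-sensitive switch."""

    name: str
    cost_sensitive: bool = False
    hyperparams: tuple = ()

    def __post_init__(self) -> None:
        if self.name not in BASE_NAMES:
            raise DataError(f"unknown algorithm {self.name!r}; choose from {BASE_NAMES}")

    @property
    def label(self) -> str:
        return f"{self.name}+CSL" if self.cost_sensitive else self.name


def enumerate_grid() -> list[BaselineSpec]:
    """All 16 configurations: 8 families × {plain, +CSL}."""
    return [
        BaselineSpec(name, cs) for name in BASE_NAMES for cs in (False, True)
    ]


@dataclass
class FittedModel:
    """Uniform handle over a fitted learner.

    ``scores`` returns a continuous ranking score per record (a probability
    for probabilistic models, the decision-function value for SVMs) so AUC
    and AP are computable for every grid entry; ``classes`` applies the
    model's thresholding rule.
    """

    spec: BaselineSpec
    scores: Callable[[FeatureTable], np.ndarray]
    classes: Callable[[FeatureTable], np.ndarray]
    params_record: dict = field(default_factory=dict)


def _class_weights(labels: LabelVector) -> dict[int, float]:
    return {0: 1.0, 1: cost_weight(labels.n_negative, labels.n_positive)}


def fit_baseline(
    spec: BaselineSpec,
    table: FeatureTable,
    group_spec: GroupSpec,
    labels: LabelVector,
    seed: int = 0,
    train_cfg: "TrainConfig | None" = None,
    variant: FCLVariant = FCLVariant(),
    threshold: float = 0.5,
) -> FittedModel:
    """Fit one grid entry on a complete table and wrap it uniformly.

    Random forests use 100 trees of maximum depth 3; the SNN uses hidden
    dims (2·d1, 2·d2); other scikit-learn models keep their library
    defaults, which are recorded in ``params_record`` for transparency.
    """
    if not table.is_complete():
        raise DataError("baselines require a complete (imputed) table")
    if labels.n_positive == 0 or labels.n_negative == 0:
        raise DataError("training labels must contain both classes")
    X, y = table.values, labels.labels
    weights = _class_weights(labels) if spec.cost_sensitive else None
    extra = dict(spec.hyperparams)

    if spec.name in ("SNN", "DNN"):
        cfg = train_cfg if train_cfg is not None else TrainConfig()
        cfg = replace(cfg, cost_sensitive=spec.cost_sensitive, seed=seed)
        cls = DualNetClassifier if spec.name == "DNN" else SingleNetClassifier
        net = cls(cfg, variant).fit(table, group_spec, labels)
        return FittedModel(
            spec,
            scores=lambda t: net.predict_proba(t, group_spec),
            classes=lambda t: net.predict(t, group_spec, threshold)[1],
            params_record=vars(cfg).copy(),
        )

    if spec.name == "LR":
        model = LogisticRegression(class_weight=weights, random_state=seed, **extra)
    elif spec.name == "DT":
        model = DecisionTreeClassifier(class_weight=weights, random_state=seed, **extra)
    elif spec.name == "RF":
        model = RandomForestClassifier(
            n_estimators=RF_N_TREES,
            max_depth=RF_MAX_DEPTH,
            class_weight=weights,
            random_state=seed,
            **extra,
        )
    else:  # SVM family: ranking by decision function, classes by its sign
        kernel = {"SVM_linear": "linear", "SVM_poly": "poly", "SVM_rbf": "rbf"}[spec.name]
        model = SVC(kernel=kernel, class_weight=weights, random_state=seed, **extra)
        model.fit(X, y)
        return FittedModel(
            spec,
            scores=lambda t: model.decision_function(t.values),
            classes=lambda t: (model.decision_function(t.values) >= 0).astype(int),
            params_record=model.get_params(),
        )

    model.fit(X, y)
    return FittedModel(
        spec,
        scores=lambda t: model.predict_proba(t.values)[:, 1],
        classes=lambda t: (model.predict_proba(t.values)[:, 1] >= threshold).astype(int),
        params_record=model.get_params(),
    )
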