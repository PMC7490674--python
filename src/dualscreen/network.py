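"""Dual-branch feed-forward network for cost-sensitive risk classification.

Two two-hidden-layer ReLU branches learn latent representations of the
profile and assessment feature groups separately:

    h^p(1) = ReLU(p W^p(1) + b^p(1)),  h^p(2) = ReLU(h^p(1) W^p(2) + b^p(2))
    h^q(1) = ReLU(q W^q(1) + b^q(1)),  h^q(2) = ReLU(h^q(1) W^q(2) + b^q(2))

The branch outputs are concatenated, h = [h^p(2), h^q(2)], optionally passed
through extra fully connected ReLU layers, and mapped to a risk probability
by a sigmoid head, ŷ = σ(h W^y + b^y). Training minimizes the mean
cross-entropy, optionally cost-sensitive: each high-risk sample's term is
weighted by w = m^n / m^d, the ratio of normal to high-risk training counts,
so the minority class is not drowned out. Optimization is mini-batch SGD
with momentum; everything is plain numpy and fully deterministic per seed.

The single-network (SNN) baseline reuses the identical branch arithmetic
with one branch consuming all features, dimensioned at (2·d1, 2·d2) so its
final representation matches the dual network's concatenated size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DataError, FeatureTable, GroupSpec, LabelVector, group_indices

#: Probabilities are clamped to this interval inside the loss to avoid log(0).
PROB_CLIP = 1e-7

PARAMS_FORMAT_VERSION = 1


@dataclass
class TrainConfig:
    """Hyperparameters of the SGD-with-momentum trainer.

    d1, d2 are the widths of the first and second hidden layer of each
    branch (defaults 128 and 32). Momentum defaults to 0.9. Learning rate,
    epoch budget and batch size are configurable; training runs the full
    epoch budget unless early stopping on a training-loss plateau is
    switched on.
    """

    d1: int = 128
    d2: int = 32
    learning_rate: float = 0.01
    momentum: float = 0.9
    epochs: int = 200
    batch_size: int = 64
    cost_sensitive: bool = False
    seed: int = 0
    early_stopping: bool = False
    patience: int = 20
    tol: float = 1e-5
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise DataError("learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise DataError("momentum must lie in [0, 1)")
        if self.epochs < 0 or self.batch_size < 1:
            raise DataError("epochs must be >= 0 and batch_size >= 1")


@dataclass(frozen=True)
class FCLVariant:
    """Extra fully connected ReLU layers between concatenation and the head.

    ``extra_dims`` lists the width of each added layer; the base model has
    none. Widths default to the concatenated representation size when built
    via :meth:`with_layers`.
    """

    extra_dims: tuple[int, ...] = ()

    @property
    def extra_layers(self) -> int:
        return len(self.extra_dims)

    @staticmethod
    def with_layers(n_layers: int, d2: int = 32) -> "FCLVariant":
        if n_layers not in (0, 1, 2):
            raise DataError("supported variants add 0, 1 or 2 fully connected layers")
        return FCLVariant(tuple([2 * d2] * n_layers))


@dataclass
class NetParams:
    """Trainable weights of a branched ReLU network with a sigmoid head.

    ``branches`` holds, per branch, the list of (W, b) layer pairs;
    ``extras`` the optional post-concatenation layers; (``W_y``, ``b_y``)
    the classification head. The dual model has two branches (profile,
    assessment); the single-network baseline has one.
    """

    branches: list[list[tuple[np.ndarray, np.ndarray]]]
    extras: list[tuple[np.ndarray, np.ndarray]]
    W_y: np.ndarray
    b_y: np.ndarray

    @property
    def input_dims(self) -> tuple[int, ...]:
        return tuple(branch[0][0].shape[0] for branch in self.branches)

    def flat(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for branch in self.branches:
            for W, b in branch:
                out.extend((W, b))
        for W, b in self.extras:
            out.extend((W, b))
        out.extend((self.W_y, self.b_y))
        return out

    def copy(self) -> "NetParams":
        return NetParams(
            [[(W.copy(), b.copy()) for W, b in branch] for branch in self.branches],
            [(W.copy(), b.copy()) for W, b in self.extras],
            self.W_y.copy(),
            self.b_y.copy(),
        )


# Backwards-compatible alias used throughout the docs: the dual model's
# parameter container is a two-branch NetParams.
DualNetParams = NetParams


def _he_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(
    input_dims: "tuple[int, ...]",
    d1: int,
    d2: int,
    variant: FCLVariant = FCLVariant(),
    seed: int = 0,
) -> NetParams:
    """He-style uniform initialization of every layer, from one seeded RNG."""
    rng = np.random.default_rng(seed)
    branches = []
    for n_in in input_dims:
        branches.append(
            [
                (_he_uniform(rng, n_in, d1), np.zeros(d1)),
                (_he_uniform(rng, d1, d2), np.zeros(d2)),
            ]
        )
    concat = d2 * len(input_dims)
    extras = []
    width = concat
    for d in variant.extra_dims:
        extras.append((_he_uniform(rng, width, d), np.zeros(d)))
        width = d
    W_y = _he_uniform(rng, width, 1)
    return NetParams(branches, extras, W_y, np.zeros(1))


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _forward_full(params: NetParams, inputs: "list[np.ndarray]"):
    """Forward pass keeping every activation (for backprop)."""
    if len(inputs) != len(params.branches):
        raise DataError("number of input blocks must match number of branches")
    branch_acts = []
    outs = []
    for X, branch in zip(inputs, params.branches):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.isfinite(X).all():
            raise DataError("network inputs must be finite")
        if X.shape[1] != branch[0][0].shape[0]:
            raise DataError(
                f"input width {X.shape[1]} does not match branch input dim "
                f"{branch[0][0].shape[0]}"
            )
        acts = [X]
        for W, b in branch:
            acts.append(_relu(acts[-1] @ W + b))
        branch_acts.append(acts)
        outs.append(acts[-1])
    h = np.concatenate(outs, axis=1)
    extra_acts = [h]
    for W, b in params.extras:
        extra_acts.append(_relu(extra_acts[-1] @ W + b))
    y_hat = _sigmoid(extra_acts[-1] @ params.W_y + params.b_y)[:, 0]
    return branch_acts, h, extra_acts, y_hat


def forward(
    p: np.ndarray,
    q: "np.ndarray | None",
    params: NetParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Compute the concatenated representation h and risk probability ŷ.

    ``p`` and ``q`` are the profile and assessment inputs (row vectors or
    matrices). For a single-branch network pass ``q=None``. Returns
    (h, ŷ) with h of width 2·d2 (or d2 per branch) and ŷ in (0, 1).
    """
    inputs = [p] if q is None else [p, q]
    _, h, _, y_hat = _forward_full(params, inputs)
    if np.asarray(p).ndim == 1:
        return h[0], float(y_hat[0])
    return h, y_hat


def cost_weight(n_normal: int, n_high_risk: int) -> float:
    """Cost ratio w = m^n / m^d applied to each high-risk sample's loss term."""
    if n_high_risk <= 0:
        raise DataError("cost ratio undefined without high-risk training samples")
    return n_normal / n_high_risk


def loss(
    y_hat: np.ndarray,
    y: np.ndarray,
    cost_sensitive: bool = False,
    class_counts: "tuple[int, int] | None" = None,
) -> float:
    """Mean (optionally cost-sensitive) binary cross-entropy.

    L = mean_i −[w_i · y_i · log ŷ_i + (1 − y_i) · log(1 − ŷ_i)] with
    w_i = m^n/m^d for high-risk samples and 1 otherwise; with
    ``cost_sensitive=False`` all w_i = 1 and the plain supervised loss is
    recovered exactly. ``class_counts`` is (n_normal, n_high_risk); when
    omitted it is computed from ``y``.
    """
    y_hat = np.clip(np.asarray(y_hat, dtype=float), PROB_CLIP, 1.0 - PROB_CLIP)
    y = np.asarray(y, dtype=float)
    if cost_sensitive:
        if class_counts is None:
            class_counts = (int((y == 0).sum()), int((y == 1).sum()))
        w = cost_weight(*class_counts)
    else:
        w = 1.0
    terms = -(w * y * np.log(y_hat) + (1.0 - y) * np.log(1.0 - y_hat))
    return float(terms.mean())


def loss_and_grads(
    params: NetParams,
    inputs: "list[np.ndarray]",
    y: np.ndarray,
    w: float = 1.0,
) -> tuple[float, NetParams]:
    """Loss value and analytic gradients for every parameter (backprop).

    The returned :class:`NetParams` holds gradient arrays in the same
    layout as ``params``. ``w`` is the cost ratio applied to positive
    samples' loss terms.
    """
    y = np.asarray(y, dtype=float)
    branch_acts, h, extra_acts, y_hat = _forward_full(params, inputs)
    m = y.shape[0]
    y_hat_c = np.clip(y_hat, PROB_CLIP, 1.0 - PROB_CLIP)
    terms = -(w * y * np.log(y_hat_c) + (1.0 - y) * np.log(1.0 - y_hat_c))
    value = float(terms.mean())

    # d loss / d pre-sigmoid logit, for the weighted cross-entropy
    dz = ((w * y + (1.0 - y)) * y_hat - w * y)[:, None] / m

    top = extra_acts[-1]
    gW_y = top.T @ dz
    gb_y = dz.sum(axis=0)
    d_top = dz @ params.W_y.T

    g_extras = []
    for idx in range(len(params.extras) - 1, -1, -1):
        W, _ = params.extras[idx]
        d_pre = d_top * (extra_acts[idx + 1] > 0)
        g_extras.append((extra_acts[idx].T @ d_pre, d_pre.sum(axis=0)))
        d_top = d_pre @ W.T
    g_extras.reverse()

    g_branches = []
    offset = 0
    for acts, branch in zip(branch_acts, params.branches):
        width = acts[-1].shape[1]
        d_out = d_top[:, offset : offset + width]
        offset += width
        grads = []
        for idx in range(len(branch) - 1, -1, -1):
            W, _ = branch[idx]
            d_pre = d_out * (acts[idx + 1] > 0)
            grads.append((acts[idx].T @ d_pre, d_pre.sum(axis=0)))
            d_out = d_pre @ W.T
        grads.reverse()
        g_branches.append(grads)

    return value, NetParams(g_branches, g_extras, gW_y, gb_y)


def _sgd_fit(
    params: NetParams,
    inputs: "list[np.ndarray]",
    y: np.ndarray,
    cfg: TrainConfig,
    w: float,
) -> tuple[NetParams, list[float]]:
    """Mini-batch SGD with momentum; returns trained params and loss history."""
    params = params.copy()
    flat = params.flat()
    velocity = [np.zeros_like(a) for a in flat]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    m = y.shape[0]
    history: list[float] = []
    best, stale = np.inf, 0
    for _ in range(cfg.epochs):
        order = rng.permutation(m)
        epoch_loss = 0.0
        for start in range(0, m, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            value, grads = loss_and_grads(
                params, [X[batch] for X in inputs], y[batch], w
            )
            epoch_loss += value * len(batch)
            for vel, par, grad in zip(velocity, params.flat(), grads.flat()):
                vel *= cfg.momentum
                vel -= cfg.learning_rate * grad
                par += vel
        history.append(epoch_loss / m)
        if cfg.early_stopping:
            if history[-1] < best - cfg.tol:
                best, stale = history[-1], 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    return params, history


def _min_max_scale(X: np.ndarray) -> np.ndarray:
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (X - lo) / span


class DualNetClassifier:
    """The dual model: profile branch + assessment branch + sigmoid head.

    Feature normalization is off by default (it degraded performance in the
    motivating study); ``cfg.normalize`` enables per-column min-max scaling
    for experimentation.
    """

    def __init__(self, cfg: "TrainConfig | None" = None, variant: FCLVariant = FCLVariant()):
        self.cfg = cfg if cfg is not None else TrainConfig()
        self.variant = variant
        self.params: "NetParams | None" = None
        self.history: list[float] = []
        self._p_idx: "np.ndarray | None" = None
        self._q_idx: "np.ndarray | None" = None

    def _split(self, table: FeatureTable, spec: GroupSpec) -> "list[np.ndarray]":
        if not table.is_complete():
            raise DataError("train/predict require a complete (imputed) table")
        if self._p_idx is None:
            self._p_idx, self._q_idx = group_indices(table, spec)
        P = table.values[:, self._p_idx]
        Q = table.values[:, self._q_idx]
        if self.cfg.normalize:
            P, Q = _min_max_scale(P), _min_max_scale(Q)
        return [P, Q]

    def fit(
        self, table: FeatureTable, spec: GroupSpec, labels: LabelVector
    ) -> "DualNetClassifier":
        y = labels.labels.astype(float)
        inputs = self._split(table, spec)
        if self.cfg.cost_sensitive:
            w = cost_weight(labels.n_negative, labels.n_positive)
        else:
            w = 1.0
        init = init_params(
            (inputs[0].shape[1], inputs[1].shape[1]),
            self.cfg.d1,
            self.cfg.d2,
            self.variant,
            seed=self.cfg.seed,
        )
        self.params, self.history = _sgd_fit(init, inputs, y, self.cfg, w)
        return self

    def predict_proba(self, table: FeatureTable, spec: GroupSpec) -> np.ndarray:
        if self.params is None:
            raise DataError("classifier is not fitted")
        inputs = self._split(table, spec)
        _, _, _, y_hat = _forward_full(self.params, inputs)
        return y_hat

    def predict(
        self, table: FeatureTable, spec: GroupSpec, threshold: float = 0.5
    ) -> tuple[np.ndarray, np.ndarray]:
        probs = self.predict_proba(table, spec)
        return probs, (probs >= threshold).astype(int)


class SingleNetClassifier(DualNetClassifier):
    """SNN baseline: one branch over all n features, dims (2·d1, 2·d2).

    Shares every piece of layer arithmetic with the dual model; only the
    branching differs, so its final representation has the same width 2·d2
    as the dual network's concatenation.
    """

    def _split(self, table: FeatureTable, spec: GroupSpec) -> "list[np.ndarray]":
        if not table.is_complete():
            raise DataError("train/predict require a complete (imputed) table")
        X = table.values
        if self.cfg.normalize:
            X = _min_max_scale(X)
        return [X]

    def fit(
        self, table: FeatureTable, spec: GroupSpec, labels: LabelVector
    ) -> "SingleNetClassifier":
        y = labels.labels.astype(float)
        inputs = self._split(table, spec)
        if self.cfg.cost_sensitive:
            w = cost_weight(labels.n_negative, labels.n_positive)
        else:
            w = 1.0
        init = init_params(
            (inputs[0].shape[1],),
            2 * self.cfg.d1,
            2 * self.cfg.d2,
            self.variant,
            seed=self.cfg.seed,
        )
        self.params, self.history = _sgd_fit(init, inputs, y, self.cfg, w)
        return self


def train(
    table: FeatureTable,
    spec: GroupSpec,
    labels: LabelVector,
    cfg: "TrainConfig | None" = None,
    variant: FCLVariant = FCLVariant(),
) -> NetParams:
    """Train the dual network and return its parameters (functional surface)."""
    return DualNetClassifier(cfg, variant).fit(table, spec, labels).params


def predict(
    table: FeatureTable,
    spec: GroupSpec,
    params: NetParams,
    threshold: float = 0.5,
    normalize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Risk probabilities and thresholded classes (1 iff prob >= threshold)."""
    clf = DualNetClassifier(TrainConfig(normalize=normalize))
    clf.params = params
    probs = clf.predict_proba(table, spec)
    return probs, (probs >= threshold).astype(int)


def save_params(params: NetParams, cfg: TrainConfig, path: str) -> None:
    """Serialize parameters + config to a versioned .npz container."""
    arrays: dict[str, np.ndarray] = {
        "format_version": np.array(PARAMS_FORMAT_VERSION),
        "n_branches": np.array(len(params.branches)),
        "n_extras": np.array(len(params.extras)),
        "W_y": params.W_y,
        "b_y": params.b_y,
    }
    for bi, branch in enumerate(params.branches):
        for li, (W, b) in enumerate(branch):
            arrays[f"branch{bi}_W{li}"] = W
            arrays[f"branch{bi}_b{li}"] = b
    for li, (W, b) in enumerate(params.extras):
        arrays[f"extra_W{li}"] = W
        arrays[f"extra_b{li}"] = b
    for key, val in vars(cfg).items():
        arrays[f"cfg_{key}"] = np.array(val)
    np.savez(path, **arrays)


def load_params(path: str) -> tuple[NetParams, TrainConfig]:
    with np.load(path) as data:
        version = int(data["format_version"])
        if version != PARAMS_FORMAT_VERSION:
            raise DataError(f"unsupported model format version {version}")
        branches = []
        for bi in range(int(data["n_branches"])):
            branch = []
            li = 0
            while f"branch{bi}_W{li}" in data:
                branch.append((data[f"branch{bi}_W{li}"], data[f"branch{bi}_b{li}"]))
                li += 1
            branches.append(branch)
        extras = [
            (data[f"extra_W{li}"], data[f"extra_b{li}"])
            for li in range(int(data["n_extras"]))
        ]
        params = NetParams(branches, extras, data["W_y"], data["b_y"])
        fields = {
            k[4:]: data[k].item() for k in data.files if k.startswith("cfg_")
        }
        cfg = TrainConfig(**fields)
    return params, cfg
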