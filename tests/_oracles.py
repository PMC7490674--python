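"""Independent brute-force reference implementations used only by tests.

Each function re-derives a quantity from first principles with explicit
Python loops, deliberately sharing no code with the package internals.
"""

import math

import numpy as np


def distance_oracle(X, metric):
    m = X.shape[0]
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            a, b = X[i], X[j]
            if metric == "euclidean":
                D[i, j] = math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))
            elif metric == "cityblock":
                D[i, j] = sum(abs(x - y) for x, y in zip(a, b))
            elif metric == "cosine":
                na = math.sqrt(sum(x * x for x in a))
                nb = math.sqrt(sum(x * x for x in b))
                if na == 0 or nb == 0:
                    D[i, j] = 0.0 if i == j else 1.0
                else:
                    D[i, j] = 1.0 - sum(x * y for x, y in zip(a, b)) / (na * nb)
    return D


def mean_impute_oracle(values, mask):
    """Per-column observed means via explicit loops."""
    out = values.astype(float).copy()
    m, n = values.shape
    for j in range(n):
        obs = [values[i, j] for i in range(m) if mask[i, j]]
        mean = sum(obs) / len(obs)
        for i in range(m):
            if not mask[i, j]:
                out[i, j] = mean
    return out


def knn_impute_oracle(values, mask, complete_cols, k, metric="euclidean", eps=1e-8):
    """Weighted-neighbor fill: sort eligible records by (distance, index),
    take k nearest that observe the feature, weight by 1/(d+eps)."""
    m, n = values.shape
    anchor = values[:, complete_cols]
    D = distance_oracle(anchor, metric)
    out = values.astype(float).copy()
    for i in range(m):
        for b in range(n):
            if mask[i, b]:
                continue
            eligible = [(D[i, j], j) for j in range(m) if mask[j, b]]
            eligible.sort(key=lambda t: (t[0], t[1]))
            chosen = eligible[:k]
            weights = [1.0 / (d + eps) for d, _ in chosen]
            total = sum(weights)
            out[i, b] = sum(
                w / total * values[j, b] for w, (_, j) in zip(weights, chosen)
            )
    return out


def auc_oracle(scores, labels):
    """Positive-negative pair counting, ties counted one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def ap_oracle(scores, labels):
    """Threshold sweep over distinct scores: AP = sum (R_t - R_{t-1}) P_t."""
    scores = list(scores)
    labels = list(labels)
    n_pos = sum(labels)
    thresholds = sorted(set(scores), reverse=True)
    ap, prev_recall = 0.0, 0.0
    for t in thresholds:
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 0)
        precision = tp / (tp + fp)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def weighted_ce_oracle(y_hat, y, w, clip=1e-7):
    """Term-by-term cost-sensitive cross-entropy."""
    total = 0.0
    for p, t in zip(y_hat, y):
        p = min(max(p, clip), 1.0 - clip)
        if t == 1:
            total += -w * math.log(p)
        else:
            total += -math.log(1.0 - p)
    return total / len(y)
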