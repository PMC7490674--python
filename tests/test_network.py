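import math

import numpy as np
import pytest

from dualscreen.data import LabelVector
from dualscreen.network import (
    DualNetClassifier,
    FCLVariant,
    NetParams,
    SingleNetClassifier,
    TrainConfig,
    cost_weight,
    forward,
    init_params,
    load_params,
    loss,
    loss_and_grads,
    save_params,
)

from _oracles import weighted_ce_oracle
from conftest import separable_dataset


def zero_params(n_p, n_q, d1, d2):
    return NetParams(
        [
            [(np.zeros((n_p, d1)), np.zeros(d1)), (np.zeros((d1, d2)), np.zeros(d2))],
            [(np.zeros((n_q, d1)), np.zeros(d1)), (np.zeros((d1, d2)), np.zeros(d2))],
        ],
        [],
        np.zeros((2 * d2, 1)),
        np.zeros(1),
    )


class TestForward:
    def test_all_zero_weights_give_probability_one_half(self):
        params = zero_params(3, 2, 4, 2)
        h, y_hat = forward(np.ones(3), np.ones(2), params)
        assert (h == 0).all()
        assert y_hat == pytest.approx(0.5)

    def test_hand_computed_two_feature_toy(self):
        # branch p: W1=[[1,0],[0,1]], b1=[0.5,-3]; W2=[[1],[1]], b2=[0]
        # branch q: W1=[[2,0],[0,2]], b1=[0,0];   W2=[[1],[-1]], b2=[1]
        params = NetParams(
            [
                [
                    (np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([0.5, -3.0])),
                    (np.array([[1.0], [1.0]]), np.array([0.0])),
                ],
                [
                    (np.array([[2.0, 0.0], [0.0, 2.0]]), np.array([0.0, 0.0])),
                    (np.array([[1.0], [-1.0]]), np.array([1.0])),
                ],
            ],
            [],
            np.array([[0.5], [-0.25]]),
            np.array([0.1]),
        )
        p, q = np.array([1.0, 2.0]), np.array([1.0, -1.0])
        # p-branch: relu([1+0.5, 2-3]) = [1.5, 0]; relu(1.5+0) = 1.5
        # q-branch: relu([2, -2]) = [2, 0]; relu(2*1 - 0 + 1) = 3
        # head: sigmoid(1.5*0.5 - 3*0.25 + 0.1) = sigmoid(0.1)
        h, y_hat = forward(p, q, params)
        np.testing.assert_allclose(h, [1.5, 3.0])
        assert y_hat == pytest.approx(1.0 / (1.0 + math.exp(-0.1)))

    def test_negative_preactivation_outputs_exactly_zero(self):
        params = zero_params(1, 1, 1, 1)
        params.branches[0][0] = (np.array([[1.0]]), np.array([-5.0]))
        h, _ = forward(np.array([2.0]), np.array([0.0]), params)
        assert h[0] == 0.0

    def test_branch_isolation(self, rng):
        params = init_params((3, 4), d1=5, d2=2, seed=1)
        p = rng.normal(size=(6, 3))
        q = rng.normal(size=(6, 4))
        h1, _ = forward(p, q, params)
        h2, _ = forward(p, np.zeros_like(q), params)
        np.testing.assert_array_equal(h1[:, :2], h2[:, :2])  # profile half intact
        assert not np.array_equal(h1[:, 2:], h2[:, 2:])

    def test_dimension_mismatch_rejected(self):
        params = zero_params(3, 2, 4, 2)
        with pytest.raises(Exception):
            forward(np.ones(4), np.ones(2), params)


class TestLoss:
    def test_cost_sensitive_with_balanced_counts_equals_plain_loss(self, rng):
        y_hat = rng.uniform(0.05, 0.95, size=10)
        y = np.array([0, 1] * 5)
        assert loss(y_hat, y, cost_sensitive=True, class_counts=(5, 5)) == pytest.approx(
            loss(y_hat, y, cost_sensitive=False), abs=0.0
        )

    def test_perfect_predictions_drive_loss_to_zero(self):
        y = np.array([0, 1, 1, 0])
        y_hat = np.array([1e-9, 1 - 1e-9, 1 - 1e-9, 1e-9])
        assert loss(y_hat, y) < 1e-5

    def test_study_class_counts_give_cost_ratio_4_4(self):
        assert round(cost_weight(1872, 427), 1) == 4.4

    def test_random_batch_matches_term_by_term_oracle(self, rng):
        y_hat = rng.uniform(0.01, 0.99, size=8)
        y = rng.integers(0, 2, size=8)
        counts = (int((y == 0).sum()), max(int((y == 1).sum()), 1))
        y[0] = 1  # guarantee a positive so the ratio is defined
        counts = (int((y == 0).sum()), int((y == 1).sum()))
        w = counts[0] / counts[1]
        got = loss(y_hat, y, cost_sensitive=True, class_counts=counts)
        assert got == pytest.approx(weighted_ce_oracle(y_hat, y, w), rel=1e-12)

    def test_cost_ratio_undefined_without_positives(self):
        with pytest.raises(Exception):
            cost_weight(10, 0)


class TestGradients:
    @pytest.mark.parametrize("extra_dims", [(), (4,), (4, 3)])
    def test_analytic_gradients_match_central_differences(self, rng, extra_dims):
        params = init_params((3, 2), d1=4, d2=2, variant=FCLVariant(extra_dims), seed=7)
        inputs = [rng.normal(size=(6, 3)), rng.normal(size=(6, 2))]
        y = rng.integers(0, 2, size=6).astype(float)
        w = 3.0
        _, grads = loss_and_grads(params, inputs, y, w)
        eps = 1e-6
        for par, grad in zip(params.flat(), grads.flat()):
            flat_p, flat_g = par.ravel(), grad.ravel()
            for idx in range(0, flat_p.size, max(1, flat_p.size // 5)):
                orig = flat_p[idx]
                flat_p[idx] = orig + eps
                up, _ = loss_and_grads(params, inputs, y, w)
                flat_p[idx] = orig - eps
                down, _ = loss_and_grads(params, inputs, y, w)
                flat_p[idx] = orig
                numeric = (up - down) / (2 * eps)
                denom = max(abs(numeric), abs(flat_g[idx]), 1e-8)
                assert abs(numeric - flat_g[idx]) / denom < 1e-5


class TestTraining:
    def test_zero_epochs_returns_initialization(self, rng):
        table, spec, labels = separable_dataset(rng, m=20)
        cfg = TrainConfig(d1=4, d2=2, epochs=0, seed=3)
        clf = DualNetClassifier(cfg).fit(table, spec, labels)
        init = init_params((2, 2), 4, 2, seed=3)
        for a, b in zip(clf.params.flat(), init.flat()):
            np.testing.assert_array_equal(a, b)

    def test_separable_toy_reaches_perfect_training_accuracy(self, rng):
        table, spec, labels = separable_dataset(rng, m=40)
        cfg = TrainConfig(d1=8, d2=4, epochs=80, batch_size=8, seed=0)
        clf = DualNetClassifier(cfg).fit(table, spec, labels)
        _, classes = clf.predict(table, spec)
        assert (classes == labels.labels).all()
        assert clf.history[-1] < clf.history[0]

    def test_same_seed_gives_identical_parameters(self, rng):
        table, spec, labels = separable_dataset(rng, m=24)
        cfg = TrainConfig(d1=4, d2=2, epochs=10, seed=11)
        p1 = DualNetClassifier(cfg).fit(table, spec, labels).params
        p2 = DualNetClassifier(cfg).fit(table, spec, labels).params
        for a, b in zip(p1.flat(), p2.flat()):
            np.testing.assert_array_equal(a, b)

    def test_increasing_cost_ratio_does_not_reduce_predicted_positives(self, rng):
        # fixed imbalanced dataset; averaged over 5 seeds per the behavioral
        # contract: a larger minority weight flags at least as many positives
        from dualscreen.network import _forward_full, _sgd_fit

        counts = {w: [] for w in (1.0, 4.0, 16.0)}
        for seed in range(5):
            r = np.random.default_rng(seed)
            y = (np.arange(60) < 12).astype(float)
            P = r.normal(size=(60, 3)) + 0.8 * y[:, None]
            Q = r.normal(size=(60, 2)) + 0.8 * y[:, None]
            for w in counts:
                params = init_params((3, 2), 6, 3, seed=seed)
                cfg = TrainConfig(d1=6, d2=3, epochs=60, batch_size=16, seed=seed)
                trained, _ = _sgd_fit(params, [P, Q], y, cfg, w)
                _, _, _, probs = _forward_full(trained, [P, Q])
                counts[w].append(int((probs >= 0.5).sum()))
        means = {w: np.mean(v) for w, v in counts.items()}
        assert means[1.0] <= means[4.0] + 1e-9
        assert means[4.0] <= means[16.0] + 1e-9

    def test_cost_sensitive_training_requires_both_classes(self, rng):
        table, spec, _ = separable_dataset(rng, m=12)
        labels = LabelVector(np.zeros(12, dtype=int))
        cfg = TrainConfig(d1=4, d2=2, epochs=1, cost_sensitive=True)
        with pytest.raises(Exception):
            DualNetClassifier(cfg).fit(table, spec, labels)


class TestSingleNetwork:
    def test_snn_dims_double_the_branch_and_match_concat_width(self, rng):
        table, spec, labels = separable_dataset(rng, m=20)
        cfg = TrainConfig(d1=4, d2=2, epochs=1, seed=0)
        clf = SingleNetClassifier(cfg).fit(table, spec, labels)
        (branch,) = clf.params.branches
        assert branch[0][0].shape == (4, 8)  # n -> 2*d1
        assert branch[1][0].shape == (8, 4)  # 2*d1 -> 2*d2
        assert clf.params.W_y.shape == (4, 1)  # final representation 2*d2

    def test_single_branch_forward_matches_hand_computed_pass(self):
        params = NetParams(
            [
                [
                    (np.array([[1.0, -1.0], [0.5, 2.0]]), np.array([0.0, 1.0])),
                    (np.array([[1.0], [0.5]]), np.array([-0.5])),
                ]
            ],
            [],
            np.array([[2.0]]),
            np.array([0.0]),
        )
        x = np.array([2.0, 4.0])
        # layer 1: relu([2+2, -2+8+1]) = [4, 7]; layer 2: relu(4 + 3.5 - 0.5) = 7
        h, y_hat = forward(x, None, params)
        assert h[0] == pytest.approx(7.0)
        assert y_hat == pytest.approx(1.0 / (1.0 + math.exp(-14.0)))


class TestPredict:
    def test_degenerate_thresholds_flag_everyone_or_no_one(self, rng):
        from dualscreen.network import predict

        table, spec, labels = separable_dataset(rng, m=20)
        cfg = TrainConfig(d1=4, d2=2, epochs=5, seed=1)
        params = DualNetClassifier(cfg).fit(table, spec, labels).params
        _, all_pos = predict(table, spec, params, threshold=0.0)
        assert all_pos.sum() == 20
        _, all_neg = predict(table, spec, params, threshold=1.0 + 1e-9)
        assert all_neg.sum() == 0

    def test_batch_probabilities_match_row_by_row_forward(self, rng):
        from dualscreen.data import group_indices
        from dualscreen.network import predict

        table, spec, labels = separable_dataset(rng, m=10)
        cfg = TrainConfig(d1=4, d2=2, epochs=5, seed=2)
        params = DualNetClassifier(cfg).fit(table, spec, labels).params
        probs, _ = predict(table, spec, params)
        p_idx, q_idx = group_indices(table, spec)
        for i in range(10):
            _, one = forward(table.values[i, p_idx], table.values[i, q_idx], params)
            assert probs[i] == pytest.approx(one, abs=1e-12)


class TestFCLVariantAndSerialization:
    def test_variant_layer_count_matches_dims(self):
        assert FCLVariant.with_layers(2, d2=32).extra_dims == (64, 64)
        assert FCLVariant().extra_layers == 0
        with pytest.raises(Exception):
            FCLVariant.with_layers(3)

    def test_extra_layers_change_the_head_input_width(self, rng):
        params = init_params((3, 2), d1=4, d2=2, variant=FCLVariant((6,)), seed=0)
        assert params.extras[0][0].shape == (4, 6)
        assert params.W_y.shape == (6, 1)

    def test_save_load_round_trip(self, tmp_path, rng):
        table, spec, labels = separable_dataset(rng, m=20)
        cfg = TrainConfig(d1=4, d2=2, epochs=5, seed=2)
        clf = DualNetClassifier(cfg).fit(table, spec, labels)
        path = tmp_path / "model.npz"
        save_params(clf.params, cfg, str(path))
        params, loaded_cfg = load_params(str(path))
        for a, b in zip(params.flat(), clf.params.flat()):
            np.testing.assert_array_equal(a, b)
        assert loaded_cfg == cfg
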