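"""Plateau schedule, SGD, the training loop, and the metric suite."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import accuracy_score, precision_score, recall_score

from ercpnet import (NetworkConfig, SyntheticSpec, TrainConfig, build_network,
                     compute_confusion, compute_metrics,
                     generate_synthetic_dataset, plateau_step, train)
from ercpnet.autodiff import Parameter, Tensor
from ercpnet.training import LRSchedulerState, SGD


class TestPlateauSchedule:
    def test_three_stale_epochs_decay_lr(self):
        cfg = TrainConfig()
        state = LRSchedulerState(current_lr=0.01)
        state = plateau_step(state, 0.5, cfg)      # first epoch sets the best
        for _ in range(3):
            state = plateau_step(state, 0.5, cfg)  # no strict improvement
        assert state.current_lr == pytest.approx(0.3 * 0.01)
        assert state.epochs_since_improvement == 0

    def test_monotone_improvement_never_decays(self):
        cfg = TrainConfig()
        state = LRSchedulerState(current_lr=0.01)
        for acc in np.linspace(0.1, 0.9, 10):
            state = plateau_step(state, float(acc), cfg)
        assert state.current_lr == 0.01

    def test_improvement_resets_counter(self):
        cfg = TrainConfig()
        state = LRSchedulerState(current_lr=0.01)
        state = plateau_step(state, 0.5, cfg)
        state = plateau_step(state, 0.5, cfg)
        state = plateau_step(state, 0.5, cfg)
        assert state.epochs_since_improvement == 2
        state = plateau_step(state, 0.6, cfg)      # improvement on epoch 2 stale
        assert state.epochs_since_improvement == 0
        assert state.current_lr == 0.01

    def test_lr_floor(self):
        cfg = TrainConfig()
        state = LRSchedulerState(current_lr=1e-8, best_val_accuracy=1.0)
        for _ in range(3):
            state = plateau_step(state, 0.0, cfg)
        assert state.current_lr == 1e-8

    def test_invalid_accuracy_rejected(self):
        with pytest.raises(ValueError):
            plateau_step(LRSchedulerState(0.01), 1.5, TrainConfig())


class TestSGDStep:
    def test_single_step_matches_analytic_gradient(self):
        # quadratic toy: L(p) = (p - 3)^2, dL/dp = 2(p - 3)
        p = Parameter(np.array([2.0]))
        opt = SGD([p], lr=0.1, momentum=0.0, weight_decay=0.0)
        loss = (p - Tensor(np.array([3.0]))) ** 2
        loss.backward()
        opt.step()
        assert p.data[0] == pytest.approx(2.0 - 0.1 * 2 * (2.0 - 3.0))

    def test_weight_decay_adds_l2_pull(self):
        p = Parameter(np.array([2.0]))
        opt = SGD([p], lr=0.1, momentum=0.0, weight_decay=0.5)
        p.grad = np.array([0.0])
        opt.step()
        assert p.data[0] == pytest.approx(2.0 - 0.1 * 0.5 * 2.0)

    def test_momentum_accumulates_velocity(self):
        p = Parameter(np.array([0.0]))
        opt = SGD([p], lr=1.0, momentum=0.5)
        p.grad = np.array([1.0])
        opt.step()   # v=1, p=-1
        p.grad = np.array([1.0])
        opt.step()   # v=1.5, p=-2.5
        assert p.data[0] == pytest.approx(-2.5)


def tiny_training_setup(epochs, seed=3):
    ds = generate_synthetic_dataset(
        SyntheticSpec(num_classes=2, per_class=6, image_size=32, seed=1))
    cfg = NetworkConfig(variant="ercp_net", stem_width=4, num_classes=2,
                        input_size=32, seed=seed)
    return build_network(cfg), ds, TrainConfig(epochs=epochs, seed=seed, batch_size=6)


class TestTrainLoop:
    def test_zero_epochs_is_a_no_op(self):
        net, ds, cfg = tiny_training_setup(epochs=0)
        before = [p.data.copy() for p in net.parameters()]
        _, history = train(net, ds, ds, cfg)
        assert history == []
        for p, b in zip(net.parameters(), before):
            np.testing.assert_array_equal(p.data, b)

    def test_same_seed_gives_identical_history(self):
        net1, ds, cfg = tiny_training_setup(epochs=2)
        _, h1 = train(net1, ds, ds, cfg)
        net2, _, _ = tiny_training_setup(epochs=2)
        _, h2 = train(net2, ds, ds, cfg)
        assert h1 == h2

    def test_lr_nonincreasing_and_changes_only_by_decay_factor(self):
        net, ds, cfg = tiny_training_setup(epochs=8)
        _, history = train(net, ds, ds, cfg)
        lrs = [h["lr"] for h in history]
        for a, b in zip(lrs, lrs[1:]):
            assert b <= a
            assert b == a or b == pytest.approx(a * cfg.lr_decay_factor)

    def test_empty_training_set_rejected(self):
        net, ds, cfg = tiny_training_setup(epochs=1)
        with pytest.raises(ValueError, match="empty"):
            train(net, ds.subset([]), ds, cfg)

    def test_nonfinite_loss_aborts_with_diagnostic(self):
        net, ds, cfg = tiny_training_setup(epochs=1)
        net.fc.weight.data[...] = np.inf
        with pytest.raises(FloatingPointError, match="non-finite"):
            train(net, ds, ds, cfg)

    def test_label_space_mismatch_rejected(self):
        net, ds, cfg = tiny_training_setup(epochs=1)
        bad = generate_synthetic_dataset(
            SyntheticSpec(num_classes=3, per_class=3, image_size=32, seed=2))
        with pytest.raises(ValueError, match="class count"):
            train(net, bad, bad, cfg)


class TestConfusionMatrix:
    def test_hand_counted_example(self):
        cm = compute_confusion([0, 1, 1, 1], [0, 0, 1, 1], num_classes=2)
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 2]])

    def test_perfect_predictions_are_diagonal(self, rng):
        labels = rng.integers(0, 5, size=40)
        cm = compute_confusion(labels, labels, num_classes=5)
        assert cm.counts.trace() == 40
        assert (cm.counts - np.diag(np.diag(cm.counts)) == 0).all()

    def test_empty_inputs_give_zero_matrix(self):
        cm = compute_confusion([], [], num_classes=3)
        assert cm.total == 0
        assert (cm.counts == 0).all()

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            compute_confusion([0, 3], [0, 1], num_classes=2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            compute_confusion([0, 1], [0], num_classes=2)


class TestMetrics:
    def test_diagonal_matrix_is_perfect(self):
        cm = compute_confusion([0, 1, 2], [0, 1, 2], num_classes=3)
        rep = compute_metrics(cm)
        assert rep.accuracy == 1.0
        np.testing.assert_array_equal(rep.per_class_precision, 1.0)
        np.testing.assert_array_equal(rep.per_class_recall, 1.0)

    def test_hand_arithmetic_example(self):
        from ercpnet.training import ConfusionMatrix
        rep = compute_metrics(ConfusionMatrix(np.array([[8, 2], [2, 8]])))
        assert rep.accuracy == pytest.approx(0.8)
        np.testing.assert_allclose(rep.per_class_precision, [0.8, 0.8])
        np.testing.assert_allclose(rep.per_class_recall, [0.8, 0.8])

    def test_degenerate_class_flagged_with_zero(self):
        from ercpnet.training import ConfusionMatrix
        rep = compute_metrics(ConfusionMatrix(np.array([[5, 0], [0, 0]])))
        assert rep.per_class_recall[1] == 0.0
        assert rep.degenerate_recall_classes == [1]

    def test_zero_total_rejected(self):
        from ercpnet.training import ConfusionMatrix
        with pytest.raises(ValueError, match="empty"):
            compute_metrics(ConfusionMatrix(np.zeros((2, 2), dtype=np.int64)))

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 7))
        n = int(rng.integers(5, 60))
        labels = rng.integers(0, k, size=n)
        preds = rng.integers(0, k, size=n)
        rep = compute_metrics(compute_confusion(preds, labels, k))
        assert rep.accuracy == pytest.approx(accuracy_score(labels, preds))
        assert rep.macro_precision == pytest.approx(
            precision_score(labels, preds, average="macro",
                            labels=range(k), zero_division=0))
        assert rep.macro_recall == pytest.approx(
            recall_score(labels, preds, average="macro",
                         labels=range(k), zero_division=0))

    def test_macro_metrics_invariant_under_class_relabeling(self, rng):
        from ercpnet.training import ConfusionMatrix
        counts = rng.integers(0, 20, size=(5, 5))
        counts[0, 0] += 1  # ensure non-empty
        rep = compute_metrics(ConfusionMatrix(counts))
        perm = rng.permutation(5)
        rep_p = compute_metrics(ConfusionMatrix(counts[np.ix_(perm, perm)]))
        assert rep.macro_precision == pytest.approx(rep_p.macro_precision)
        assert rep.macro_recall == pytest.approx(rep_p.macro_recall)
        assert rep.accuracy == pytest.approx(rep_p.accuracy)
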