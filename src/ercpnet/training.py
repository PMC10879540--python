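"""Training loop, plateau learning-rate schedule, and evaluation metrics.

The optimizer is SGD with momentum and weight decay on a cross-entropy loss
(defaults: batch 16, initial learning rate 0.01, momentum 0.9, weight decay
1e-4).  Validation accuracy is monitored after every epoch; when it fails to
improve for `patience_epochs` consecutive epochs the learning rate is
multiplied by `lr_decay_factor` (0.3 by default) and the stall counter
resets.

Metrics follow the one-vs-rest reduction of a KxK confusion matrix:
accuracy = trace/total, per-class precision = TP/(TP+FP) and recall =
TP/(TP+FN), macro values are unweighted class means.  Zero denominators
yield 0 and the class is flagged as degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, cross_entropy_logits
from .data import AugmentConfig, LabeledImageSet, augment_image
from .network import Network

__all__ = ["TrainConfig", "LRSchedulerState", "plateau_step", "SGD", "train",
           "evaluate", "predict_labels", "ConfusionMatrix", "compute_confusion",
           "MetricsReport", "compute_metrics"]

LR_FLOOR = 1e-8


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    init_lr: float = 0.01
    epochs: int = 100
    momentum: float = 0.9
    weight_decay: float = 1e-4
    lr_decay_factor: float = 0.3
    patience_epochs: int = 3
    seed: int = 0
    augment: AugmentConfig | None = None

    def __post_init__(self):
        if self.batch_size < 1 or self.init_lr <= 0:
            raise ValueError("batch_size and init_lr must be positive")
        if self.momentum < 0 or self.weight_decay < 0:
            raise ValueError("momentum and weight_decay must be non-negative")
        if self.epochs < 0 or self.patience_epochs < 1:
            raise ValueError("epochs must be >= 0 and patience_epochs >= 1")
        if not (0 < self.lr_decay_factor < 1):
            raise ValueError("lr_decay_factor must lie in (0, 1)")


@dataclass
class LRSchedulerState:
    current_lr: float
    best_val_accuracy: float = -np.inf
    epochs_since_improvement: int = 0


def plateau_step(state: LRSchedulerState, val_accuracy: float,
                 config: TrainConfig) -> LRSchedulerState:
    """Update the plateau schedule with this epoch's validation accuracy.

    A strict improvement over the best-so-far resets the stall counter;
    otherwise the counter increments, and on reaching the patience the
    learning rate is multiplied by the decay factor (floored at 1e-8) and
    the counter resets.
    """
    if not (0.0 <= val_accuracy <= 1.0):
        raise ValueError("val_accuracy must lie in [0, 1]")
    if val_accuracy > state.best_val_accuracy:
        return LRSchedulerState(state.current_lr, val_accuracy, 0)
    stalled = state.epochs_since_improvement + 1
    if stalled >= config.patience_epochs:
        new_lr = max(state.current_lr * config.lr_decay_factor, LR_FLOOR)
        return LRSchedulerState(new_lr, state.best_val_accuracy, 0)
    return LRSchedulerState(state.current_lr, state.best_val_accuracy, stalled)


class SGD:
    """Momentum SGD with decoupled-from-nothing classic L2 weight decay."""

    def __init__(self, params: list, lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _forward_batch_probs(net: Network, images: np.ndarray,
                         batch_size: int = 32) -> np.ndarray:
    outs = []
    for start in range(0, len(images), batch_size):
        outs.append(net(Tensor(images[start:start + batch_size])))
    return np.concatenate(outs, axis=0)


def predict_labels(net: Network, dataset: LabeledImageSet,
                   batch_size: int = 32) -> np.ndarray:
    was_training = net.training
    net.eval()
    probs = _forward_batch_probs(net, dataset.images(), batch_size)
    if was_training:
        net.train()
    return probs.argmax(axis=1)


def evaluate(net: Network, dataset: LabeledImageSet, batch_size: int = 32) -> float:
    """Accuracy of the network on a dataset, in evaluation mode."""
    preds = predict_labels(net, dataset, batch_size)
    return float((preds == dataset.labels()).mean())


def train(net: Network, train_set: LabeledImageSet, val_set: LabeledImageSet,
          config: TrainConfig) -> tuple:
    """Mini-batch SGD training with the plateau schedule.

    Returns (net, history) where history is a list of per-epoch dicts with
    keys epoch, train_loss, train_accuracy, val_accuracy, lr.  Data order,
    augmentation and everything downstream are driven by config.seed.
    """
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    for ds in (train_set, val_set):
        if ds.labels().max(initial=0) >= net.num_classes:
            raise ValueError("dataset labels exceed the network's class count")
    rng = np.random.default_rng(config.seed)
    opt = SGD(net.parameters(), config.init_lr, config.momentum, config.weight_decay)
    sched = LRSchedulerState(current_lr=config.init_lr)
    images = train_set.images()
    labels = train_set.labels()
    history = []
    for epoch in range(config.epochs):
        net.train()
        order = rng.permutation(len(images))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = images[idx]
            if config.augment is not None:
                batch = np.stack([augment_image(im, config.augment, rng) for im in batch])
            logits = net.forward_logits(Tensor(batch))
            loss = cross_entropy_logits(logits, labels[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.lr = sched.current_lr
            opt.step()
            losses.append(float(loss.data))
        train_acc = evaluate(net, train_set)
        val_acc = evaluate(net, val_set) if len(val_set) else train_acc
        sched = plateau_step(sched, val_acc, config)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "train_accuracy": train_acc, "val_accuracy": val_acc,
                        "lr": sched.current_lr})
    return net, history


# ---------------------------------------------------------------------- #
#  Confusion matrix and metrics
# ---------------------------------------------------------------------- #
@dataclass
class ConfusionMatrix:
    """KxK counts; rows index the true class, columns the predicted class."""

    counts: np.ndarray

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def compute_confusion(predictions, labels, num_classes: int) -> ConfusionMatrix:
    predictions = np.asarray(predictions, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    for name, arr in (("predictions", predictions), ("labels", labels)):
        if arr.size and (arr.min() < 0 or arr.max() >= num_classes):
            raise ValueError(f"{name} contain values outside [0, {num_classes})")
    counts = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(counts, (labels, predictions), 1)
    return ConfusionMatrix(counts)


@dataclass
class MetricsReport:
    accuracy: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    macro_precision: float
    macro_recall: float
    degenerate_precision_classes: list = field(default_factory=list)
    degenerate_recall_classes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy,
                "per_class_precision": self.per_class_precision.tolist(),
                "per_class_recall": self.per_class_recall.tolist(),
                "macro_precision": self.macro_precision,
                "macro_recall": self.macro_recall,
                "degenerate_precision_classes": self.degenerate_precision_classes,
                "degenerate_recall_classes": self.degenerate_recall_classes}


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, per-class one-vs-rest precision/recall, macro averages.

    A zero denominator (no predictions for a class, or no true members)
    yields 0 for that class and the class index is flagged.
    """
    counts = cm.counts
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    k = cm.num_classes
    tp = np.diag(counts).astype(np.float64)
    col = counts.sum(axis=0).astype(np.float64)
    row = counts.sum(axis=1).astype(np.float64)
    precision = np.where(col > 0, tp / np.maximum(col, 1), 0.0)
    recall = np.where(row > 0, tp / np.maximum(row, 1), 0.0)
    return MetricsReport(
        accuracy=float(tp.sum() / cm.total),
        per_class_precision=precision,
        per_class_recall=recall,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        degenerate_precision_classes=[int(i) for i in np.flatnonzero(col == 0)],
        degenerate_recall_classes=[int(i) for i in np.flatnonzero(row == 0)],
    )
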