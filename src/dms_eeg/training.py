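"""Optimisation protocol: Adam + validation-monitored LR plateau schedule.

The model is trained with categorical cross-entropy and Adam starting at
3e-4.  Validation accuracy is monitored each epoch; after ``patience``
epochs without improvement the learning rate is halved, never below the
1e-4 floor.  Trials are split into training and validation sets with a
stratified 0.3 hold-out, batches of 8, and the checkpoint with the best
validation accuracy (earliest epoch on ties) is returned as the final
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.random import default_rng

from . import autodiff as ad
from .backbone import ModelState


@dataclass(frozen=True)
class TrainConfig:
    lr_init: float = 3e-4
    lr_min: float = 1e-4
    lr_factor: float = 0.5
    patience: int = 10
    batch_size: int = 8
    val_fraction: float = 0.3
    max_epochs: int = 100
    seed: int = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if not (0 < self.lr_min <= self.lr_init):
            raise ValueError("require 0 < lr_min <= lr_init")
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.batch_size < 1 or self.patience < 1:
            raise ValueError("batch_size and patience must be >= 1")
        if not (0 < self.lr_factor < 1):
            raise ValueError("lr_factor must lie in (0, 1)")


@dataclass
class TrainHistory:
    """Per-epoch training record."""

    loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = 0.0

    def n_epochs(self) -> int:
        return len(self.loss)

    def to_rows(self) -> list[dict]:
        return [{"epoch": i, "loss": self.loss[i],
                 "train_acc": self.train_accuracy[i],
                 "val_acc": self.val_accuracy[i],
                 "lr": self.learning_rate[i]}
                for i in range(self.n_epochs())]


def split_train_val(labels: np.ndarray, val_fraction: float,
                    seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Stratified hold-out split; returns (train_idx, val_idx).

    Each class contributes round(n_class * val_fraction) trials to the
    validation set; the split is disjoint, exhaustive and deterministic
    given the seed.
    """
    labels = np.asarray(labels)
    rng = default_rng(seed)
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 trials")
        idx = rng.permutation(idx)
        n_val = int(round(idx.size * val_fraction))
        n_val = min(max(n_val, 1), idx.size - 1)
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return (np.sort(np.concatenate(train_idx)),
            np.sort(np.concatenate(val_idx)))


def cross_entropy_loss(probabilities: np.ndarray, labels: np.ndarray,
                       eps: float = 1e-7) -> float:
    """Mean -log p(true class), natural log, with an epsilon clamp."""
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=np.intp)
    if p.ndim != 2 or p.shape[0] != y.shape[0]:
        raise ValueError("probabilities must be (n, k) matching n labels")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    picked = np.clip(p[np.arange(y.size), y], eps, 1.0)
    return float(-np.log(picked).mean())


class PlateauScheduler:
    """ReduceLROnPlateau on validation accuracy.

    After ``patience`` consecutive epochs without a new best accuracy the
    learning rate is multiplied by ``lr_factor`` and clamped at ``lr_min``;
    the stale counter resets on improvement or on reduction.
    """

    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg
        self.lr = cfg.lr_init
        self.best = -np.inf
        self.stale = 0

    def update(self, val_accuracy: float) -> float:
        if val_accuracy > self.best:
            self.best = val_accuracy
            self.stale = 0
        else:
            self.stale += 1
            if self.stale >= self.cfg.patience:
                self.lr = max(self.lr * self.cfg.lr_factor, self.cfg.lr_min)
                self.stale = 0
        return self.lr


def reduce_lr_on_plateau(val_accuracies, cfg: TrainConfig) -> float:
    """Replay a validation-accuracy history, return the resulting LR."""
    sched = PlateauScheduler(cfg)
    lr = cfg.lr_init
    for acc in val_accuracies:
        lr = sched.update(float(acc))
    return lr


def lr_trace(val_accuracies, cfg: TrainConfig) -> list[float]:
    """Per-epoch learning rate produced by a validation-accuracy history."""
    sched = PlateauScheduler(cfg)
    return [sched.update(float(a)) for a in val_accuracies]


class Adam:
    """Adam optimiser over a flat parameter list."""

    def __init__(self, params, cfg: TrainConfig):
        self.params = list(params)
        self.cfg = cfg
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2, eps = self.cfg.adam_beta1, self.cfg.adam_beta2, self.cfg.adam_eps
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data -= lr * m_hat / (np.sqrt(v_hat) + eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _accuracy(model: ModelState, X: np.ndarray, y: np.ndarray,
              batch: int = 32) -> float:
    correct = 0
    for lo in range(0, X.shape[0], batch):
        probs = model.forward(X[lo:lo + batch])
        correct += int((np.argmax(probs, axis=1) == y[lo:lo + batch]).sum())
    return correct / X.shape[0]


def train_model(model: ModelState, X: np.ndarray, y: np.ndarray,
                cfg: TrainConfig,
                split: tuple[np.ndarray, np.ndarray] | None = None,
                ) -> tuple[ModelState, TrainHistory]:
    """Train on encoded features; return (best-epoch model, history).

    ``X`` is (n, n_bins, n_frames, n_channels); ``y`` holds integer class
    indices.  The stratified split is drawn from ``cfg.seed`` unless an
    explicit (train_idx, val_idx) pair is given.  The weights restored into
    the returned model are those of the epoch with the highest validation
    accuracy, earliest epoch winning ties.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.intp)
    if X.shape[0] != y.shape[0]:
        raise ValueError("feature/label count mismatch")
    if split is None:
        train_idx, val_idx = split_train_val(y, cfg.val_fraction, cfg.seed)
    else:
        train_idx, val_idx = (np.asarray(split[0]), np.asarray(split[1]))
    if train_idx.size == 0 or val_idx.size == 0:
        raise ValueError("empty train or validation set")
    Xtr, ytr = X[train_idx], y[train_idx]
    Xva, yva = X[val_idx], y[val_idx]

    history = TrainHistory()
    if cfg.max_epochs == 0:
        return model, history

    rng = default_rng(cfg.seed + 1)
    optimiser = Adam(model.params, cfg)
    scheduler = PlateauScheduler(cfg)
    lr = cfg.lr_init
    best_weights = model.get_weights()
    best_acc, best_epoch = -np.inf, -1

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(Xtr.shape[0])
        losses = []
        n_correct = 0
        for lo in range(0, order.size, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            optimiser.zero_grad()
            logits = model.logits(Xtr[idx])
            loss, probs = ad.softmax_cross_entropy(logits, ytr[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; aborting")
            loss.backward()
            optimiser.step(lr)
            losses.append(float(loss.data))
            n_correct += int((np.argmax(probs, axis=1) == ytr[idx]).sum())
        val_acc = _accuracy(model, Xva, yva)
        history.loss.append(float(np.mean(losses)))
        history.train_accuracy.append(n_correct / order.size)
        history.val_accuracy.append(val_acc)
        history.learning_rate.append(lr)
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_weights = model.get_weights()
        lr = scheduler.update(val_acc)

    history.best_epoch = best_epoch
    history.best_val_accuracy = float(best_acc)
    model.set_weights(best_weights)
    return model, history
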