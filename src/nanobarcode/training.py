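"""Supervised training of the pixel classifier.

The labeled pixel dataset is split 80%/10%/10% into training, validation
and hold-out test partitions (stratified per class).  Every time the
optimizer accesses a training batch, channel intensities are multiplied by
independent uniform draws from a contrast range (default [0.5, 1.5]) so the
classifier also covers lower signal-to-noise acquisitions.  Optimization is
AdamW on the mean negative log-likelihood with a step-decayed learning rate
(initial 5e-4, factor 0.9 every 20 epochs) and early stopping on validation
accuracy; the returned model is the best-validation-epoch checkpoint.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .masking import PixelDataset
from .network import AdamW, ResidualClassifier, nll_loss


@dataclass
class TrainConfig:
    learning_rate: float = 5e-4
    decay_factor: float = 0.9
    decay_every: int = 20
    batch_size: int = 458
    max_epochs: int = 100
    split_fractions: tuple[float, float, float] = (0.80, 0.10, 0.10)
    contrast_range: tuple[float, float] = (0.5, 1.5)
    early_stop_patience: int = 10
    weight_decay: float = 1e-2
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        lo, hi = self.contrast_range
        if not (0 < lo <= hi):
            raise ValueError("contrast range bounds must be positive with lo <= hi")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "train_accuracy", "val_accuracy", "lr"])
            for e in range(self.n_epochs):
                w.writerow([e, self.train_loss[e], self.train_accuracy[e],
                            self.val_accuracy[e], self.learning_rate[e]])


def split_dataset(
    ds: PixelDataset,
    fractions: Sequence[float] = (0.80, 0.10, 0.10),
    seed: int = 0,
) -> tuple[PixelDataset, PixelDataset, PixelDataset]:
    """Stratified disjoint train/validation/test partition of a pixel dataset.

    Per class, validation and test sizes are rounded to the nearest integer
    (error at most 1 per class) and the remainder trains.  Classes with
    fewer than 3 members cannot be stratified: they are assigned wholly to
    the training partition with a warning.
    """
    if len(ds) == 0:
        raise ValueError("dataset is empty")
    f_train, f_val, f_test = fractions
    if min(fractions) < 0 or abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    tr_idx, va_idx, te_idx = [], [], []
    for cls in np.unique(ds.labels):
        idx = np.flatnonzero(ds.labels == cls)
        if len(idx) < 3:
            warnings.warn(
                f"class {cls} has {len(idx)} member(s); cannot stratify, assigned to train"
            )
            tr_idx.append(idx)
            continue
        idx = rng.permutation(idx)
        n_val = int(round(f_val * len(idx)))
        n_test = int(round(f_test * len(idx)))
        va_idx.append(idx[:n_val])
        te_idx.append(idx[n_val:n_val + n_test])
        tr_idx.append(idx[n_val + n_test:])
    cat = lambda parts: np.sort(np.concatenate(parts)) if parts else np.array([], dtype=int)
    return ds.subset(cat(tr_idx)), ds.subset(cat(va_idx)), ds.subset(cat(te_idx))


def augment_contrast(
    batch: np.ndarray,
    contrast_range: tuple[float, float] = (0.5, 1.5),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Stochastic per-entry contrast scaling of a feature batch.

    Each (sample, channel) entry is multiplied by an independent uniform
    draw from the range; the input array is left unmodified.
    """
    lo, hi = contrast_range
    if not (0 < lo <= hi):
        raise ValueError("contrast range bounds must be positive with lo <= hi")
    if rng is None:
        rng = np.random.default_rng()
    batch = np.asarray(batch)
    factors = rng.uniform(lo, hi, size=batch.shape)
    return (batch * factors).astype(batch.dtype)


def learning_rate_at(epoch: int, cfg: TrainConfig) -> float:
    """Step-decayed rate: initial * factor ** floor(epoch / decay_every)."""
    return cfg.learning_rate * cfg.decay_factor ** (epoch // cfg.decay_every)


def _accuracy(model: ResidualClassifier, features, labels, chunk: int = 16384) -> float:
    correct = 0
    for i in range(0, len(features), chunk):
        logits = model.forward_logits(features[i : i + chunk], train=False)
        correct += int((logits.argmax(axis=1) == labels[i : i + chunk]).sum())
    return correct / len(features)


def train(
    model: ResidualClassifier,
    splits: tuple[PixelDataset, PixelDataset, PixelDataset] | tuple[PixelDataset, PixelDataset],
    cfg: TrainConfig = TrainConfig(),
) -> tuple[ResidualClassifier, TrainingHistory]:
    """Mini-batch AdamW training with augmentation, decay and early stopping.

    Returns the model restored to its best-validation-accuracy checkpoint,
    along with the full per-epoch history.  A non-finite loss aborts the
    run; the last finite checkpoint is preserved.
    """
    train_ds, val_ds = splits[0], splits[1]
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("train and validation splits must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.params(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    history = TrainingHistory()
    best_val, best_state, since_best = -np.inf, model.get_state(), 0

    for epoch in range(cfg.max_epochs):
        lr = learning_rate_at(epoch, cfg)
        opt.lr = lr
        order = rng.permutation(len(train_ds))
        losses, correct = [], 0
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            x = train_ds.features[sel]
            if cfg.augment:
                x = augment_contrast(x, cfg.contrast_range, rng)
            y = train_ds.labels[sel]
            probs = model.predict_proba(x, train=True, cache=True)
            loss = nll_loss(probs, y)
            if not np.isfinite(loss):
                history.stop_reason = f"non-finite loss at epoch {epoch}"
                model.set_state(best_state)
                history.best_epoch = int(np.argmax(history.val_accuracy)) if history.val_accuracy else -1
                return model, history
            losses.append(loss)
            correct += int((probs.argmax(axis=1) == y).sum())
            # d(loss)/d(logits) for mean NLL under softmax
            g = probs.copy()
            g[np.arange(len(y)), y] -= 1.0
            model.backward((g / len(y)).astype(np.float32))
            opt.step()
        # augmented batches inflate the tracked normalization statistics;
        # recalibrate on clean training data before any inference-mode use
        model.refresh_norm_statistics(train_ds.features, seed=cfg.seed)
        val_acc = _accuracy(model, val_ds.features, val_ds.labels)
        history.train_loss.append(float(np.mean(losses)))
        history.train_accuracy.append(correct / len(order))
        history.val_accuracy.append(val_acc)
        history.learning_rate.append(lr)
        if val_acc > best_val:
            best_val, best_state, since_best = val_acc, model.get_state(), 0
            history.best_epoch = epoch
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                history.stop_reason = "early stop: validation accuracy plateaued"
                break
    else:
        history.stop_reason = "max epochs reached"

    model.set_state(best_state)
    return model, history


def evaluate_holdout(model: ResidualClassifier, test: PixelDataset):
    """Score argmax predictions on the hold-out partition.

    Ties in the probability vector resolve to the lowest class index (the
    behavior of argmax).  Returns a full :class:`~nanobarcode.evaluation.MetricsReport`.
    """
    from .evaluation import compute_metrics, confusion_from_pairs

    if len(test) == 0:
        raise ValueError("test split is empty")
    if test.labels.max() >= model.config.n_classes:
        raise ValueError("test labels outside the model's class registry")
    preds = np.concatenate([
        model.forward_logits(test.features[i : i + 16384], train=False).argmax(axis=1)
        for i in range(0, len(test), 16384)
    ])
    confusion = confusion_from_pairs(test.labels, preds, model.config.n_classes)
    return compute_metrics(confusion, class_names=model.class_names)
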