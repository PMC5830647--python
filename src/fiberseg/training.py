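"""Training loop: spatially-weighted cross-entropy, Adam, scheduled decay.

The loss is a 3-class cross-entropy where each pixel's contribution is
multiplied by a class weight (defaults 1.1 / 1.0 / 1.3 for background /
myelin / axon, correcting class imbalance).  The learning rate follows a
polynomial decay ``lr0 * (1 - t/T_total)^0.9`` over a decay length of 200
epochs; batch-norm momentum is scheduled from 0.7 toward 0.9 by an
exponential approach ``0.9 - 0.2 * exp(-5 e / T)``, so early epochs average
statistics over few batches (faster convergence) while late epochs are
stable.  Patches are shuffled each epoch, augmented on the fly, normalized,
and consumed in batches of 8; the checkpoint with the lowest validation
loss is kept.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .augmentation import AugmentationSpec, augment
from .engine import Adam
from .imagery import PatchSet, normalize_patch
from .network import UNet, save_model

__all__ = [
    "TrainingConfig",
    "TrainingState",
    "weighted_cross_entropy",
    "loss_gradient",
    "lr_at",
    "bn_momentum_at",
    "train",
]


@dataclass
class TrainingConfig:
    """Hyperparameters of the training procedure (see module docstring)."""

    lr0: float = 0.001
    decay_power: float = 0.9
    decay_epochs: int = 200          # decay length T; training stops here
    batch_size: int = 8
    class_weights: tuple[float, float, float] = (1.1, 1.0, 1.3)
    dropout: float = 0.25
    bn_momentum_start: float = 0.7
    bn_momentum_end: float = 0.9
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    per_step_decay: bool = True      # decay per optimizer step; else per epoch
    epochs: int | None = None        # actual epochs to run (<= decay_epochs)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_weights) != 3 or any(w <= 0 for w in self.class_weights):
            raise ValueError("class_weights must be 3 positive values")
        if self.lr0 <= 0 or self.decay_epochs <= 0 or self.batch_size <= 0:
            raise ValueError("lr0, decay_epochs and batch_size must be positive")
        if self.epochs is None:
            self.epochs = self.decay_epochs

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        d = dict(d)
        if "class_weights" in d:
            d["class_weights"] = tuple(d["class_weights"])
        return cls(**d)


@dataclass
class TrainingState:
    """Per-epoch trace and best-validation bookkeeping."""

    history: list[dict] = field(default_factory=list)
    best_val_loss: float = np.inf
    best_epoch: int = -1
    checkpoint_dir: str | None = None

    def log(self, record: dict, stream=None) -> None:
        self.history.append(record)
        if stream is not None:
            print("\t".join(f"{record[k]:.6g}" if isinstance(record[k], float)
                            else str(record[k]) for k in record), file=stream)


def weighted_cross_entropy(probabilities: np.ndarray, mask: np.ndarray,
                           class_weights=(1.1, 1.0, 1.3)) -> float:
    """Mean over pixels of ``w[c] * (-log p_c)`` at the true class ``c``.

    Probabilities are floored at 1e-12 before the log.  With unit weights
    this reduces to the ordinary multi-class cross-entropy.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    mask = np.asarray(mask)
    if probabilities.ndim == 3:
        probabilities = probabilities[None]
    if mask.ndim == 2:
        mask = mask[None]
    if probabilities.shape[0] != mask.shape[0] or probabilities.shape[2:] != mask.shape[1:]:
        raise ValueError(
            f"probability shape {probabilities.shape} does not match mask {mask.shape}")
    w = np.asarray(class_weights, dtype=float)
    p_true = np.take_along_axis(probabilities, mask[:, None].astype(int), axis=1)[:, 0]
    return float(np.mean(w[mask] * -np.log(np.maximum(p_true, 1e-12))))


def loss_gradient(probabilities: np.ndarray, mask: np.ndarray,
                  class_weights=(1.1, 1.0, 1.3)) -> np.ndarray:
    """Gradient of :func:`weighted_cross_entropy` with respect to the logits
    (softmax and loss fused): ``w[c] * (p - onehot) / n_pixels``."""
    w = np.asarray(class_weights, dtype=probabilities.dtype)
    n_classes = probabilities.shape[1]
    onehot = np.eye(n_classes, dtype=probabilities.dtype)[mask].transpose(0, 3, 1, 2)
    return (probabilities - onehot) * w[mask][:, None] / np.asarray(mask.size, probabilities.dtype)


def lr_at(step: int, steps_per_epoch: int, cfg: TrainingConfig) -> float:
    """Polynomial decay ``lr0 * (1 - t/T_total)^p`` on the global step,
    clamped at 0 beyond the decay length."""
    total = cfg.decay_epochs * steps_per_epoch
    t = min(max(step, 0), total)
    return cfg.lr0 * (1.0 - t / total) ** cfg.decay_power


def bn_momentum_at(epoch: int, cfg: TrainingConfig) -> float:
    """Exponential approach from the start momentum to the end momentum:
    ``m(e) = end - (end - start) * exp(-5 e / T)``."""
    span = cfg.bn_momentum_end - cfg.bn_momentum_start
    return cfg.bn_momentum_end - span * np.exp(-5.0 * epoch / cfg.decay_epochs)


def _batches(items: list, size: int):
    for i in range(0, len(items), size):
        yield items[i:i + size]


def pixel_accuracy_from_probs(probs: np.ndarray, mask: np.ndarray) -> float:
    return float(np.mean(probs.argmax(axis=1) == mask))


def train(model: UNet, patchset: PatchSet, cfg: TrainingConfig,
          augmentation_spec: AugmentationSpec | None = None,
          checkpoint_dir: str | Path | None = None,
          log_file: str | Path | None = None,
          verbose: bool = False) -> TrainingState:
    """Run the epoch loop and return the training trace.

    Patches tagged ``train`` are augmented on the fly (validation patches are
    not), normalized, and fed in shuffled batches.  The model with the lowest
    validation loss is checkpointed to ``checkpoint_dir``.
    """
    train_pairs = patchset.subset("train")
    val_pairs = patchset.subset("validation")
    if not train_pairs or not val_pairs:
        raise ValueError("both train and validation splits must be non-empty")

    rng = np.random.default_rng(cfg.seed)
    model.rng = np.random.default_rng(rng.integers(2**31))
    optimizer = Adam(model.params(), cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps)
    steps_per_epoch = int(np.ceil(len(train_pairs) / cfg.batch_size))
    state = TrainingState(checkpoint_dir=str(checkpoint_dir) if checkpoint_dir else None)

    val_x = np.stack([normalize_patch(im) for im, _ in val_pairs])
    val_y = np.stack([ma for _, ma in val_pairs]).astype(int)
    if augmentation_spec is None:  # normalization is then epoch-invariant
        train_norm = [(normalize_patch(im), ma) for im, ma in train_pairs]

    log_fh = open(log_file, "w") if log_file else None
    header = ["epoch", "lr", "bn_momentum", "train_loss", "val_loss", "val_accuracy"]
    for fh in filter(None, [log_fh, sys.stderr if verbose else None]):
        print("\t".join(header), file=fh)

    step = 0
    try:
        for epoch in range(cfg.epochs):
            model.train()
            model.set_bn_momentum(float(bn_momentum_at(epoch, cfg)))
            order = rng.permutation(len(train_pairs))
            epoch_loss, n_batches = 0.0, 0
            for batch_idx in _batches(list(order), cfg.batch_size):
                xs, ys = [], []
                for i in batch_idx:
                    if augmentation_spec is not None:
                        im, ma = train_pairs[i]
                        im, ma = augment(im, ma, augmentation_spec, rng)
                        im = normalize_patch(im)
                    else:
                        im, ma = train_norm[i]
                    xs.append(im)
                    ys.append(ma)
                x = np.stack(xs)
                y = np.stack(ys).astype(int)
                probs = model.forward(x)
                loss = weighted_cross_entropy(probs, y, cfg.class_weights)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}, step {step}")
                optimizer.zero_grad()
                model.backward(loss_gradient(probs, y, cfg.class_weights))
                lr = lr_at(step if cfg.per_step_decay else epoch * steps_per_epoch,
                           steps_per_epoch, cfg)
                optimizer.step(lr)
                epoch_loss += loss
                n_batches += 1
                step += 1

            model.eval()
            val_losses, val_accs = [], []
            for batch in _batches(list(range(len(val_pairs))), cfg.batch_size):
                probs = model.forward(val_x[batch])
                val_losses.append(weighted_cross_entropy(probs, val_y[batch],
                                                         cfg.class_weights))
                val_accs.append(pixel_accuracy_from_probs(probs, val_y[batch]))
            record = {
                "epoch": epoch,
                "lr": lr,
                "bn_momentum": float(bn_momentum_at(epoch, cfg)),
                "train_loss": epoch_loss / n_batches,
                "val_loss": float(np.mean(val_losses)),
                "val_accuracy": float(np.mean(val_accs)),
            }
            state.log(record, stream=None)
            for fh in filter(None, [log_fh, sys.stderr if verbose else None]):
                print("\t".join(f"{record[k]:.6g}" if isinstance(record[k], float)
                                else str(record[k]) for k in header), file=fh)
            if record["val_loss"] < state.best_val_loss:
                state.best_val_loss = record["val_loss"]
                state.best_epoch = epoch
                if checkpoint_dir is not None:
                    save_model(model, checkpoint_dir)
    finally:
        if log_fh:
            log_fh.close()
    return state
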