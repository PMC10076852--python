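"""Training loop and evaluation pipeline.

The protocol: Adam at initial learning rate 0.001, combined BCE+Dice
loss, left-right/up-down flip augmentation, and an 8:2 train/test split.
The reference protocol trains with batch size 64 for 300 epochs; those
are the config defaults, and smaller profiles are used for CPU-scale
phantom experiments.  The checkpoint with the best validation F1 is
returned; a per-epoch log records the mean training loss and the
validation F1 so loss curves can be drawn.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .losses import combined_loss
from .metrics import MetricsReport, report_from_pairs
from .model import RADUNet, segment
from .nn import Adam, Tensor
from .phantom import PhantomSample
from .preprocess import random_flip


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the reference protocol)."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 300
    seed: int = 0
    augment: bool = True
    threshold: float = 0.5
    val_fraction: float = 0.15

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")


@dataclass
class TrainLog:
    """Per-epoch training record."""

    epoch_loss: list[float] = field(default_factory=list)
    val_f1: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_f1: float = -1.0


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def _stack_batch(samples: list[PhantomSample], augment: bool, rng: np.random.Generator):
    imgs, masks = [], []
    for s in samples:
        img, msk = (random_flip(s.image, s.mask, rng) if augment else (s.image, s.mask))
        imgs.append(img)
        masks.append(msk)
    x = np.stack(imgs)[:, None].astype(np.float32)
    y = np.stack(masks)[:, None].astype(np.float32)
    return x, y


def train(
    model: RADUNet,
    train_set: list[PhantomSample],
    cfg: TrainConfig,
    val_set: list[PhantomSample] | None = None,
) -> tuple[RADUNet, TrainLog]:
    """Optimize the model; returns the best-validation-F1 checkpoint and the log.

    If no validation set is given, ``val_fraction`` of the training set is
    held out (seed-deterministically).  Aborts with :class:`DivergenceError`
    if the loss becomes non-finite.
    """
    if not train_set:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)

    if val_set is None:
        n_val = max(1, int(round(len(train_set) * cfg.val_fraction))) if cfg.val_fraction > 0 else 0
        order = rng.permutation(len(train_set))
        val_set = [train_set[i] for i in order[:n_val]]
        train_set = [train_set[i] for i in order[n_val:]]
        if not train_set:
            raise ValueError("validation split consumed the whole training set")

    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    log = TrainLog()
    best_state = None
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_set[i] for i in order[start:start + cfg.batch_size]]
            x, y = _stack_batch(batch, cfg.augment, rng)
            optimizer.zero_grad()
            pred = model.forward(Tensor(x))
            loss = combined_loss(y, pred)
            value = float(loss.data)
            if not np.isfinite(value):
                raise DivergenceError(f"non-finite loss at epoch {epoch + 1}")
            loss.backward()
            optimizer.step()
            losses.append(value)
        log.epoch_loss.append(float(np.mean(losses)))

        if val_set:
            vf1 = evaluate(model, val_set, threshold=cfg.threshold).f1
        else:
            vf1 = -log.epoch_loss[-1]
        log.val_f1.append(vf1 if val_set else float("nan"))
        if vf1 > log.best_val_f1:
            log.best_val_f1 = vf1
            log.best_epoch = epoch
            best_state = copy.deepcopy(model.state_dict())

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, log


def evaluate(
    model: RADUNet,
    test_set: list[PhantomSample],
    threshold: float = 0.5,
    by_category: bool = True,
    include_background: bool = False,
) -> MetricsReport:
    """Segment every test image and accumulate the confusion-matrix metrics.

    Per-image IoU/recall/precision/F1 are averaged over the set; with
    ``by_category`` each image also contributes to the sub-report of its
    dominant lesion size class.
    """
    if not test_set:
        raise ValueError("empty test set")
    pairs = [(segment(model, s.image, threshold), s.mask) for s in test_set]
    categories = [s.dominant_category for s in test_set] if by_category else None
    return report_from_pairs(pairs, categories, include_background=include_background)
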