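"""k-fold training of the segmentation ensemble.

The dataset is split into k disjoint, near-equal folds (default k = 5).
One network is trained per fold on the other k−1 folds with Adam at an
initial learning rate of 0.001 decaying to 99.9% of its value each epoch;
the held-out fold is only ever *scored* — its loss is recorded per epoch but
never used for any optimisation or model-selection decision. The k models
together form the inference ensemble, and because each image sits in exactly
one fold, every image receives exactly one held-out prediction, giving
complete cross-validated coverage of the dataset.

Epochs, batch size and the loss function are configuration (defaults:
15 epochs, batch 4, mean per-class binary cross-entropy; a soft-Dice loss
is available as ``loss="dice"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import ClassMasks, ImageSample, InputError
from .nn import Adam, bce_with_logits, sigmoid
from .unet import (Ensemble, ProbabilityMaps, UNet, UNetConfig, build_unet,
                   ConfigurationError, predict_member)

Sample = tuple[ImageSample, ClassMasks]


@dataclass(frozen=True)
class TrainingConfig:
    initial_lr: float = 0.001
    lr_decay_per_epoch: float = 0.999
    epochs: int = 15
    batch_size: int = 4
    loss: str = "bce"  # or "dice"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.lr_decay_per_epoch <= 1:
            raise ConfigurationError("lr_decay_per_epoch must be in (0,1]")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be >= 1")
        if self.loss not in ("bce", "dice"):
            raise ConfigurationError(f"unknown loss {self.loss!r}")


@dataclass
class FoldAssignment:
    """Disjoint covering partition of image ids into k folds."""

    k: int
    fold_of: dict[str, int]

    def ids_in_fold(self, fold: int) -> list[str]:
        return [i for i, f in self.fold_of.items() if f == fold]

    def ids_not_in_fold(self, fold: int) -> list[str]:
        return [i for i, f in self.fold_of.items() if f != fold]


@dataclass
class LossHistory:
    train: list[float] = field(default_factory=list)
    heldout: list[float] = field(default_factory=list)


def make_folds(ids: Sequence[str], k: int = 5, seed: int = 0) -> FoldAssignment:
    """Seeded random partition into k disjoint folds with sizes within 1."""
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise InputError("duplicate ids in fold assignment")
    if len(ids) < k:
        raise ConfigurationError(f"need at least k={k} ids, got {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    fold_of: dict[str, int] = {}
    for fold, chunk in enumerate(np.array_split(perm, k)):
        for idx in chunk:
            fold_of[ids[idx]] = fold
    return FoldAssignment(k=k, fold_of=fold_of)


def lr_at_epoch(config: TrainingConfig, epoch: int) -> float:
    """Closed-form schedule: ``initial_lr × decay^epoch``."""
    if epoch < 0:
        raise ConfigurationError("epoch must be >= 0")
    return config.initial_lr * config.lr_decay_per_epoch**epoch


def _soft_dice_loss(logits: np.ndarray, targets: np.ndarray,
                    eps: float = 1.0) -> tuple[float, np.ndarray]:
    """Soft Dice loss per class, averaged; gradient w.r.t. logits."""
    p = sigmoid(logits)
    y = targets.astype(np.float64)
    axes = (0, 2, 3)
    inter = (p * y).sum(axis=axes)
    denom = (p + y).sum(axis=axes)
    dice = (2 * inter + eps) / (denom + eps)
    loss = float(1 - dice.mean())
    ddice_dp = (2 * y * (denom + eps)[None, :, None, None]
                - (2 * inter + eps)[None, :, None, None]) / \
        ((denom + eps) ** 2)[None, :, None, None]
    dloss_dp = -ddice_dp / dice.size
    grad = dloss_dp * p * (1 - p)
    return loss, grad.astype(np.float32)


def _as_arrays(samples: Sequence[Sample]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    xs, ys, ids = [], [], []
    shape = None
    for img, masks in samples:
        if img.pixels.shape != masks.shape:
            raise InputError(
                f"{img.id}: image shape {img.pixels.shape} does not match "
                f"mask shape {masks.shape}")
        if shape is None:
            shape = img.pixels.shape
        elif img.pixels.shape != shape:
            raise InputError("all training images must share one shape")
        xs.append(img.pixels.astype(np.float32))
        ys.append(np.stack([masks.rod, masks.ring]).astype(np.float32))
        ids.append(img.id)
    return np.stack(xs)[:, None], np.stack(ys), ids


def _epoch_loss(model: UNet, x: np.ndarray, y: np.ndarray,
                loss_name: str, batch: int) -> float:
    total, n = 0.0, 0
    loss_fn = bce_with_logits if loss_name == "bce" else _soft_dice_loss
    for s in range(0, len(x), batch):
        logits = model.forward(x[s:s + batch], train=False)
        loss, _ = loss_fn(logits, y[s:s + batch])
        total += loss * len(x[s:s + batch])
        n += len(x[s:s + batch])
    return total / max(n, 1)


def train_fold(train_samples: Sequence[Sample],
               heldout_samples: Sequence[Sample],
               unet_config: UNetConfig,
               training_config: TrainingConfig,
               *, member_seed: int | None = None,
               ) -> tuple[UNet, LossHistory]:
    """Train one network on the training folds; score (only) the held-out fold.

    Deterministic for a fixed ``(training_config.seed, member_seed)`` in
    single-threaded execution: initialisation, batch order and the optimiser
    all draw from seeded generators.
    """
    if len(train_samples) == 0:
        raise InputError("training set is empty")
    x, y, _ = _as_arrays(train_samples)
    xh = yh = None
    if len(heldout_samples):
        xh, yh, _ = _as_arrays(heldout_samples)

    seed = training_config.seed if member_seed is None else member_seed
    model = build_unet(unet_config, seed=seed)
    opt = Adam(model.params())
    shuffle_rng = np.random.default_rng([abs(int(seed)) + 1, 0xD1CE])
    loss_fn = bce_with_logits if training_config.loss == "bce" else _soft_dice_loss
    history = LossHistory()

    for epoch in range(training_config.epochs):
        lr = lr_at_epoch(training_config, epoch)
        order = shuffle_rng.permutation(len(x))
        epoch_total, seen = 0.0, 0
        for s in range(0, len(order), training_config.batch_size):
            idx = order[s:s + training_config.batch_size]
            opt.zero_grad()
            logits = model.forward(x[idx], train=True)
            loss, grad = loss_fn(logits, y[idx])
            model.backward(grad)
            opt.step(lr)
            epoch_total += loss * len(idx)
            seen += len(idx)
        history.train.append(epoch_total / seen)
        if xh is not None:
            history.heldout.append(
                _epoch_loss(model, xh, yh, training_config.loss,
                            training_config.batch_size))
        else:
            history.heldout.append(float("nan"))
    return model, history


def train_ensemble(dataset: Sequence[Sample], folds: FoldAssignment,
                   unet_config: UNetConfig, training_config: TrainingConfig,
                   ) -> tuple[Ensemble, dict[str, ProbabilityMaps],
                              list[LossHistory]]:
    """Train k members, one per fold, and collect held-out predictions.

    Member *f* trains on every fold except *f* and predicts fold *f*, so
    every image receives exactly one prediction from a model that never saw
    it — complete cross-validated coverage. Returns the assembled
    :class:`Ensemble`, the held-out :class:`ProbabilityMaps` keyed by image
    id, and the per-member loss histories.
    """
    by_id = {img.id: (img, masks) for img, masks in dataset}
    if len(by_id) != len(dataset):
        raise InputError("duplicate image ids in dataset")
    missing = set(folds.fold_of) - set(by_id)
    if missing or set(by_id) - set(folds.fold_of):
        raise InputError("fold assignment does not match dataset ids")

    members: list[UNet] = []
    heldout_maps: dict[str, ProbabilityMaps] = {}
    histories: list[LossHistory] = []
    for f in range(folds.k):
        train_ids = folds.ids_not_in_fold(f)
        test_ids = folds.ids_in_fold(f)
        model, hist = train_fold(
            [by_id[i] for i in train_ids], [by_id[i] for i in test_ids],
            unet_config, training_config,
            member_seed=(training_config.seed * 1000 + f) % (2**31 - 1))
        members.append(model)
        histories.append(hist)
        for i in test_ids:
            img, _ = by_id[i]
            heldout_maps[i] = predict_member(model, img.pixels, id=i)
    return Ensemble(members=members), heldout_maps, histories
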