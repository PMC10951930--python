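"""Cross-validation folds and MIL training with bag-level supervision.

Folds stratify jointly on the slide label and the colour-appearance
category, so each train/val/test partition preserves both distributions.
Training minimises the binary cross-entropy between each bag's predicted
probability and the slide label it inherits (the proxy ground truth), with
Adam, separate encoder/head learning rates, and early stopping on the
validation loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .bagbuild import augment_tile
from .milmodel import MILModel
from .nn import Adam, sigmoid
from .slideio import SlideRecord

__all__ = [
    "FoldAssignment",
    "TrainConfig",
    "BagItem",
    "stratified_folds",
    "bag_bce",
    "train_model",
    "evaluate_loss",
]

LABEL_TO_INT = {"mild": 0, "severe": 1}


@dataclass(frozen=True)
class FoldAssignment:
    """One fold's slide partition: every slide is train, val, or test."""

    fold_id: int
    partition: dict[str, str]  # slide_id -> {"train", "val", "test"}

    def ids(self, part: str) -> list[str]:
        return sorted(sid for sid, p in self.partition.items() if p == part)

    @property
    def train_ids(self) -> list[str]:
        return self.ids("train")

    @property
    def val_ids(self) -> list[str]:
        return self.ids("val")

    @property
    def test_ids(self) -> list[str]:
        return self.ids("test")


@dataclass
class TrainConfig:
    """Optimisation settings.

    The default learning rates are fine-tuning surrogates (a pretrained
    encoder adjusted gently, a fresh head trained faster); from-scratch
    training of the small reference encoder wants larger rates, set per
    experiment.
    """

    encoder_lr: float = 1e-5
    head_lr: float = 1e-4
    weight_decay: float = 1e-4
    batch_size_bags: int = 6
    max_epochs: int = 50
    patience: int = 10
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if min(self.encoder_lr, self.head_lr, self.weight_decay) < 0:
            raise ValueError("rates must be non-negative")
        if self.batch_size_bags < 1:
            raise ValueError("batch_size_bags must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class BagItem:
    """One training/eval sample: a bag's tile stack plus its proxy label."""

    bag_id: str
    slide_id: str
    label: int                     # 0 = mild, 1 = severe
    tiles: np.ndarray              # (k, 3, H, W) float in [-0.5, 0.5]


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation matching ``total`` with proportional quotas."""
    base = np.floor(quotas).astype(int)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(quotas - base), kind="stable")
        base[order[:short]] += 1
    return base


def stratified_folds(
    cohort: Sequence[SlideRecord], n_folds: int = 5, seed: int = 0,
    val_share: float = 0.10,
) -> list[FoldAssignment]:
    """Cross-validation folds stratified on (label x color_category).

    Test sets partition the cohort across folds (each close to 1/n_folds of
    the slides); within each fold the validation set — ``val_share`` of the
    whole cohort — is carved out of the non-test remainder with the same
    stratification, leaving the rest for training.  Deterministic for a
    fixed seed.
    """
    labels_present = {r.label for r in cohort}
    if len(labels_present) < 2:
        raise ValueError("cohort must contain both classes")
    rng = np.random.default_rng(seed)
    strata: dict[tuple[str, str], list[int]] = {}
    for i, rec in enumerate(cohort):
        strata.setdefault((rec.label, rec.color_category), []).append(i)

    # deal each stratum round-robin into test folds, rotating the starting
    # fold per stratum so remainders spread evenly
    test_idx: list[list[int]] = [[] for _ in range(n_folds)]
    for s_num, (key, idx) in enumerate(sorted(strata.items())):
        if len(idx) < n_folds:
            warnings.warn(
                f"stratum {key} has {len(idx)} slides (< {n_folds} folds); "
                "distributing as evenly as possible"
            )
        perm = rng.permutation(len(idx))
        for j, pi in enumerate(perm):
            test_idx[(j + s_num) % n_folds].append(idx[pi])

    n_val_total = round(val_share * len(cohort))
    folds = []
    for f in range(n_folds):
        test = set(test_idx[f])
        partition = {cohort[i].slide_id: "test" for i in test}
        # stratified validation split from the remainder
        rem_strata = [
            [i for i in idx if i not in test] for _, idx in sorted(strata.items())
        ]
        quotas = np.array(
            [n_val_total * len(rs) / max(1, len(cohort) - len(test)) for rs in rem_strata]
        )
        n_val = _largest_remainder(quotas, n_val_total)
        for rs, nv in zip(rem_strata, n_val):
            perm = rng.permutation(len(rs))
            chosen = {rs[p] for p in perm[:nv]}
            for i in rs:
                partition[cohort[i].slide_id] = "val" if i in chosen else "train"
        folds.append(FoldAssignment(fold_id=f + 1, partition=partition))
    return folds


def bag_bce(p: float, y: int) -> float:
    """Binary cross-entropy of one bag prediction, clamped for stability."""
    p = float(np.clip(p, 1e-7, 1.0 - 1e-7))
    return float(-(y * np.log(p) + (1 - y) * np.log(1.0 - p)))


def _augment_chw(tiles: np.ndarray, seed: int) -> np.ndarray:
    """Apply the seeded flip/rotation augmentation to a (k, 3, H, W) stack."""
    out = np.empty_like(tiles)
    for t in range(tiles.shape[0]):
        hwc = np.transpose(tiles[t], (1, 2, 0))
        out[t] = np.transpose(augment_tile(hwc, seed=seed + t), (2, 0, 1))
    return out


def evaluate_loss(model: MILModel, items: Sequence[BagItem], batch_size: int = 16) -> float:
    """Mean bag-level BCE over a set of bags (eval mode, no augmentation)."""
    if len(items) == 0:
        return float("nan")
    model.eval()
    total = 0.0
    for start in range(0, len(items), batch_size):
        chunk = items[start : start + batch_size]
        logits, _ = model.forward_batch([it.tiles for it in chunk])
        probs = sigmoid(logits)
        total += sum(bag_bce(p, it.label) for p, it in zip(probs, chunk))
    return total / len(items)


def train_model(
    train_items: Sequence[BagItem],
    val_items: Sequence[BagItem],
    model: MILModel,
    cfg: TrainConfig,
    augment: bool = False,
) -> tuple[MILModel, pd.DataFrame]:
    """Train a MIL model on bag items; returns the best-validation model.

    Bags referencing the same slide all carry the slide's proxy label; this
    is asserted at load.  Training stops once the validation loss has not
    improved for ``cfg.patience`` consecutive epochs, and the weights from
    the best-validation epoch are restored before returning.
    """
    if len(train_items) == 0:
        raise ValueError("empty training split")
    slide_labels: dict[str, int] = {}
    for it in list(train_items) + list(val_items):
        if slide_labels.setdefault(it.slide_id, it.label) != it.label:
            raise ValueError(f"conflicting proxy labels for slide {it.slide_id}")

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(
        [
            {"params": model.encoder_parameters(), "lr": cfg.encoder_lr},
            {"params": model.head_parameters(), "lr": cfg.head_lr},
        ],
        weight_decay=cfg.weight_decay,
    )
    best_val = float("inf")
    best_state = {k: v.copy() for k, v in model.state_dict().items()}
    epochs_no_improve = 0
    rows = []
    for epoch in range(1, cfg.max_epochs + 1):
        model.train()
        order = rng.permutation(len(train_items))
        train_loss = 0.0
        for start in range(0, len(order), cfg.batch_size_bags):
            batch_idx = order[start : start + cfg.batch_size_bags]
            arrays, labels = [], []
            for bi in batch_idx:
                item = train_items[bi]
                tiles = item.tiles
                if augment:
                    aug_seed = (cfg.seed * 1_000_003 + epoch * 8191 + int(bi) * 131) % (2**31)
                    tiles = _augment_chw(tiles, aug_seed)
                arrays.append(tiles)
                labels.append(item.label)
            y = np.asarray(labels, dtype=np.float64)
            logits, cache = model.forward_batch(arrays)
            probs = sigmoid(logits)
            batch_loss = float(np.mean([bag_bce(p, int(t)) for p, t in zip(probs, y)]))
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rates or check the input scaling"
                )
            train_loss += batch_loss * len(batch_idx)
            opt.zero_grad()
            model.backward_batch((probs - y) / len(batch_idx), cache)
            opt.step()
        train_loss /= len(train_items)
        val_loss = evaluate_loss(model, val_items)
        rows.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss,
             "encoder_lr": cfg.encoder_lr, "head_lr": cfg.head_lr}
        )
        monitored = val_loss if np.isfinite(val_loss) else train_loss
        if monitored < best_val:
            best_val = monitored
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
            epochs_no_improve = 0
        else:
            epochs_no_improve += 1
            if epochs_no_improve >= cfg.patience:
                break
    model.load_state_dict(best_state)
    model.eval()
    return model, pd.DataFrame(rows)
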