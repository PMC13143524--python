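"""Training protocol: weighted cross-entropy, early stopping, k-fold runs.

The optimization recipe is fixed by the study design: Adam (lr 1e-4,
default betas), batch size 16, at most 50 epochs, early stopping with
patience 10 monitored on validation loss, and per-fold checkpointing of
the weights with the best validation macro-F1 (previous checkpoints are
deleted).  Normalization statistics are computed from each fold's
training split only; validation preprocessing is deterministic (resize +
normalize, no augmentation).

The class-imbalance correction is the normalized inverse-frequency
weighted cross-entropy

    L = -(1/N) sum_n w_{y_n} log( exp(z_{n,y_n}) / sum_c exp(z_{n,c}) )

with w_c = N / (N_c * C).  Division is by the batch size N exactly (not
by the summed weights), so with unit weights the loss is the ordinary
mean cross-entropy.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .colorspace import (
    MultiColorImage,
    NormalizationStats,
    augment,
    compute_norm_stats,
    decompose_and_normalize,
    load_rgb,
)
from .data import DatasetManifest, FoldSplit, compute_class_weights, stratified_kfold
from .evaluation import EvalReport, evaluate_predictions
from .model import CSFNetModel, ModelConfig, build_variant, save_checkpoint
from .nn.attention import softmax
from .nn.layers import F32
from .nn.optim import Adam

logger = logging.getLogger("ocufusion")


@dataclass
class TrainConfig:
    epochs_max: int = 50
    batch_size: int = 16
    learning_rate: float = 1e-4
    early_stop_patience: int = 10  # monitored on validation loss
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs_max, self.batch_size, self.early_stop_patience) <= 0:
            raise ValueError("all training hyper-parameters must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        # patience never exceeds the epoch budget
        self.early_stop_patience = min(self.early_stop_patience, self.epochs_max)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def weighted_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Weighted cross-entropy loss and its gradient w.r.t. the logits.

    Returns ``(loss, dlogits)``.  Raises on non-finite logits.
    """
    logits = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite logits passed to the loss")
    labels = np.asarray(labels, dtype=np.int64)
    weights = np.asarray(weights, dtype=np.float64)
    if labels.min() < 0 or labels.max() >= weights.size:
        raise ValueError("labels out of range for the given weight vector")
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    logp = logits - np.log(np.exp(logits - logits.max(axis=1, keepdims=True)).sum(axis=1, keepdims=True)) - logits.max(axis=1, keepdims=True)
    w = weights[labels]
    loss = float(-(w * logp[np.arange(n), labels]).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (w / n)[:, None]
    return loss, grad.astype(F32)


# ---------------------------------------------------------------------------
# early stopping / checkpoint bookkeeping
# ---------------------------------------------------------------------------

class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without a strictly lower
    validation loss (min_delta 0)."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.stale = 0

    def update(self, val_loss: float) -> bool:
        """Record one epoch; returns True when training should stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


class BestCheckpoint:
    """Keep only the weights with the highest validation macro-F1.

    The best state is always held in memory (so the previous checkpoint
    is implicitly discarded); with a directory it is also written to
    ``<tag>_best.npz``, replacing the previous file.
    """

    def __init__(self, directory: str | Path | None, tag: str):
        self.directory = Path(directory) if directory is not None else None
        self.tag = tag
        self.best_f1 = -np.inf
        self.best_epoch: int | None = None
        self.state: dict[str, np.ndarray] | None = None
        self.path: Path | None = None

    def update(self, f1: float, model: CSFNetModel, stats: NormalizationStats,
               epoch: int) -> bool:
        if f1 <= self.best_f1:
            return False
        self.best_f1 = f1
        self.best_epoch = epoch
        self.state = {k: v.copy() for k, v in model.state_dict().items()}
        if self.directory is not None:
            self.directory.mkdir(parents=True, exist_ok=True)
            self.path = self.directory / f"{self.tag}_best.npz"
            save_checkpoint(model, self.path, norm_stats=stats,
                            extra={"epoch": epoch, "val_macro_f1": float(f1)})
        return True

    def restore(self, model: CSFNetModel) -> None:
        if self.state is not None:
            model.load_state_dict(self.state)


@dataclass
class TrainRunState:
    """Per-epoch history of one fold's training run."""

    history: list[dict] = field(default_factory=list)
    best_f1: float = -np.inf
    best_checkpoint: Path | None = None
    stopped_early: bool = False
    epochs_run: int = 0
    checkpointer: "BestCheckpoint | None" = None

    def log_epoch(self, row: dict) -> None:
        self.history.append(row)
        self.epochs_run = len(self.history)
        self.best_f1 = max(self.best_f1, row.get("val_macro_f1", -np.inf))

    def to_csv(self, path: str | Path) -> None:
        if not self.history:
            return
        keys = list(self.history[0].keys())
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=keys)
            w.writeheader()
            w.writerows(self.history)


# ---------------------------------------------------------------------------
# data loading helpers
# ---------------------------------------------------------------------------

class FoldData:
    """Materialized train/validation arrays for one fold.

    Validation planes are precomputed once (deterministic preprocessing);
    training images are kept as raw RGB and re-augmented every epoch.
    """

    def __init__(
        self,
        manifest: DatasetManifest,
        train_idx: np.ndarray,
        val_idx: np.ndarray,
        image_size: int,
        stats: NormalizationStats,
    ):
        if len(train_idx) == 0 or len(val_idx) == 0:
            raise ValueError("empty train or validation split")
        self.image_size = image_size
        self.stats = stats
        labels = manifest.labels
        paths = manifest.filepaths
        self.train_rgb = [load_rgb(paths[i]) for i in train_idx]
        self.train_labels = labels[train_idx]
        self.val_labels = labels[val_idx]
        val_planes = [
            decompose_and_normalize(load_rgb(paths[i]), stats, size=image_size)
            for i in val_idx
        ]
        self.val_batch = _stack_planes(val_planes)

    def train_epoch_batches(self, batch_size: int, rng: np.random.Generator,
                            augment_train: bool = True):
        order = rng.permutation(len(self.train_rgb))
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            planes = []
            for i in idx:
                img = self.train_rgb[i].astype(np.float32)
                if augment_train:
                    img = augment(img, rng)
                planes.append(
                    decompose_and_normalize(img, self.stats, size=self.image_size)
                )
            yield _stack_planes(planes), self.train_labels[idx]


def _stack_planes(items: list[MultiColorImage]) -> dict[str, np.ndarray]:
    return {
        s: np.stack([getattr(it, s) for it in items]).astype(F32)
        for s in ("rgb", "hsv", "ycbcr")
    }


def _eval_in_batches(model: CSFNetModel, batch: dict[str, np.ndarray],
                     batch_size: int = 32) -> np.ndarray:
    n = batch["rgb"].shape[0]
    outs = []
    for start in range(0, n, batch_size):
        sub = {k: v[start : start + batch_size] for k, v in batch.items()}
        outs.append(model.forward(sub, training=False))
    return np.concatenate(outs, axis=0)


# ---------------------------------------------------------------------------
# fold training
# ---------------------------------------------------------------------------

def train_fold(
    model: CSFNetModel,
    fold_data: FoldData,
    config: TrainConfig,
    class_weights: np.ndarray,
    out_dir: str | Path | None = None,
    fold_tag: str = "fold0",
    augment_train: bool = True,
) -> TrainRunState:
    """Optimize one fold; returns the epoch history.

    Stops early after ``early_stop_patience`` epochs without validation
    loss improvement and checkpoints whenever validation macro-F1
    improves (if ``out_dir`` is given).
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 101)))
    model.set_rng(rng)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    stopper = EarlyStopper(config.early_stop_patience)
    ckpt = BestCheckpoint(out_dir, fold_tag)
    state = TrainRunState()
    state.checkpointer = ckpt

    for epoch in range(1, config.epochs_max + 1):
        train_losses = []
        for batch, labels in fold_data.train_epoch_batches(
            config.batch_size, rng, augment_train=augment_train
        ):
            logits = model.forward(batch, training=True)
            loss, dlogits = weighted_cross_entropy(logits, labels, class_weights)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} ({fold_tag})"
                )
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
            train_losses.append(loss)

        val_logits = _eval_in_batches(model, fold_data.val_batch)
        val_loss, _ = weighted_cross_entropy(
            val_logits, fold_data.val_labels, class_weights
        )
        report = evaluate_predictions(
            fold_data.val_labels, softmax(val_logits, axis=1)
        )
        row = {
            "epoch": epoch,
            "train_loss": round(float(np.mean(train_losses)), 6),
            "val_loss": round(float(val_loss), 6),
            "val_accuracy": round(report.accuracy, 6),
            "val_macro_precision": round(report.macro_precision, 6),
            "val_macro_recall": round(report.macro_recall, 6),
            "val_macro_f1": round(report.macro_f1, 6),
        }
        state.log_epoch(row)
        logger.info(
            "%s epoch %d train_loss %.4f val_loss %.4f val_f1 %.4f",
            fold_tag, epoch, row["train_loss"], row["val_loss"], row["val_macro_f1"],
        )
        if ckpt.update(report.macro_f1, model, fold_data.stats, epoch):
            state.best_checkpoint = ckpt.path
        if stopper.update(val_loss):
            state.stopped_early = True
            break
    return state


# ---------------------------------------------------------------------------
# cross-validation driver
# ---------------------------------------------------------------------------

def run_cross_validation(
    manifest: DatasetManifest,
    model_config: ModelConfig,
    train_config: TrainConfig,
    k: int = 5,
    out_dir: str | Path | None = None,
    split: FoldSplit | None = None,
    augment_train: bool = True,
    restore_best: bool = True,
) -> list[EvalReport]:
    """Stratified k-fold training and evaluation.

    For each fold: compute normalization statistics on the training split,
    re-initialize the model from scratch, train with early stopping, then
    evaluate the checkpointed best weights on the validation split.
    Returns one :class:`EvalReport` per fold.
    """
    if split is None:
        split = stratified_kfold(manifest, k=k, seed=train_config.seed)
    weights = compute_class_weights(manifest)
    reports: list[EvalReport] = []
    paths = manifest.filepaths
    for f, (train_idx, val_idx) in enumerate(split.folds):
        stats = compute_norm_stats(
            [paths[i] for i in train_idx],
            computed_from=f"fold{f}/train",
            size=model_config.image_size,
        )
        fold_dir = Path(out_dir) / f"fold{f}" if out_dir is not None else None
        if fold_dir is not None:
            fold_dir.mkdir(parents=True, exist_ok=True)
            stats.to_json(fold_dir / "norm_stats.json")
        fold_data = FoldData(manifest, train_idx, val_idx, model_config.image_size, stats)
        cfg = ModelConfig(**{
            **model_config.__dict__, "init_seed": train_config.seed + f
        })
        model = build_variant(cfg.variant, cfg)
        state = train_fold(
            model, fold_data, train_config, weights,
            out_dir=fold_dir, fold_tag=f"fold{f}", augment_train=augment_train,
        )
        if fold_dir is not None:
            state.to_csv(fold_dir / "metrics.csv")
        if restore_best and state.checkpointer is not None:
            state.checkpointer.restore(model)
        probs = softmax(_eval_in_batches(model, fold_data.val_batch), axis=1)
        report = evaluate_predictions(fold_data.val_labels, probs, fold=f)
        reports.append(report)
        if fold_dir is not None:
            report.to_csv(fold_dir / "eval_report.csv")
    return reports
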