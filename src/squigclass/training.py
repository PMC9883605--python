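"""Training protocol: read-level splits, k-fold CV, LR schedule, early stop.

Splits are stratified by class and performed at read level so that sibling
segments of one read never straddle a train/validation boundary. Training
runs for at most ``max_epochs``, monitors validation binary accuracy,
halves the learning rate after ``lr_patience_epochs`` epochs without
improvement, and stops early after ``early_stop_patience_epochs``. The
weights from the best-validation epoch are restored when a fold finishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import Classifier
from .nn import bce_with_logits

__all__ = [
    "TrainConfig",
    "SegmentData",
    "FoldResult",
    "TrainingDivergedError",
    "ReduceLROnPlateau",
    "EarlyStopping",
    "split_train_val",
    "make_folds",
    "train_fold",
    "cross_validate",
    "select_best_model",
    "write_run_log",
]

#: metric improvements below this do not reset plateau/early-stop counters
MIN_DELTA = 1e-4


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training."""


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults follow the standard protocol
    (5 folds, 7:3 split, 1000-read batches, 200 epochs, LR x0.5 after a
    20-epoch plateau of validation binary accuracy, early stop after 30)."""

    n_folds: int = 5
    train_fraction: float = 0.7
    batch_reads: int = 1000
    max_epochs: int = 200
    lr_factor: float = 0.5
    lr_patience_epochs: int = 20
    early_stop_patience_epochs: int = 30
    initial_lr: float = 1e-3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must be in (0, 1)")
        if self.early_stop_patience_epochs < 1:
            raise ValueError("early_stop_patience_epochs must be >= 1")
        for name in ("n_folds", "batch_reads", "max_epochs", "lr_patience_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class SegmentData:
    """Preprocessed segments with per-segment labels and parent read ids."""

    X: np.ndarray          # (n_segments, segment_length) float32
    y: np.ndarray          # (n_segments,) {0,1}
    read_ids: np.ndarray   # (n_segments,) parent read of each segment

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.read_ids = np.asarray(self.read_ids)
        if not (len(self.X) == len(self.y) == len(self.read_ids)):
            raise ValueError("X, y and read_ids must have equal length")

    def __len__(self) -> int:
        return len(self.X)

    def subset_by_reads(self, reads: set[str]) -> "SegmentData":
        mask = np.isin(self.read_ids, list(reads))
        return SegmentData(self.X[mask], self.y[mask], self.read_ids[mask])

    def unique_reads(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique read ids and the (per-read) label of each."""
        ids, first = np.unique(self.read_ids, return_index=True)
        return ids, self.y[first]


@dataclass
class FoldResult:
    fold_index: int
    model: Classifier
    history: dict[str, list] = field(default_factory=dict)
    best_val_acc: float = 0.0
    best_epoch: int = 0


class ReduceLROnPlateau:
    """Multiply the optimizer LR by ``factor`` after ``patience`` epochs
    without a > MIN_DELTA improvement of the monitored metric (mode: max)."""

    def __init__(self, optimizer, factor: float, patience: int):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.best = -np.inf
        self.wait = 0

    def step(self, metric: float) -> None:
        if metric > self.best + MIN_DELTA:
            self.best = metric
            self.wait = 0
        else:
            self.wait += 1
            if self.wait >= self.patience:
                self.optimizer.lr *= self.factor
                self.wait = 0


class EarlyStopping:
    """Signal a stop after ``patience`` epochs without improvement (max)."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = -np.inf
        self.wait = 0

    def step(self, metric: float) -> bool:
        """Record an epoch's metric; return True when training should stop."""
        if metric > self.best + MIN_DELTA:
            self.best = metric
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience


def _stratified_read_split(
    data: SegmentData, train_fraction: float, seed: int
) -> tuple[set[str], set[str]]:
    ids, labels = data.unique_reads()
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("both classes must be present to split")
    rng = np.random.default_rng(seed)
    train: set[str] = set()
    val: set[str] = set()
    for c in classes:
        members = ids[labels == c]
        members = members[rng.permutation(members.size)]
        n_train = int(round(train_fraction * members.size))
        train.update(members[:n_train])
        val.update(members[n_train:])
    return train, val


def split_train_val(
    data: SegmentData, train_fraction: float = 0.7, seed: int = 0
) -> tuple[SegmentData, SegmentData]:
    """Read-level stratified split (default 7:3); deterministic given seed."""
    train, val = _stratified_read_split(data, train_fraction, seed)
    return data.subset_by_reads(train), data.subset_by_reads(val)


def make_folds(
    data: SegmentData, n_folds: int = 5, seed: int = 0
) -> list[tuple[SegmentData, SegmentData]]:
    """Stratified k-fold at read level: validation sets are disjoint,
    exhaustive, class-balanced, and deterministic given the seed."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    ids, labels = data.unique_reads()
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("both classes must be present to make folds")
    rng = np.random.default_rng(seed)
    val_sets: list[set[str]] = [set() for _ in range(n_folds)]
    for c in classes:
        members = ids[labels == c]
        if members.size < n_folds:
            raise ValueError(
                f"class {c} has {members.size} reads, fewer than {n_folds} folds"
            )
        members = members[rng.permutation(members.size)]
        for i, rid in enumerate(members):
            val_sets[i % n_folds].add(rid)
    all_reads = set(ids)
    return [
        (data.subset_by_reads(all_reads - vs), data.subset_by_reads(vs))
        for vs in val_sets
    ]


def _epoch_eval(model: Classifier, data: SegmentData, batch: int) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(data), batch):
        Xb, yb = data.X[i : i + batch], data.y[i : i + batch]
        z = model.forward_logits(Xb, training=False)
        loss, _ = bce_with_logits(z, yb)
        losses.append(loss * len(yb))
        correct += int(np.sum((z >= 0) == (yb == 1)))
    return float(np.sum(losses) / len(data)), correct / len(data)


def train_fold(
    model: Classifier,
    train: SegmentData,
    val: SegmentData,
    cfg: TrainConfig,
    segments_per_read: int = 4,
    fold_index: int = 0,
) -> FoldResult:
    """Train one fold under the plateau-LR / early-stopping protocol.

    A training batch holds ``batch_reads`` reads' worth of segments
    (``batch_reads * segments_per_read`` rows). Validation binary accuracy
    is the monitored metric for both the LR schedule and early stopping;
    the best-epoch weights are restored before returning.
    """
    rng = np.random.default_rng(cfg.rng_seed + 7919 * fold_index)
    model.reseed_dropout(cfg.rng_seed + 104729 * (fold_index + 1))
    opt = model.make_optimizer(cfg.initial_lr)
    scheduler = ReduceLROnPlateau(opt, cfg.lr_factor, cfg.lr_patience_epochs)
    stopper = EarlyStopping(cfg.early_stop_patience_epochs)
    batch = max(1, cfg.batch_reads * segments_per_read)

    history: dict[str, list] = {
        k: [] for k in ("epoch", "lr", "train_loss", "train_acc", "val_loss", "val_acc")
    }
    result = FoldResult(fold_index, model, history)
    best_state = model.copy_state()
    best_acc, best_epoch = -np.inf, 0

    n = len(train)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss, correct = 0.0, 0
        for i in range(0, n, batch):
            idx = order[i : i + batch]
            Xb, yb = train.X[idx], train.y[idx]
            z = model.forward_logits(Xb, training=True)
            loss, dz = bce_with_logits(z, yb)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"fold {fold_index}: non-finite loss at epoch {epoch}"
                )
            opt.zero_grad()
            model.backward(dz)
            opt.step()
            epoch_loss += loss * len(yb)
            correct += int(np.sum((z >= 0) == (yb == 1)))
        val_loss, val_acc = _epoch_eval(model, val, batch)
        history["epoch"].append(epoch)
        history["lr"].append(opt.lr)
        history["train_loss"].append(epoch_loss / n)
        history["train_acc"].append(correct / n)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)

        if val_acc > best_acc + MIN_DELTA:
            best_acc, best_epoch = val_acc, epoch
            best_state = model.copy_state()
        scheduler.step(val_acc)
        if stopper.step(val_acc):
            break

    model.restore_state(best_state)
    result.best_val_acc = float(max(best_acc, 0.0))
    result.best_epoch = best_epoch
    return result


def cross_validate(
    model_factory,
    data: SegmentData,
    cfg: TrainConfig,
    segments_per_read: int = 4,
) -> list[FoldResult]:
    """Run k-fold CV; ``model_factory(fold_index)`` builds a fresh model."""
    folds = make_folds(data, cfg.n_folds, cfg.rng_seed)
    results = []
    for f, (train, val) in enumerate(folds):
        model = model_factory(f)
        results.append(train_fold(model, train, val, cfg, segments_per_read, f))
    return results


def select_best_model(fold_results: list[FoldResult]) -> FoldResult:
    """Fold with the highest best-validation accuracy; ties -> lowest index."""
    if not fold_results:
        raise ValueError("no fold results to select from")
    return max(fold_results, key=lambda r: (r.best_val_acc, -r.fold_index))


def write_run_log(path, fold_results: list[FoldResult], cfg: TrainConfig) -> None:
    """Tab-separated per-epoch log with the config echoed as a header."""
    with open(path, "w") as fh:
        for key, value in vars(cfg).items():
            fh.write(f"# {key}\t{value}\n")
        fh.write("fold\tepoch\tlr\ttrain_loss\ttrain_acc\tval_loss\tval_acc\n")
        for r in fold_results:
            h = r.history
            for i in range(len(h["epoch"])):
                fh.write(
                    f"{r.fold_index}\t{h['epoch'][i]}\t{h['lr'][i]:.6g}\t"
                    f"{h['train_loss'][i]:.6f}\t{h['train_acc'][i]:.6f}\t"
                    f"{h['val_loss'][i]:.6f}\t{h['val_acc'][i]:.6f}\n"
                )
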