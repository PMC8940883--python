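"""Volume-wise splitting, class weighting, SGD training and cross-validation.

Splits are made at the OCT-volume level so that frames from one volume never
appear on both sides of a train/evaluation boundary; this is asserted (not
just arranged) on every training call, and violating it raises
:class:`LeakageError`.

Training follows the fixed recipe: SGD (momentum 0.9, learning rate 5e-4),
batch size 32, class-weighted categorical cross-entropy with L2 weight decay,
augmentation on training frames only, and early stopping that restores the
weights of the epoch with the lowest validation loss once the loss has not
reached a new strict minimum for ``patience_epochs`` consecutive epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import frames as frames_mod
from .core import (
    CLASS_ORDER,
    DegenerateClassError,
    FrameRecord,
    LeakageError,
    SplitError,
    TissueClass,
    logger,
    records_as_arrays,
    stage_seed,
)
from .model import AttentionResNet, ModelConfig, build_model, predict_proba
from .nn import SGD, weighted_cross_entropy


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 0.0005
    momentum: float = 0.9
    l2_coefficient: float = 1e-4
    patience_epochs: int = 10
    max_epochs: int = 200
    augment_probability: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience_epochs < 1:
            raise ValueError("patience_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0.0 <= self.augment_probability <= 1.0):
            raise ValueError("augment_probability must be in [0, 1]")


@dataclass
class SplitPlan:
    """Fold assignment keyed by volume id; holdout volumes are never folded."""

    fold_of_volume: dict
    holdout_volumes: list

    def __post_init__(self) -> None:
        overlap = set(self.fold_of_volume) & set(self.holdout_volumes)
        if overlap:
            raise SplitError(f"volumes in both folds and holdout: {sorted(overlap)}")
        folds = set(self.fold_of_volume.values())
        for k in range(max(folds, default=-1) + 1):
            if k not in folds:
                raise SplitError(f"fold {k} is empty")

    @property
    def n_folds(self) -> int:
        return len(set(self.fold_of_volume.values()))

    def volumes_in_fold(self, k: int) -> list:
        return sorted(v for v, f in self.fold_of_volume.items() if f == k)

    def training_volumes_for_fold(self, k: int) -> list:
        return sorted(v for v, f in self.fold_of_volume.items() if f != k)


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    best_epoch: int = 0  # 1-based

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, len(self.train_loss) + 1),
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "val_accuracy": self.val_accuracy,
        })


class EarlyStopping:
    """Stop when the monitored loss has not made a new strict minimum for
    ``patience`` consecutive epochs; remembers the best (1-based) epoch."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.epoch = 0
        self.stale = 0

    def update(self, loss: float) -> bool:
        """Record one epoch's loss; returns True when training should stop."""
        self.epoch += 1
        if loss < self.best:
            self.best = loss
            self.best_epoch = self.epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


# ---------------------------------------------------------------------------
# Splitting and class weights
# ---------------------------------------------------------------------------

def split_by_volume(manifest: pd.DataFrame, n_folds: int = 5, seed: int = 0) -> SplitPlan:
    """Stratified volume-level fold assignment; ``split_hint == 'test'`` rows
    go to the holdout pool. Requires >= n_folds training volumes per class."""
    if "split_hint" in manifest.columns:
        train = manifest[manifest["split_hint"] != "test"]
        holdout = list(manifest.loc[manifest["split_hint"] == "test", "volume_id"])
    else:
        train, holdout = manifest, []
    rng = np.random.default_rng(seed)
    fold_of_volume: dict = {}
    for label in CLASS_ORDER:
        vols = sorted(train.loc[train["label"] == label, "volume_id"].unique())
        if 0 < len(vols) < n_folds:
            raise SplitError(
                f"class {label}: {len(vols)} training volumes < {n_folds} folds"
            )
        rng.shuffle(vols)
        for i, v in enumerate(vols):
            fold_of_volume[v] = i % n_folds
    return SplitPlan(fold_of_volume, holdout)


def compute_class_weights(frame_counts: dict) -> dict:
    """Inverse-frequency weights: w_c = N_total / (n_classes * N_c).

    With the study's training frame counts (14,517 / 9,698 / 4,854 for
    NOR / GBM / PCNSL) this yields (0.667, 0.999, 1.996).
    """
    counts = {}
    for k, v in frame_counts.items():
        key = k if isinstance(k, TissueClass) else TissueClass.from_string(str(k))
        counts[key] = int(v)
    for cls, n in counts.items():
        if n <= 0:
            raise DegenerateClassError(f"class {cls.value} has no frames")
    total = sum(counts.values())
    n_classes = len(counts)
    return {cls: total / (n_classes * n) for cls, n in counts.items()}


def class_weight_vector(weights: dict) -> np.ndarray:
    return np.array([weights[TissueClass(c)] for c in CLASS_ORDER])


def assert_no_leakage(train_vids, eval_vids, context: str = "train/val") -> None:
    shared = set(train_vids) & set(eval_vids)
    if shared:
        raise LeakageError(
            f"volume ids present in both sides of the {context} split: {sorted(shared)}"
        )


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _augment_batch(x: np.ndarray, rng: np.random.Generator, probability: float,
                   params: frames_mod.AugmentParams) -> np.ndarray:
    if probability <= 0:
        return x
    out = x.copy()
    for i in range(len(out)):
        if rng.random() < probability:
            frame = frames_mod.BScanFrame(out[i, :, :, 0].astype(np.float64),
                                          frames_mod.STANDARD_DEPTH_MM, 5.0)
            aug = frames_mod.augment(frame, int(rng.integers(0, 2**31)), params)
            out[i, :, :, 0] = np.clip(aug.pixels, 0.0, 1.0)
    return out


def evaluate_loss_accuracy(model: AttentionResNet, x: np.ndarray, y: np.ndarray,
                           weights: np.ndarray | None, batch_size: int = 32
                           ) -> tuple[float, float]:
    losses, hits, n = [], 0, len(x)
    for i in range(0, n, batch_size):
        logits = model.forward(x[i:i + batch_size], training=False)
        loss, _ = weighted_cross_entropy(logits, y[i:i + batch_size], weights)
        losses.append(loss * len(logits))
        hits += int(np.sum(np.argmax(logits, axis=1) == y[i:i + batch_size]))
    return float(np.sum(losses) / n), hits / n


def train_classifier(model: AttentionResNet, train_records: list[FrameRecord],
                     val_records: list[FrameRecord], config: TrainConfig,
                     class_weights: dict | None = None,
                     augment_params: frames_mod.AugmentParams | None = None,
                     ) -> tuple[AttentionResNet, TrainHistory]:
    """Train with the fixed SGD recipe and early stopping on validation loss."""
    x_tr, y_tr, vids_tr = records_as_arrays(train_records)
    x_va, y_va, vids_va = records_as_arrays(val_records)
    assert_no_leakage(vids_tr, vids_va)

    if class_weights is None:
        counts = {c: max(int(np.sum(y_tr == i)), 1) for i, c in enumerate(CLASS_ORDER)}
        class_weights = compute_class_weights(counts)
    wvec = class_weight_vector(class_weights)
    aug_params = augment_params if augment_params is not None else frames_mod.AugmentParams()

    optimizer = SGD(model.params(), config.learning_rate, config.momentum,
                    config.l2_coefficient)
    stopper = EarlyStopping(config.patience_epochs)
    history = TrainHistory()
    best_state = model.get_state()
    n = len(x_tr)

    for epoch in range(1, config.max_epochs + 1):
        rng = np.random.default_rng(stage_seed(config.seed, f"epoch{epoch}"))
        order = rng.permutation(n)
        epoch_losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            xb = _augment_batch(x_tr[idx], rng, config.augment_probability, aug_params)
            model.zero_grad()
            logits = model.forward(xb, training=True)
            loss, dlogits = weighted_cross_entropy(logits, y_tr[idx], wvec)
            model.backward(dlogits)
            optimizer.step()
            epoch_losses.append(loss * len(idx))
        val_loss, val_acc = evaluate_loss_accuracy(model, x_va, y_va, wvec,
                                                   config.batch_size)
        history.train_loss.append(float(np.sum(epoch_losses) / n))
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        logger.info("epoch %3d  train %.4f  val %.4f  acc %.3f",
                    epoch, history.train_loss[-1], val_loss, val_acc)
        stop = stopper.update(val_loss)
        if stopper.best_epoch == epoch:
            best_state = model.get_state()
        if stop:
            break
    model.set_state(best_state)
    history.best_epoch = stopper.best_epoch
    return model, history


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    histories: list
    fold_accuracies: list      # frame-level accuracy on each fold's validation set
    holdout_accuracies: list   # each fold model evaluated on the untouched holdout
    mean_accuracy: float
    sd_accuracy: float
    models: list


def summarize_accuracies(accuracies) -> tuple[float, float]:
    a = np.asarray(list(accuracies), dtype=float)
    sd = float(np.std(a, ddof=1)) if len(a) > 1 else 0.0
    return float(np.mean(a)), sd


def run_cross_validation(records: list[FrameRecord], plan: SplitPlan,
                         model_config: ModelConfig, train_config: TrainConfig,
                         holdout_records: list[FrameRecord] | None = None,
                         keep_models: bool = False) -> CVResult:
    """Fivefold (in general, n-fold) volume-wise cross-validation.

    Fold k's model trains on all other folds and validates on fold k; every
    fold model is additionally evaluated on the untouched holdout records.
    """
    holdout_records = holdout_records or []
    by_vid: dict = {}
    for r in records:
        by_vid.setdefault(r.volume_id, []).append(r)
    unknown = set(by_vid) - set(plan.fold_of_volume)
    if unknown:
        raise SplitError(f"records reference volumes missing from the plan: {sorted(unknown)}")
    histories, models = [], []
    fold_acc, holdout_acc = [], []
    if holdout_records:
        x_ho, y_ho, vids_ho = records_as_arrays(holdout_records)
    for k in range(plan.n_folds):
        tr_vids = plan.training_volumes_for_fold(k)
        va_vids = plan.volumes_in_fold(k)
        assert_no_leakage(tr_vids, va_vids, context=f"fold {k}")
        assert_no_leakage(tr_vids, plan.holdout_volumes, context=f"fold {k}/holdout")
        tr = [r for v in tr_vids for r in by_vid.get(v, [])]
        va = [r for v in va_vids for r in by_vid.get(v, [])]
        model = build_model(model_config, seed=stage_seed(train_config.seed, f"fold{k}"))
        model, hist = train_classifier(model, tr, va, train_config)
        histories.append(hist)
        x_va, y_va, _ = records_as_arrays(va)
        _, acc = evaluate_loss_accuracy(model, x_va, y_va, None, train_config.batch_size)
        fold_acc.append(acc)
        if holdout_records:
            assert_no_leakage(tr_vids, vids_ho, context=f"fold {k}/holdout frames")
            _, h_acc = evaluate_loss_accuracy(model, x_ho, y_ho, None,
                                              train_config.batch_size)
            holdout_acc.append(h_acc)
        if keep_models:
            models.append(model)
    mean_acc, sd_acc = summarize_accuracies(fold_acc)
    return CVResult(histories, fold_acc, holdout_acc, mean_acc, sd_acc, models)
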