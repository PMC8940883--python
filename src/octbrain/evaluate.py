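"""Metrics and interpretability: confusion matrix, one-vs-rest ROC/AUC with
fold-averaged curves, grad-CAM heatmaps, and t-SNE of the 64-d embeddings.

Per-tumor ROC curves use the one-vs-rest reduction of the three-class
problem; AUC is the trapezoidal area under the threshold-swept curve, which
equals the pair-counting statistic #(pos > neg) + 0.5 * #(ties) over all
positive-negative pairs (the Mann-Whitney identity, used as a cross-check).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from skimage import transform as sktransform
from sklearn.metrics import roc_curve as _sk_roc_curve

from .core import (
    CLASS_ORDER,
    FrameRecord,
    LabelError,
    TissueClass,
    UndefinedMetricError,
    logger,
    records_as_arrays,
)
from .model import AttentionResNet, extract_features, predict_proba


# ---------------------------------------------------------------------------
# Confusion matrix and derived rates
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """3x3 counts; rows = true class, columns = predicted, order NOR/GBM/PCNSL."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3) or np.any(self.counts < 0):
            raise ValueError("confusion matrix must be 3x3 with non-negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def _to_indices(labels) -> np.ndarray:
    out = []
    for lab in labels:
        if isinstance(lab, TissueClass):
            out.append(lab.index)
        elif isinstance(lab, str):
            out.append(TissueClass.from_string(lab).index)
        else:
            i = int(lab)
            if not 0 <= i < 3:
                raise LabelError(f"label index {i} outside the 3-class set")
            out.append(i)
    return np.asarray(out, dtype=int)


def confusion_matrix(true_labels, predicted_labels) -> ConfusionMatrix:
    t = _to_indices(true_labels)
    p = _to_indices(predicted_labels)
    if len(t) != len(p):
        raise ValueError("true and predicted label sequences differ in length")
    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


@dataclass
class SensSpec:
    sensitivity: float
    specificity: float
    sensitivity_defined: bool = True
    specificity_defined: bool = True


def sensitivity_specificity(cm: ConfusionMatrix, cls) -> SensSpec:
    """One-vs-rest collapse of the 3x3 matrix for the given class."""
    i = _to_indices([cls])[0]
    tp = cm.counts[i, i]
    fn = cm.counts[i].sum() - tp
    fp = cm.counts[:, i].sum() - tp
    tn = cm.total - tp - fn - fp
    sens_def = (tp + fn) > 0
    spec_def = (tn + fp) > 0
    if not sens_def:
        logger.warning("sensitivity undefined: no true instances of class %s",
                       CLASS_ORDER[i])
    return SensSpec(
        sensitivity=tp / (tp + fn) if sens_def else math.nan,
        specificity=tn / (tn + fp) if spec_def else math.nan,
        sensitivity_defined=bool(sens_def),
        specificity_defined=bool(spec_def),
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray   # TPR, non-decreasing along the sweep
    specificity: np.ndarray   # TNR = 1 - FPR
    auc: float
    target_class: str = ""


def roc_auc_ovr(scores, true_labels, cls) -> ROCResult:
    """One-vs-rest ROC for a class from its probability scores.

    AUC is the trapezoidal area under the swept curve; score ties are handled
    by the sweep visiting each unique score once (equivalent to the
    rank-midpoint convention).
    """
    scores = np.asarray(scores, dtype=float)
    if np.any(scores < 0) or np.any(scores > 1):
        raise ValueError("scores must be probabilities in [0, 1]")
    i = _to_indices([cls])[0]
    y = (_to_indices(true_labels) == i).astype(int)
    if y.min() == y.max():
        raise UndefinedMetricError(
            f"AUC undefined: labels contain only one class for {CLASS_ORDER[i]}"
        )
    fpr, tpr, thr = _sk_roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr,
                     auc=auc, target_class=CLASS_ORDER[i])


def pairwise_auc(scores, positives) -> float:
    """Brute-force pair-counting AUC: mean over all positive-negative pairs of
    1 if pos > neg, 0.5 if tied. Independent cross-check of the trapezoid."""
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives).astype(bool)
    pos = scores[positives]
    neg = scores[~positives]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedMetricError("pair-counting AUC needs both classes")
    wins = ties = 0.0
    for p in pos:
        wins += np.sum(p > neg)
        ties += np.sum(p == neg)
    return float((wins + 0.5 * ties) / (len(pos) * len(neg)))


@dataclass
class MeanROC:
    specificity_grid: np.ndarray
    mean_sensitivity: np.ndarray
    sd_sensitivity: np.ndarray
    mean_auc: float
    sd_auc: float


def average_roc_over_folds(curves: list[ROCResult], grid_step: float = 0.01) -> MeanROC:
    """Interpolate fold ROC curves onto a fixed specificity grid and average."""
    if not curves:
        raise ValueError("need at least one ROC curve to average")
    grid_spec = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    grid_fpr = 1.0 - grid_spec
    sens = []
    for c in curves:
        fpr = 1.0 - np.asarray(c.specificity)
        order = np.argsort(fpr, kind="stable")
        sens.append(np.interp(grid_fpr, fpr[order], np.asarray(c.sensitivity)[order]))
    sens = np.vstack(sens)
    aucs = np.array([c.auc for c in curves])
    sd = sens.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros(len(grid_spec))
    sd_auc = float(aucs.std(ddof=1)) if len(curves) > 1 else 0.0
    return MeanROC(grid_spec, sens.mean(axis=0), sd, float(aucs.mean()), sd_auc)


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

@dataclass
class CamMap:
    heatmap: np.ndarray       # (128, 256), >= 0, max-normalized when non-zero
    target_class: TissueClass
    overlay: np.ndarray       # (128, 256, 3) RGB in [0, 1]


# Default grad-CAM target: the 16-filter stage (64 x 128 map). Its 2 px
# spatial stride still resolves the smallest simulated inclusion (~0.05 mm
# semi-axis, 2.5 px on the standard raster); the deeper 32/64-filter maps
# (4/8 px stride) average such lesions away, so heatmaps taken there can only
# show the large-scale attenuation pattern. Pass target_stage explicitly
# (e.g. 3 for the deepest post-gate map) to override.
GRADCAM_DEFAULT_STAGE = 1


def grad_cam(model: AttentionResNet, frame, target_class,
             target_stage: int | None = GRADCAM_DEFAULT_STAGE) -> CamMap:
    """Class-activation heatmap from a stage feature map (post-gate if gated).

    Channel weights are the spatial means of d(logit)/d(map), backpropagated
    from the class logit through all layers above the map; the heatmap is the
    ReLU of the weighted channel sum, bilinearly upsampled to the input
    raster and normalized to max 1. ``target_stage=None`` selects the deepest
    stage (the conventional grad-CAM choice).
    """
    cls = target_class if isinstance(target_class, TissueClass) \
        else TissueClass.from_string(str(target_class))
    px = frame.pixels if hasattr(frame, "pixels") else np.asarray(frame)
    x = np.asarray(px, dtype=np.float32)[None, :, :, None]
    fmap, grad = model.stage_map_and_gradient(x, cls.index, target_stage)
    weights = grad[0].mean(axis=(0, 1))                      # (C,)
    cam = np.maximum((fmap[0] * weights).sum(axis=-1), 0.0)  # (h, w)
    target_shape = model.config.input_shape[:2]
    cam = sktransform.resize(cam, target_shape, order=1, mode="edge",
                             anti_aliasing=False, preserve_range=True)
    if cam.max() > 0:
        cam = cam / cam.max()
    intensity = np.asarray(px, dtype=float)
    rng_ = intensity.max() - intensity.min()
    gray = (intensity - intensity.min()) / rng_ if rng_ > 0 else intensity * 0
    heat_rgb = plt.get_cmap("jet")(cam)[..., :3]
    overlay = np.clip(0.6 * gray[..., None] + 0.4 * heat_rgb, 0, 1)
    return CamMap(heatmap=cam, target_class=cls, overlay=overlay)


# ---------------------------------------------------------------------------
# t-SNE of embeddings
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingPlot:
    coords: np.ndarray
    predicted_labels: np.ndarray
    true_labels: np.ndarray
    split_tags: np.ndarray


def tsne_scatter(embeddings: np.ndarray, labels, split_tags, seed: int = 0,
                 perplexity: float = 30.0,
                 predicted_labels=None) -> EmbeddingPlot:
    """2D t-SNE of last-average-pool embeddings, PCA-initialized and seeded."""
    from sklearn.manifold import TSNE

    emb = np.asarray(embeddings, dtype=float)
    n = len(emb)
    if n < 5:
        raise UndefinedMetricError(f"t-SNE needs at least 5 points, got {n}")
    perplexity = min(perplexity, (n - 1) / 3.0)
    tsne = TSNE(n_components=2, perplexity=perplexity, init="pca",
                random_state=seed, method="barnes_hut" if n > 50 else "exact")
    coords = tsne.fit_transform(emb)
    true = _to_indices(labels)
    pred = true if predicted_labels is None else _to_indices(predicted_labels)
    return EmbeddingPlot(coords=coords, predicted_labels=pred, true_labels=true,
                         split_tags=np.asarray(list(split_tags)))


# ---------------------------------------------------------------------------
# Whole-model evaluation report
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    cm: ConfusionMatrix
    accuracy: float
    macro_accuracy: float               # mean per-class recall
    per_class: dict = field(default_factory=dict)   # label -> SensSpec
    roc: dict = field(default_factory=dict)         # label -> ROCResult (tumors)
    volume_vote_accuracy: float = math.nan
    probabilities: np.ndarray | None = None
    y_true: np.ndarray | None = None


def evaluate_model(model: AttentionResNet, records: list[FrameRecord],
                   roc_classes=("GBM", "PCNSL")) -> EvalReport:
    """Frame-level confusion matrix, rates and per-tumor one-vs-rest ROC,
    plus a per-volume majority-vote accuracy."""
    x, y, vids = records_as_arrays(records)
    proba = predict_proba(model, x)
    pred = np.argmax(proba, axis=1)  # ties: lowest class index wins (NOR<GBM<PCNSL)
    cm = confusion_matrix(y, pred)
    per_class = {c: sensitivity_specificity(cm, c) for c in CLASS_ORDER}
    macro = float(np.mean([per_class[c].sensitivity for c in CLASS_ORDER
                           if per_class[c].sensitivity_defined]))
    roc = {}
    for c in roc_classes:
        i = _to_indices([c])[0]
        if len(np.unique((y == i).astype(int))) == 2:
            roc[c] = roc_auc_ovr(proba[:, i], y, c)
    votes_true, votes_pred = [], []
    for vid in sorted(set(vids)):
        idx = [i for i, v in enumerate(vids) if v == vid]
        votes_true.append(y[idx[0]])
        votes_pred.append(np.bincount(pred[idx], minlength=3).argmax())
    vote_acc = float(np.mean(np.asarray(votes_true) == np.asarray(votes_pred)))
    return EvalReport(cm=cm, accuracy=cm.accuracy, macro_accuracy=macro,
                      per_class=per_class, roc=roc, volume_vote_accuracy=vote_acc,
                      probabilities=proba, y_true=y)


# ---------------------------------------------------------------------------
# Figure / table writers
# ---------------------------------------------------------------------------

def save_report(report: EvalReport, out_dir) -> None:
    """Write metrics table, confusion matrix and ROC point CSVs plus figures."""
    import pandas as pd
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(report.cm.counts, index=CLASS_ORDER,
                 columns=CLASS_ORDER).to_csv(out_dir / "confusion_matrix.csv")
    rows = [{"metric": "accuracy", "value": report.accuracy},
            {"metric": "macro_accuracy", "value": report.macro_accuracy},
            {"metric": "volume_vote_accuracy", "value": report.volume_vote_accuracy}]
    for c, ss in report.per_class.items():
        rows.append({"metric": f"sensitivity_{c}", "value": ss.sensitivity})
        rows.append({"metric": f"specificity_{c}", "value": ss.specificity})
    for c, r in report.roc.items():
        rows.append({"metric": f"auc_{c}", "value": r.auc})
        pd.DataFrame({"threshold": r.thresholds, "sensitivity": r.sensitivity,
                      "specificity": r.specificity}).to_csv(
            out_dir / f"roc_{c}.csv", index=False)
    pd.DataFrame(rows).to_csv(out_dir / "metrics.csv", index=False)

    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(report.cm.counts, cmap="Blues")
    for i in range(3):
        for j in range(3):
            ax.text(j, i, str(report.cm.counts[i, j]), ha="center", va="center")
    ax.set_xticks(range(3), CLASS_ORDER)
    ax.set_yticks(range(3), CLASS_ORDER)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(out_dir / "confusion_matrix.png", dpi=120)
    plt.close(fig)

    if report.roc:
        fig, ax = plt.subplots(figsize=(4, 4))
        for c, r in report.roc.items():
            ax.plot(1 - r.specificity, r.sensitivity, label=f"{c} (AUC {r.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_dir / "roc.png", dpi=120)
        plt.close(fig)


def save_mean_roc_plot(mean_rocs: dict, out_path) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    for c, m in mean_rocs.items():
        fpr = 1.0 - m.specificity_grid
        ax.plot(fpr, m.mean_sensitivity,
                label=f"{c} (AUC {m.mean_auc:.3f}±{m.sd_auc:.3f})")
        ax.fill_between(fpr, m.mean_sensitivity - m.sd_sensitivity,
                        np.minimum(m.mean_sensitivity + m.sd_sensitivity, 1.0),
                        alpha=0.25)
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def save_cam_overlays(cams: list[CamMap], out_path, n_cols: int = 4) -> None:
    n = len(cams)
    n_rows = -(-n // n_cols)
    fig, axes = plt.subplots(n_rows, n_cols, figsize=(3 * n_cols, 1.8 * n_rows),
                             squeeze=False)
    for ax in axes.flat:
        ax.axis("off")
    for ax, cam in zip(axes.flat, cams):
        ax.imshow(cam.overlay)
        ax.set_title(cam.target_class.value, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def save_tsne_plot(plot: EmbeddingPlot, out_path) -> None:
    """Predicted-label colors; training points light, test points dark;
    misclassified points are ringed instead of guessing a class boundary."""
    colors = {0: "tab:green", 1: "tab:red", 2: "tab:blue"}
    fig, ax = plt.subplots(figsize=(5, 4.5))
    for split, alpha in (("train", 0.35), ("test", 0.95)):
        sel = plot.split_tags == split
        for c in range(3):
            m = sel & (plot.predicted_labels == c)
            if m.any():
                ax.scatter(plot.coords[m, 0], plot.coords[m, 1], s=8,
                           color=colors[c], alpha=alpha,
                           label=f"{CLASS_ORDER[c]} ({split})")
    wrong = plot.predicted_labels != plot.true_labels
    if wrong.any():
        ax.scatter(plot.coords[wrong, 0], plot.coords[wrong, 1], s=28,
                   facecolors="none", edgecolors="k", linewidths=0.6,
                   label="misclassified")
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.legend(fontsize=6, markerscale=1.2)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
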