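"""End-to-end reference experiment on the default synthetic dataset.

Mirrors the study design at desk scale: 33 OCT volumes (15/10/5 training and
2/3/3 held-out NOR/GBM/PCNSL), sliding-window despeckling (window 10,
stride 1), one attention-ResNet trained with the standard recipe (SGD,
learning rate 5e-4, momentum 0.9, batch 32, class weights, early stopping)
with fold 0 of the volume-wise split as validation, then holdout evaluation,
per-tumor one-vs-rest ROC/AUC and a grad-CAM localization check against the
simulator's ground-truth inclusion masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as _ndi
from skimage import morphology
from skimage import transform as sktransform

from . import synthetic as syn
from .core import TissueClass, logger, records_as_arrays, stage_seed
from .evaluate import EvalReport, evaluate_model, grad_cam
from .frames import STANDARD_SHAPE, preprocess_manifest
from .model import AttentionResNet, ModelConfig, build_model
from .training import SplitPlan, TrainConfig, split_by_volume, train_classifier

CAM_DILATION_RADIUS = 8  # px on the standardized 128 x 256 raster


@dataclass
class ExperimentResult:
    model: AttentionResNet
    report: EvalReport
    history: object
    plan: SplitPlan
    manifest: object
    holdout_records: list
    n_train_frames: int
    n_holdout_frames: int
    cam_localization: float = float("nan")
    cam_n_frames: int = 0
    extras: dict = field(default_factory=dict)


def standardized_mask(mask: np.ndarray, dilation_radius: int = CAM_DILATION_RADIUS,
                      registration_margin: int | None = None) -> np.ndarray:
    """Resample a phantom-grid inclusion mask to 128 x 256 and dilate it.

    Mirrors the frame path: crop the registration margin, re-pad the depth
    axis, nearest-neighbour resize, then dilate (the dilation absorbs the
    residual inter-frame jitter and the CAM upsampling blur).
    """
    from .frames import REGISTRATION_MARGIN_PX

    margin = REGISTRATION_MARGIN_PX if registration_margin is None else registration_margin
    m = mask.astype(float)
    if margin > 0:
        rows = m.shape[0]
        m = m[margin:-margin, margin:-margin]
        m = np.vstack([m, np.zeros((rows - m.shape[0], m.shape[1]))])
    m = sktransform.resize(m, STANDARD_SHAPE, order=0,
                           anti_aliasing=False, preserve_range=True) > 0.5
    if dilation_radius > 0:
        m = _ndi.binary_dilation(m, structure=morphology.disk(dilation_radius))
    return m


def cam_localization_rate(model: AttentionResNet, records, manifest,
                          dilation_radius: int = CAM_DILATION_RADIUS
                          ) -> tuple[float, int]:
    """Fraction of inclusion-bearing GBM frames whose grad-CAM argmax falls
    inside the dilated ground-truth inclusion mask of their source volume."""
    masks = {}
    rows = {r["volume_id"]: r for _, r in manifest.iterrows()}
    hits, n = 0, 0
    for rec in records:
        if rec.label != TissueClass.GBM:
            continue
        vid = rec.volume_id
        if vid not in masks:
            masks[vid] = standardized_mask(syn.load_inclusion_mask(rows[vid]),
                                           dilation_radius)
        mask = masks[vid]
        if not mask.any():
            continue
        cam = grad_cam(model, rec.frame, TissueClass.GBM)
        iz, ix = np.unravel_index(np.argmax(cam.heatmap), cam.heatmap.shape)
        hits += bool(mask[iz, ix])
        n += 1
    return (hits / n if n else float("nan")), n


def run_end_to_end(seed: int, data_dir, max_epochs: int = 30,
                   dataset_spec: syn.DatasetSpec | None = None,
                   with_cam: bool = True) -> ExperimentResult:
    """Generate data, preprocess, train once (validation = fold 0), evaluate."""
    data_dir = Path(data_dir)
    spec = dataset_spec if dataset_spec is not None else syn.DatasetSpec()
    manifest = syn.generate_dataset(spec, data_dir, stage_seed(seed, "simulate"))
    records = preprocess_manifest(manifest)
    plan = split_by_volume(manifest, n_folds=5, seed=stage_seed(seed, "split"))
    holdout_ids = set(plan.holdout_volumes)
    pool = [r for r in records if r.volume_id in plan.fold_of_volume]
    holdout = [r for r in records if r.volume_id in holdout_ids]
    val_ids = set(plan.volumes_in_fold(0))
    train = [r for r in pool if r.volume_id not in val_ids]
    val = [r for r in pool if r.volume_id in val_ids]
    logger.info("end-to-end: %d train / %d val / %d holdout frames",
                len(train), len(val), len(holdout))
    tconf = TrainConfig(max_epochs=max_epochs, seed=stage_seed(seed, "train"))
    model = build_model(ModelConfig(), seed=stage_seed(seed, "model"))
    model, history = train_classifier(model, train, val, tconf)
    report = evaluate_model(model, holdout)
    result = ExperimentResult(
        model=model, report=report, history=history, plan=plan, manifest=manifest,
        holdout_records=holdout, n_train_frames=len(train),
        n_holdout_frames=len(holdout),
    )
    if with_cam:
        result.cam_localization, result.cam_n_frames = cam_localization_rate(
            model, holdout, manifest)
    return result
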