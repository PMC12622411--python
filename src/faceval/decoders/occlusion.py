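"""Occlusion-sensitivity analysis with per-region retraining under trial-level CV.

Unlike fixed-parameter occlusion, every masked dataset retrains the
classifier from scratch in each cross-validation fold, so the accuracy drop
measures how much a facial region contributes when the model is free to
re-weight the remaining features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .classifier import fit_classifier
from .data import ClassifierConfig, FrameDataset
from .splits import split_by_trial

__all__ = ["OcclusionResult", "occlusion_cv"]


@dataclass
class OcclusionResult:
    accuracy: dict[str, float]  # region -> mean CV accuracy ("none" = control)
    drop: dict[str, float]  # control accuracy minus region accuracy
    fold_accuracy: dict[str, np.ndarray]


def _apply_mask(images: np.ndarray, mask: np.ndarray, fill: float) -> np.ndarray:
    out = images.copy()
    out[:, :, mask] = fill
    return out


def occlusion_cv(dataset: FrameDataset, region_masks: dict[str, np.ndarray],
                 k: int = 10, cfg: ClassifierConfig | None = None,
                 face_roi: np.ndarray | None = None) -> OcclusionResult:
    """Mean CV accuracy per occluded region plus the unmasked control.

    Masks are filled with the dataset mean intensity ("neutral-colored").
    A mask covering more than 90% of the face ROI (default: whole frame)
    only warns.
    """
    cfg = cfg or ClassifierConfig()
    side = dataset.side
    roi = np.ones((side, side), dtype=bool) if face_roi is None else face_roi
    for name, mask in region_masks.items():
        if mask.shape != (side, side):
            raise ValueError(f"mask {name!r} does not match the image side")
        if (mask & roi).sum() > 0.9 * roi.sum():
            warnings.warn(f"mask {name!r} covers >90% of the face ROI")

    fill = float(dataset.images.mean())
    splits = split_by_trial(dataset.trial_ids, dataset.labels, scheme="kfold",
                            k=k, stratify=True, seed=cfg.seed)

    conditions = {"none": None, **region_masks}
    fold_acc = {name: np.empty(len(splits)) for name in conditions}
    for name, mask in conditions.items():
        imgs = dataset.images if mask is None else _apply_mask(dataset.images, mask, fill)
        for f, (tr, te) in enumerate(splits):
            net = fit_classifier(imgs[tr], dataset.labels[tr], cfg,
                                 n_classes=len(dataset.classes))
            pred = net.predict(imgs[te])
            fold_acc[name][f] = float((pred == dataset.labels[te]).mean())

    accuracy = {name: float(a.mean()) for name, a in fold_acc.items()}
    control = accuracy["none"]
    drop = {name: control - acc for name, acc in accuracy.items() if name != "none"}
    return OcclusionResult(accuracy=accuracy, drop=drop, fold_accuracy=fold_acc)
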