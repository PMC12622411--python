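"""Frame classifier training with trial-level evaluation and shuffle control."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..nn import SGD, SmallResNet, softmax_cross_entropy
from .data import ClassifierConfig, FrameDataset, augment_batch
from .splits import split_by_trial

__all__ = ["TrainResult", "train_frame_classifier", "fit_classifier", "evaluate"]


@dataclass
class TrainResult:
    model: SmallResNet
    accuracy: float  # frame-wise accuracy on held-out trials
    per_mouse_accuracy: dict[str, float]
    confusion: np.ndarray  # rows = true class, columns = predicted
    train_idx: np.ndarray = field(default=None, repr=False)
    test_idx: np.ndarray = field(default=None, repr=False)


def fit_classifier(images: np.ndarray, labels: np.ndarray, cfg: ClassifierConfig,
                   n_classes: int = 5) -> SmallResNet:
    """Train a fresh reduced residual classifier on the given frames."""
    if len(np.unique(labels)) < 2:
        raise ValueError("training set contains a single class")
    net = SmallResNet(n_classes=n_classes, seed=cfg.seed)
    opt = SGD(net.params(), lr=cfg.lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    idx = np.arange(len(images))
    for _ in range(cfg.epochs):
        rng.shuffle(idx)
        for i in range(0, len(idx), cfg.batch_size):
            b = idx[i:i + cfg.batch_size]
            if len(b) < 2:
                continue  # BatchNorm needs more than one sample
            xb = images[b]
            if cfg.augment:
                xb = augment_batch(xb, rng, cfg.rotation_deg, cfg.resize_jitter)
            opt.zero_grad()
            logits = net.forward(xb, train=True)
            _, dlogits, _ = softmax_cross_entropy(logits, labels[b])
            net.backward(dlogits)
            opt.step()
    return net


def evaluate(net: SmallResNet, dataset: FrameDataset, idx: np.ndarray):
    """Frame-wise accuracy on ``idx``, per-mouse means and confusion matrix."""
    pred = net.predict(dataset.images[idx])
    truth = dataset.labels[idx]
    acc = float((pred == truth).mean())
    per_mouse = {}
    mice = dataset.mouse_ids[idx]
    for m in np.unique(mice):
        sel = mice == m
        per_mouse[str(m)] = float((pred[sel] == truth[sel]).mean())
    k = len(dataset.classes)
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (truth, pred), 1)
    return acc, per_mouse, confusion


def train_frame_classifier(dataset: FrameDataset, cfg: ClassifierConfig | None = None,
                           shuffle_labels: bool = False, shuffle_unit: str = "frame",
                           split=None) -> TrainResult:
    """Train and evaluate on a trial-level split.

    ``shuffle_labels`` randomly permutes the training labels (evaluation
    labels stay intact), the chance-level control. The default permutes at
    the frame level, which destroys every label-image association and pins
    held-out accuracy at chance; ``shuffle_unit='trial'`` permutes whole
    trials' labels instead (a weaker control that can retain partial
    structure). ``split`` is a (train_idx, test_idx) pair; default is a
    stratified 80/20 trial holdout derived from ``cfg.seed``.
    """
    cfg = cfg or ClassifierConfig()
    if split is None:
        split = split_by_trial(dataset.trial_ids, dataset.labels, scheme="holdout",
                               stratify=True, seed=cfg.seed)[0]
    train_idx, test_idx = split
    assert not set(dataset.trial_ids[train_idx]) & set(dataset.trial_ids[test_idx])

    train_labels = dataset.labels[train_idx].copy()
    if shuffle_labels:
        rng = np.random.default_rng(cfg.seed + 1)
        if shuffle_unit == "frame":
            train_labels = rng.permutation(train_labels)
        elif shuffle_unit == "trial":
            trials = dataset.trial_ids[train_idx]
            uniq = np.unique(trials)
            trial_lab = {t: train_labels[trials == t][0] for t in uniq}
            permuted = rng.permutation([trial_lab[t] for t in uniq])
            lut = dict(zip(uniq, permuted))
            train_labels = np.array([lut[t] for t in trials])
        else:
            raise ValueError("shuffle_unit must be 'frame' or 'trial'")

    net = fit_classifier(dataset.images[train_idx], train_labels, cfg,
                         n_classes=len(dataset.classes))
    acc, per_mouse, confusion = evaluate(net, dataset, test_idx)
    return TrainResult(model=net, accuracy=acc, per_mouse_accuracy=per_mouse,
                       confusion=confusion, train_idx=train_idx, test_idx=test_idx)
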