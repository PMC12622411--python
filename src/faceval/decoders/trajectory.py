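"""Region-wise LSTM decoding of keypoint trajectories.

Per trial, the (x, y) coordinates of the four highest-variance keypoints of
one facial region are extracted over a 2.5 s window (0.5 s before to 2 s
after stimulus onset), z-scored, and downsampled by keeping every third
frame — 25 timepoints x 8 channels, a 200-dimensional trajectory — then
classified over the five stimulus conditions with a stacked LSTM under
stratified trial-level cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn import Adam, LSTMClassifier, softmax_cross_entropy
from ..synthgen.cohort import SessionFixture
from ..synthgen.render import KEYPOINT_NAMES, KEYPOINT_REGIONS
from .data import CLASS_ORDER
from .splits import split_by_trial

__all__ = ["TrajectoryDataset", "trajectories_from_cohort", "lstm_region_decoder",
           "REGIONS"]

REGIONS = ("ear", "whisker", "snout", "pupil", "mixed")

# "snout" pools the nose and mouth keypoints of the schematic face.
_REGION_KEYPOINTS = {
    "ear": [n for n in KEYPOINT_NAMES if KEYPOINT_REGIONS[n] == "ear"],
    "whisker": [n for n in KEYPOINT_NAMES if KEYPOINT_REGIONS[n] == "whisker"],
    "pupil": [n for n in KEYPOINT_NAMES if KEYPOINT_REGIONS[n] == "pupil"],
    "snout": [n for n in KEYPOINT_NAMES if KEYPOINT_REGIONS[n] in ("nose", "mouth")],
}


@dataclass
class TrajectoryDataset:
    """(n_trials, 25, 8) z-scored trajectories with labels and bookkeeping."""

    tensors: np.ndarray
    labels: np.ndarray
    trial_ids: np.ndarray
    mouse_ids: np.ndarray
    region: str
    keypoint_names: list[str]

    @property
    def flat_dim(self) -> int:
        return self.tensors.shape[1] * self.tensors.shape[2]


def trajectories_from_cohort(cohort: list[SessionFixture], region: str,
                             pre_s: float = 0.5, post_s: float = 2.0,
                             downsample: int = 3, n_keypoints: int = 4,
                             seed: int = 0) -> TrajectoryDataset:
    """Build the trajectory tensor for one region (or 'mixed').

    The ``n_keypoints`` keypoints with the highest coordinate variance
    across trials are selected within the region; 'mixed' samples one
    keypoint from each of four different regions (seeded).
    """
    if region not in REGIONS:
        raise ValueError(f"region must be one of {REGIONS}")
    name_idx = {n: i for i, n in enumerate(KEYPOINT_NAMES)}

    segs = [seg for ses in cohort for seg in ses.trials]
    fps = cohort[0].spec.fps
    windows = []
    for seg in segs:
        mask = (seg.times >= -pre_s) & (seg.times < post_s)
        w = seg.keypoints[mask]
        n_expected = int(round((pre_s + post_s) * fps))
        if w.shape[0] < n_expected:
            raise ValueError("trial window extends beyond the recording")
        windows.append(w[:n_expected])
    stack = np.stack(windows)  # (trials, T, 37, 2)

    if region == "mixed":
        rng = np.random.default_rng(seed)
        picks = []
        for r in rng.permutation(list(_REGION_KEYPOINTS))[:n_keypoints]:
            cand = _REGION_KEYPOINTS[r]
            var = [stack[:, :, name_idx[n], :].var() for n in cand]
            picks.append(cand[int(np.argmax(var))])
        names = picks
    else:
        cand = _REGION_KEYPOINTS[region]
        if len(cand) < n_keypoints:
            raise ValueError(f"region {region!r} has fewer than {n_keypoints} keypoints")
        var = np.array([stack[:, :, name_idx[n], :].var() for n in cand])
        order = np.argsort(-var, kind="stable")[:n_keypoints]
        names = [cand[i] for i in order]

    sel = [name_idx[n] for n in names]
    traj = stack[:, :, sel, :]  # (trials, T, 4, 2)
    traj = traj[:, ::downsample]
    t_pts = traj.shape[1]
    traj = traj.reshape(len(segs), t_pts, -1)
    mu = traj.mean(axis=(0, 1), keepdims=True)
    sd = traj.std(axis=(0, 1), keepdims=True)
    sd[sd == 0] = 1.0
    traj = (traj - mu) / sd
    labels = np.array([CLASS_ORDER.index(s.stimulus) for s in segs])
    return TrajectoryDataset(
        tensors=traj.astype(np.float32), labels=labels,
        trial_ids=np.array([s.trial_id for s in segs]),
        mouse_ids=np.array([s.mouse_id for s in segs]),
        region=region, keypoint_names=names)


def lstm_region_decoder(data: TrajectoryDataset, k: int = 10, seed: int = 0,
                        hidden: int = 128, n_layers: int = 3, dropout: float = 0.3,
                        epochs: int = 60, lr: float = 3e-3,
                        shuffle_labels: bool = False) -> dict:
    """Stratified trial-level k-fold CV accuracy of the LSTM decoder.

    Returns {'accuracy', 'fold_accuracy', 'region'}. ``shuffle_labels``
    permutes training labels (chance-level control).
    """
    splits = split_by_trial(data.trial_ids, data.labels, scheme="kfold", k=k,
                            stratify=True, seed=seed)
    rng = np.random.default_rng(seed)
    fold_acc = []
    for tr, te in splits:
        x_tr, y_tr = data.tensors[tr], data.labels[tr].copy()
        if shuffle_labels:
            y_tr = rng.permutation(y_tr)
        model = LSTMClassifier(d_in=data.tensors.shape[2], n_classes=len(CLASS_ORDER),
                               hidden=hidden, n_layers=n_layers, dropout=dropout,
                               seed=seed)
        opt = Adam(model.params(), lr=lr)
        idx = np.arange(len(tr))
        best_loss, stall = np.inf, 0
        for _ in range(epochs):
            rng.shuffle(idx)
            ep_loss = 0.0
            for i in range(0, len(idx), 32):
                b = idx[i:i + 32]
                opt.zero_grad()
                logits = model.forward(x_tr[b], train=True)
                loss, dl, _ = softmax_cross_entropy(logits, y_tr[b])
                model.backward(dl)
                opt.step()
                ep_loss += loss * len(b)
            ep_loss /= len(idx)
            if ep_loss < best_loss - 1e-4:
                best_loss, stall = ep_loss, 0
            else:
                stall += 1
                if stall >= 8:
                    break
        pred = model.predict(data.tensors[te])
        fold_acc.append(float((pred == data.labels[te]).mean()))
    return {"accuracy": float(np.mean(fold_acc)),
            "fold_accuracy": np.array(fold_acc), "region": data.region}
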