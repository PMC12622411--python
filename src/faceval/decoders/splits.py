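"""Trial-level data splits (no trial ever spans train and test)."""

from __future__ import annotations

import numpy as np

__all__ = ["split_by_trial"]


def split_by_trial(trial_ids: np.ndarray, labels: np.ndarray | None = None,
                   scheme: str = "kfold", k: int = 10, holdout_frac: float = 0.2,
                   stratify: bool = True, seed: int = 0):
    """Partition frames into folds at the trial level.

    Returns a list of (train_idx, test_idx) frame-index pairs — one pair for
    ``scheme='holdout'``, ``k`` pairs for ``scheme='kfold'``. Stratification
    assigns each class's trials round-robin to folds (class proportions per
    fold are preserved within one trial) and requires every class to reach
    every fold.
    """
    trial_ids = np.asarray(trial_ids)
    trials = np.unique(trial_ids)
    rng = np.random.default_rng(seed)

    if labels is not None:
        labels = np.asarray(labels)
        trial_label = {t: labels[trial_ids == t][0] for t in trials}
    else:
        stratify = False

    if scheme == "holdout":
        k_eff = max(int(round(1.0 / holdout_frac)), 2)
        folds = _assign_folds(trials, trial_label if stratify else None, k_eff, rng)
        test_trials = trials[folds == 0]
        test_mask = np.isin(trial_ids, test_trials)
        return [(np.flatnonzero(~test_mask), np.flatnonzero(test_mask))]
    if scheme != "kfold":
        raise ValueError("scheme must be 'holdout' or 'kfold'")
    if len(trials) < k:
        raise ValueError(f"need at least k={k} trials, got {len(trials)}")
    folds = _assign_folds(trials, trial_label if stratify else None, k, rng)
    if stratify:
        classes = set(trial_label.values())
        for f in range(k):
            fold_classes = {trial_label[t] for t in trials[folds == f]}
            if fold_classes != classes:
                raise ValueError(
                    f"class missing from fold {f} under stratification; "
                    "use more trials per class or fewer folds")
    out = []
    for f in range(k):
        test_trials = trials[folds == f]
        test_mask = np.isin(trial_ids, test_trials)
        out.append((np.flatnonzero(~test_mask), np.flatnonzero(test_mask)))
    return out


def _assign_folds(trials, trial_label, k, rng):
    folds = np.empty(len(trials), dtype=int)
    if trial_label is None:
        perm = rng.permutation(len(trials))
        folds[perm] = np.arange(len(trials)) % k
        return folds
    by_class: dict = {}
    for i, t in enumerate(trials):
        by_class.setdefault(trial_label[t], []).append(i)
    for idxs in by_class.values():
        idxs = np.array(idxs)
        perm = rng.permutation(len(idxs))
        start = int(rng.integers(k))
        folds[idxs[perm]] = (np.arange(len(idxs)) + start) % k
    return folds
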