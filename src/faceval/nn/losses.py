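"""Losses with analytic gradients."""

from __future__ import annotations

import numpy as np

__all__ = ["softmax_cross_entropy", "contrastive_loss_grad"]


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch.

    Returns (loss, dlogits, probabilities); labels are integer class ids.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n, probs


def contrastive_loss_grad(e1: np.ndarray, e2: np.ndarray, labels: np.ndarray,
                          margin: float):
    """Pairwise contrastive loss and its gradients w.r.t. both embeddings.

    L = 1/(2N) sum_i [ y_i d_i^2 + (1 - y_i) max(m - d_i, 0)^2 ], with
    d_i the Euclidean distance between the paired embeddings and y_i = 1 for
    same-valence pairs. Returns (loss, de1, de2, distances).
    """
    if margin <= 0:
        raise ValueError("margin must be > 0")
    y = np.asarray(labels, dtype=float)
    diff = e1 - e2
    d = np.sqrt((diff ** 2).sum(axis=1))
    n = len(y)
    slack = np.maximum(margin - d, 0.0)
    loss = (y * d ** 2 + (1.0 - y) * slack ** 2).sum() / (2.0 * n)

    # dL/dd = [y*d - (1-y)*slack] / N; dd/de1 = diff/d (0 at d == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(d[:, None] > 0, diff / np.where(d[:, None] == 0, 1, d[:, None]), 0.0)
    dl_dd = (y * d - (1.0 - y) * slack) / n
    de1 = dl_dd[:, None] * unit
    return float(loss), de1.astype(e1.dtype), (-de1).astype(e2.dtype), d
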