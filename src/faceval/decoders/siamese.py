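"""Siamese contrastive embedding with the cross-mouse pair strategy.

Pairs are labeled "same valence" (y = 1) only when the two frames come from
*different* mice sharing a valence, and "different valence" (y = 0) only
when they come from the *same* mouse with opposite valences. This forces
the twin encoder to separate valence while discarding identity, so the
embedding generalizes to mice never seen in training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..nn import Adam, SiameseEncoder, contrastive_loss_grad
from .data import FrameDataset

__all__ = ["PairDataset", "ContrastiveConfig", "SiameseResult",
           "contrastive_loss", "auto_margin", "make_pairs", "train_siamese"]


def contrastive_loss(distances: np.ndarray, labels: np.ndarray, m: float) -> float:
    """L = 1/(2N) sum[ y d^2 + (1 - y) max(m - d, 0)^2 ]."""
    if m <= 0:
        raise ValueError("margin must be > 0")
    d = np.asarray(distances, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be 0 or 1")
    slack = np.maximum(m - d, 0.0)
    return float((y * d ** 2 + (1.0 - y) * slack ** 2).sum() / (2.0 * len(d)))


def auto_margin(distances: np.ndarray, squared: bool = False) -> tuple[float, bool]:
    """Empirical margin from training-pair embedding distances.

    Default: the mean interpair distance; ``squared=True`` uses the mean
    squared distance instead (both conventions are in circulation). Returns
    (margin, flagged); all-zero distances fall back to m = 1 with a flag.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two pair distances")
    m = float((d ** 2).mean() if squared else d.mean())
    if m == 0.0:
        return 1.0, True
    return m, False


@dataclass
class PairDataset:
    """Index pairs into a FrameDataset with same/different-valence labels."""

    idx1: np.ndarray
    idx2: np.ndarray
    labels: np.ndarray  # 1 = same valence (different mice), 0 = different valence (same mouse)
    dataset: FrameDataset = field(repr=False)


_VALENCE_OF_CLASS = {"sucrose": "positive", "NaCl": "positive",
                     "bitterness": "negative", "shock": "negative", "water": "neutral"}


def make_pairs(dataset: FrameDataset, n_pairs: int = 500, seed: int = 0,
               max_per_mouse: int | None = None) -> PairDataset:
    """Sample a balanced pair set under the sanctioned pair categories.

    Neutral frames are excluded. Same-valence pairs are drawn across
    distinct mice; different-valence pairs within one mouse; no same-mouse
    same-valence pair is ever emitted. ``max_per_mouse`` caps how often one
    mouse appears in each category (default: no cap).
    """
    rng = np.random.default_rng(seed)
    valences = np.array([_VALENCE_OF_CLASS[dataset.classes[l]] for l in dataset.labels])
    usable = valences != "neutral"
    mice = np.unique(dataset.mouse_ids[usable])
    if len(mice) < 2:
        raise ValueError("need at least two mice for cross-mouse pair sampling")

    by_mouse_val: dict[tuple[str, str], np.ndarray] = {}
    for m in mice:
        for v in ("positive", "negative"):
            sel = np.flatnonzero((dataset.mouse_ids == m) & (valences == v))
            if sel.size:
                by_mouse_val[(m, v)] = sel
    both = [m for m in mice
            if (m, "positive") in by_mouse_val and (m, "negative") in by_mouse_val]
    for m in mice:
        if m not in both:
            warnings.warn(f"mouse {m} lacks one valence; excluded from "
                          "different-valence sampling")
    if not both:
        raise ValueError("no mouse has both valences; cannot build different-valence pairs")

    n_same = n_pairs // 2
    n_diff = n_pairs - n_same
    counts: dict[str, int] = {m: 0 for m in mice}

    def cap_ok(*ms):
        return max_per_mouse is None or all(counts[m] < max_per_mouse for m in ms)

    i1, i2, lab = [], [], []
    guard = 0
    while len(lab) < n_same and guard < 100 * n_pairs:
        guard += 1
        v = rng.choice(("positive", "negative"))
        cands = [m for m in mice if (m, v) in by_mouse_val]
        if len(cands) < 2:
            continue
        ma, mb = rng.choice(cands, size=2, replace=False)
        if not cap_ok(ma, mb):
            continue
        i1.append(rng.choice(by_mouse_val[(ma, v)]))
        i2.append(rng.choice(by_mouse_val[(mb, v)]))
        lab.append(1)
        counts[ma] += 1
        counts[mb] += 1
    guard = 0
    while len(lab) < n_same + n_diff and guard < 100 * n_pairs:
        guard += 1
        m = both[rng.integers(len(both))]
        if not cap_ok(m):
            continue
        i1.append(rng.choice(by_mouse_val[(m, "positive")]))
        i2.append(rng.choice(by_mouse_val[(m, "negative")]))
        lab.append(0)
        counts[m] += 1
    return PairDataset(np.array(i1), np.array(i2), np.array(lab), dataset)


@dataclass
class ContrastiveConfig:
    margin: float | None = None  # None -> auto_margin from initial distances
    squared_margin: bool = False
    embed_dim: int = 16
    epochs: int = 8
    batch_pairs: int = 32
    lr: float = 1e-3
    seed: int = 0


@dataclass
class SiameseResult:
    model: SiameseEncoder
    margin: float
    train_loss: list[float]
    held_out_same: np.ndarray  # distances of same-valence pairs, unseen mice
    held_out_diff: np.ndarray
    margin_flagged: bool = False


def _pair_distances(model: SiameseEncoder, pairs: PairDataset) -> np.ndarray:
    e1 = model.embed(pairs.dataset.images[pairs.idx1])
    e2 = model.embed(pairs.dataset.images[pairs.idx2])
    return np.linalg.norm(e1 - e2, axis=1)


def train_siamese(pairs: PairDataset, cfg: ContrastiveConfig | None = None,
                  held_out_pairs: PairDataset | None = None) -> SiameseResult:
    """Minimize the contrastive loss over a balanced pair set.

    The two branches run as one batched pass through shared layers (exact
    weight sharing). When ``held_out_pairs`` is given (pairs built from mice
    absent from ``pairs``), the result carries their same/different distance
    samples as the across-subject generalization readout.
    """
    cfg = cfg or ContrastiveConfig()
    if len(pairs.labels) < 2:
        raise ValueError("need at least two pairs")
    model = SiameseEncoder(embed_dim=cfg.embed_dim, seed=cfg.seed)

    if cfg.margin is None:
        d0 = _pair_distances(model, pairs)
        margin, flagged = auto_margin(d0, squared=cfg.squared_margin)
    else:
        margin, flagged = float(cfg.margin), False

    opt = Adam(model.params(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    order = np.arange(len(pairs.labels))
    losses = []
    imgs = pairs.dataset.images
    for _ in range(cfg.epochs):
        rng.shuffle(order)
        ep_loss = 0.0
        for i in range(0, len(order), cfg.batch_pairs):
            b = order[i:i + cfg.batch_pairs]
            if len(b) < 2:
                continue
            x = np.concatenate([imgs[pairs.idx1[b]], imgs[pairs.idx2[b]]])
            opt.zero_grad()
            emb = model.forward(x, train=True)
            e1, e2 = emb[:len(b)], emb[len(b):]
            loss, de1, de2, _ = contrastive_loss_grad(e1, e2, pairs.labels[b], margin)
            model.backward(np.concatenate([de1, de2]))
            opt.step()
            ep_loss += loss * len(b)
        losses.append(ep_loss / len(order))

    if held_out_pairs is not None:
        d = _pair_distances(model, held_out_pairs)
        same = d[held_out_pairs.labels == 1]
        diff = d[held_out_pairs.labels == 0]
    else:
        d = _pair_distances(model, pairs)
        same = d[pairs.labels == 1]
        diff = d[pairs.labels == 0]
    return SiameseResult(model=model, margin=margin, train_loss=losses,
                         held_out_same=same, held_out_diff=diff, margin_flagged=flagged)
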