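"""Valence-specific HOG prototypes and similarity scoring.

A positive and a negative prototype are built from one designated prototype
mouse (excluded from every downstream evaluation): for each stimulus, the
subprototype frames that are least similar to the neutral baseline yet most
representative of their stimulus are selected with the two-step apex
procedure, and their HOG vectors are averaged within each valence (positive
<- sucrose, NaCl; negative <- bitterness, shock). Any frame stream can then
be scored by cosine similarity to both prototypes; the per-frame difference
sim_pos - sim_neg is the real-time valence readout used for drug sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .hogspace import _cosine_matrix, select_apex_frame
from .synthgen.phenotype import VALENCE_OF

__all__ = [
    "ValencePrototype",
    "SimilarityTimecourse",
    "ValenceSummary",
    "select_subprototypes",
    "build_prototype",
    "score_stream",
    "cumulative_similarity",
    "drug_valence_index",
]


@dataclass
class ValencePrototype:
    positive_vector: np.ndarray
    negative_vector: np.ndarray
    subprototype_indices: dict[str, np.ndarray] = field(default_factory=dict)
    source_mouse: str = ""
    k_frames: int = 10

    def __post_init__(self):
        self.positive_vector = np.asarray(self.positive_vector, dtype=float)
        self.negative_vector = np.asarray(self.negative_vector, dtype=float)
        if not self.positive_vector.any() or not self.negative_vector.any():
            raise ValueError("prototype vectors must be nonzero")


@dataclass
class SimilarityTimecourse:
    """Per-frame cosine similarity to each prototype and their difference."""

    sim_pos: np.ndarray
    sim_neg: np.ndarray
    times: np.ndarray  # seconds

    @property
    def diff(self) -> np.ndarray:
        return self.sim_pos - self.sim_neg


@dataclass
class ValenceSummary:
    """Per-epoch drug-session summary of the valence readout."""

    epochs: list[tuple[float, float]]
    normalized_difference: list[float]
    proportion_positive: list[float]
    proportion_negative: list[float]
    ratio: list[float]  # positive : negative frame counts (inf if no negative)
    baseline_flagged: bool = False  # True when baseline SD was 0


def select_subprototypes(stim_hogs: np.ndarray, neutral_hogs: np.ndarray,
                         k: int = 10, shortlist_k: int = 10) -> np.ndarray:
    """Indices of the k subprototype frames of one stimulus.

    Reuses the apex two-step procedure: shortlist by within-stimulus
    similarity, then rank shortlist members by ascending similarity to the
    neutral baseline and keep the first ``k``.
    """
    _, shortlist = select_apex_frame(stim_hogs, neutral_hogs, shortlist_k=shortlist_k)
    if k > len(shortlist):
        warnings.warn(f"k={k} exceeds shortlist size {len(shortlist)}; clamping")
        k = len(shortlist)
    to_base = _cosine_matrix(np.atleast_2d(stim_hogs)[shortlist],
                             np.atleast_2d(neutral_hogs)).mean(axis=1)
    order = np.lexsort((shortlist, to_base))
    return np.sort(shortlist[order[:k]])


def build_prototype(subprototype_hogs: dict[str, np.ndarray],
                    valence_map: dict[str, str] | None = None,
                    source_mouse: str = "", k_frames: int = 10) -> ValencePrototype:
    """Average subprototype HOG vectors within each valence.

    ``subprototype_hogs`` maps stimulus -> (k, n_features) array;
    ``valence_map`` maps stimulus -> "positive"/"negative" (defaults to the
    canonical grouping; neutral stimuli are ignored).
    """
    vmap = VALENCE_OF if valence_map is None else valence_map
    pools: dict[str, list[np.ndarray]] = {"positive": [], "negative": []}
    for stim, hogs in subprototype_hogs.items():
        v = vmap.get(stim)
        if v in pools:
            pools[v].append(np.atleast_2d(np.asarray(hogs, dtype=float)))
    for v, vecs in pools.items():
        if not vecs:
            raise ValueError(f"no stimuli of valence {v!r} among {sorted(subprototype_hogs)}")
    pos = np.vstack(pools["positive"]).mean(axis=0)
    neg = np.vstack(pools["negative"]).mean(axis=0)
    return ValencePrototype(pos, neg, source_mouse=source_mouse, k_frames=k_frames)


def score_stream(frame_hogs: np.ndarray, proto: ValencePrototype,
                 times: np.ndarray | None = None) -> SimilarityTimecourse:
    """Per-frame cosine similarity of a (aligned) frame stream to both prototypes."""
    frame_hogs = np.atleast_2d(np.asarray(frame_hogs, dtype=float))
    if frame_hogs.shape[1] != proto.positive_vector.shape[0]:
        raise ValueError(
            f"HOG length {frame_hogs.shape[1]} does not match prototype "
            f"length {proto.positive_vector.shape[0]} (config mismatch?)")
    sim_pos = _cosine_matrix(frame_hogs, proto.positive_vector[None, :])[:, 0]
    sim_neg = _cosine_matrix(frame_hogs, proto.negative_vector[None, :])[:, 0]
    if times is None:
        times = np.arange(frame_hogs.shape[0], dtype=float)
    return SimilarityTimecourse(sim_pos=sim_pos, sim_neg=sim_neg, times=np.asarray(times, float))


def cumulative_similarity(tc: SimilarityTimecourse,
                          window: tuple[float, float]) -> tuple[float, float]:
    """Sums of sim_pos and sim_neg over a [t0, t1) time window."""
    t0, t1 = window
    step = float(tc.times[1] - tc.times[0]) if len(tc.times) > 1 else 1.0
    if t0 < tc.times[0] - 1e-9 or t1 > tc.times[-1] + step + 1e-9:
        raise ValueError("window outside the timecourse")
    mask = (tc.times >= t0) & (tc.times < t1)
    return float(tc.sim_pos[mask].sum()), float(tc.sim_neg[mask].sum())


def drug_valence_index(tc: SimilarityTimecourse, baseline_window: tuple[float, float],
                       epochs: list[tuple[float, float]]) -> ValenceSummary:
    """Epoch summaries of a drug session's valence readout.

    The normalized similarity difference of an epoch is the baseline-z-scored
    epoch mean of diff: (mean(diff in epoch) - mean(diff in baseline)) /
    SD(diff in baseline). Frames are classified positive/negative by the sign
    of diff (exact zeros excluded); proportions and the positive:negative
    ratio are reported per epoch. A zero-variance baseline falls back to the
    unscaled difference and sets ``baseline_flagged``.
    """
    b0, b1 = baseline_window
    if b1 <= b0:
        raise ValueError("empty baseline window")
    if epochs and min(e[0] for e in epochs) < b1:
        if any(e[0] < b0 for e in epochs):
            raise ValueError("epochs must not precede the baseline window")
    diff = tc.diff
    bmask = (tc.times >= b0) & (tc.times < b1)
    if not bmask.any():
        raise ValueError("baseline window contains no frames")
    bmean = diff[bmask].mean()
    bsd = diff[bmask].std(ddof=0)
    flagged = bsd == 0.0

    norm_diff, prop_pos, prop_neg, ratio = [], [], [], []
    for t0, t1 in epochs:
        emask = (tc.times >= t0) & (tc.times < t1)
        if not emask.any():
            raise ValueError(f"epoch ({t0}, {t1}) contains no frames")
        shift = diff[emask].mean() - bmean
        norm_diff.append(float(shift if flagged else shift / bsd))
        d = diff[emask]
        n_pos = int((d > 0).sum())
        n_neg = int((d < 0).sum())
        n_cls = n_pos + n_neg
        prop_pos.append(n_pos / n_cls if n_cls else np.nan)
        prop_neg.append(n_neg / n_cls if n_cls else np.nan)
        ratio.append(n_pos / n_neg if n_neg else np.inf)
    return ValenceSummary(epochs=list(epochs), normalized_difference=norm_diff,
                          proportion_positive=prop_pos, proportion_negative=prop_neg,
                          ratio=ratio, baseline_flagged=flagged)


def save_prototype_h5(path, proto: ValencePrototype) -> None:
    """Persist both prototype vectors plus provenance metadata."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("positive", data=proto.positive_vector)
        f.create_dataset("negative", data=proto.negative_vector)
        f.attrs["source_mouse"] = proto.source_mouse
        f.attrs["k_frames"] = proto.k_frames


def load_prototype_h5(path) -> ValencePrototype:
    import h5py

    with h5py.File(path, "r") as f:
        return ValencePrototype(
            positive_vector=f["positive"][...],
            negative_vector=f["negative"][...],
            source_mouse=str(f.attrs["source_mouse"]),
            k_frames=int(f.attrs["k_frames"]))
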