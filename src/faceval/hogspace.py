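"""Frame-appearance descriptors and unsupervised structure.

Histogram-of-oriented-gradients (HOG) vectors are the coordinate system for
everything similarity-based in this package: 8 orientation bins, 16x16-pixel
cells at a 1024-px input (cell size scales with the canvas so the descriptor
length is canvas-invariant), 1x1 cells per block, so block normalization
degenerates to per-cell L2 normalization with a zero-gradient guard.
Cosine similarity between two HOG vectors a and b is a.b / (||a|| ||b||).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import hog as _sk_hog
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "HOGConfig",
    "MotionEnergySeries",
    "EmbeddingResult",
    "compute_hog",
    "hog_matrix",
    "cosine_similarity",
    "motion_energy",
    "select_apex_frame",
    "embed_expressions",
    "pre_post_similarity",
]


@dataclass(frozen=True)
class HOGConfig:
    """HOG extraction parameters; defaults follow the 1024-px reference setup."""

    orientations: int = 8
    cell_size: int = 16  # px at input_side=1024; scale together with input_side
    cells_per_block: int = 1
    input_side: int = 1024

    def __post_init__(self):
        if self.input_side % self.cell_size:
            raise ValueError("input_side must be divisible by cell_size")

    @property
    def n_features(self) -> int:
        n_cells = self.input_side // self.cell_size
        blocks = n_cells - self.cells_per_block + 1
        return blocks * blocks * self.cells_per_block ** 2 * self.orientations

    @classmethod
    def for_canvas(cls, side: int, orientations: int = 8) -> "HOGConfig":
        """Config for a smaller canvas keeping the reference cell grid (64x64
        cells), i.e. cell_size scaled proportionally from 16 px at 1024."""
        cell = max(2, round(side * 16 / 1024))
        while side % cell:
            cell -= 1
        return cls(orientations=orientations, cell_size=cell, input_side=side)


@dataclass
class MotionEnergySeries:
    """Mean absolute inter-frame pixel change within an ROI."""

    values: np.ndarray  # (n_frames - 1,)
    heatmap: np.ndarray | None = None  # per-pixel mean |delta| over a window


@dataclass
class EmbeddingResult:
    """2-D embedding of frames with k-means structure."""

    coords: np.ndarray  # (n, 2)
    labels: np.ndarray  # (n,)
    centers: np.ndarray  # (k, 2)
    pca_dims: int
    n_neighbors: int


def compute_hog(image: np.ndarray, config: HOGConfig) -> np.ndarray:
    """HOG descriptor of one grayscale frame.

    The image side must equal ``config.input_side`` (resize beforehand).
    Constant images yield the all-zero vector (no gradients anywhere).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("expected a square 2-D grayscale image")
    if image.shape[0] != config.input_side:
        raise ValueError(
            f"image side {image.shape[0]} != configured input_side {config.input_side}")
    vec = _sk_hog(
        image,
        orientations=config.orientations,
        pixels_per_cell=(config.cell_size, config.cell_size),
        cells_per_block=(config.cells_per_block, config.cells_per_block),
        block_norm="L2",
        feature_vector=True,
    )
    return vec.astype(np.float64)


def hog_matrix(frames: np.ndarray, config: HOGConfig | None = None) -> tuple[np.ndarray, HOGConfig]:
    """Stack HOG vectors for a (T, H, W) frame array."""
    if config is None:
        config = HOGConfig.for_canvas(frames.shape[1])
    out = np.empty((frames.shape[0], config.n_features))
    for i in range(frames.shape[0]):
        out[i] = compute_hog(frames[i], config)
    return out, config


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """cos(a, b) = a.b / (||a|| ||b||); raises on zero vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def _cosine_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    nx = np.linalg.norm(x, axis=1, keepdims=True)
    ny = np.linalg.norm(y, axis=1, keepdims=True)
    if np.any(nx == 0) or np.any(ny == 0):
        raise ValueError("cosine similarity undefined for a zero vector")
    return (x / nx) @ (y / ny).T


def motion_energy(frames: np.ndarray, roi: np.ndarray | None = None,
                  heatmap_window: slice | None = None) -> MotionEnergySeries:
    """Per-transition mean absolute pixel difference.

    ``roi`` is a boolean mask on the frame grid (None = whole frame);
    ``heatmap_window`` optionally selects which transitions enter the
    per-pixel mean |delta| heatmap (default: all).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.shape[0] < 2:
        raise ValueError("need at least two frames")
    if roi is None:
        roi = np.ones(frames.shape[1:], dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    diffs = np.abs(np.diff(frames, axis=0))
    values = diffs[:, roi].mean(axis=1)
    window = heatmap_window if heatmap_window is not None else slice(None)
    heatmap = diffs[window].mean(axis=0)
    return MotionEnergySeries(values=values, heatmap=heatmap)


def select_apex_frame(stim_hogs: np.ndarray, baseline_hogs: np.ndarray,
                      shortlist_k: int = 10) -> tuple[int, np.ndarray]:
    """Two-step apex selection.

    Step 1 ranks stimulus frames by mean cosine similarity to all *other*
    stimulus frames and keeps the top ``shortlist_k``; step 2 returns the
    shortlist member least similar (mean cosine) to the baseline frames.
    Ties break toward the earliest frame index.
    """
    stim_hogs = np.atleast_2d(np.asarray(stim_hogs, dtype=float))
    baseline_hogs = np.atleast_2d(np.asarray(baseline_hogs, dtype=float))
    n = stim_hogs.shape[0]
    if baseline_hogs.shape[0] < 1:
        raise ValueError("need at least one baseline frame")
    k = shortlist_k
    if n < k:
        warnings.warn(f"only {n} stimulus frames < shortlist_k={shortlist_k}; clamping")
        k = n

    sim = _cosine_matrix(stim_hogs, stim_hogs)
    np.fill_diagonal(sim, 0.0)
    within = sim.sum(axis=1) / max(n - 1, 1)
    order = np.lexsort((np.arange(n), -within))  # stable: score desc, index asc
    shortlist = np.sort(order[:k])

    to_base = _cosine_matrix(stim_hogs[shortlist], baseline_hogs).mean(axis=1)
    best = shortlist[np.lexsort((shortlist, to_base))[0]]
    return int(best), shortlist


def embed_expressions(hog_mat: np.ndarray, pca_dims: int = 400, n_neighbors: int = 45,
                      k: int = 4, seed: int = 0, min_dist: float = 0.1) -> EmbeddingResult:
    """PCA -> UMAP(2-D) -> k-means on the 2-D coordinates.

    ``pca_dims`` is clamped to min(n_frames - 1, n_features); ``n_neighbors``
    to n_frames - 1. k-means runs on the UMAP plane (cluster centers live in
    the visualization space); ``k`` is clamped when there are fewer distinct
    frames than clusters.
    """
    import umap  # deferred: numba compilation is slow at import time

    hog_mat = np.asarray(hog_mat, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    n = hog_mat.shape[0]
    dims = int(min(pca_dims, n - 1, hog_mat.shape[1]))
    x = PCA(n_components=dims, random_state=seed).fit_transform(hog_mat) if dims >= 1 else hog_mat
    nn = int(min(n_neighbors, n - 1))
    reducer = umap.UMAP(n_components=2, n_neighbors=max(nn, 2), min_dist=min_dist,
                        random_state=seed)
    coords = np.asarray(reducer.fit_transform(x), dtype=float)
    n_distinct = np.unique(np.round(coords, 9), axis=0).shape[0]
    k_eff = int(min(k, n_distinct))
    km = KMeans(n_clusters=k_eff, n_init=10, random_state=seed).fit(coords)
    return EmbeddingResult(coords=coords, labels=km.labels_, centers=km.cluster_centers_,
                           pca_dims=dims, n_neighbors=nn)


def pre_post_similarity(trial_hogs: np.ndarray, onset: int,
                        reference_window: tuple[int, int] | None = None,
                        post_window: tuple[int, int] | None = None,
                        normalize: bool = False):
    """Similarity of every frame to the mean pre-stimulus HOG.

    ``reference_window`` is a [start, stop) frame range preceding ``onset``
    (default: all frames before onset); the trough is the minimum similarity
    within ``post_window`` (default: everything from onset on). The
    normalized variant divides the trace by its mean over the reference
    window.

    Returns (trace, trough).
    """
    trial_hogs = np.asarray(trial_hogs, dtype=float)
    if reference_window is None:
        reference_window = (0, onset)
    r0, r1 = reference_window
    if not (0 <= r0 < r1 <= onset):
        raise ValueError("reference window must be non-empty and precede onset")
    if post_window is None:
        post_window = (onset, trial_hogs.shape[0])
    p0, p1 = post_window
    if p0 >= p1:
        raise ValueError("empty post window")

    ref = trial_hogs[r0:r1].mean(axis=0)
    trace = _cosine_matrix(trial_hogs, ref[None, :])[:, 0]
    if normalize:
        denom = trace[r0:r1].mean()
        if denom == 0:
            raise ValueError("pre-window mean similarity is zero; cannot normalize")
        trace = trace / denom
    trough = float(trace[p0:p1].min())
    return trace, trough


def save_hog_h5(path, hog_mat: np.ndarray, config: HOGConfig) -> None:
    """Cache a HOG matrix (frames x features) with its config as attributes."""
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("hog", data=np.asarray(hog_mat, dtype=np.float32),
                             compression="gzip")
        for k in ("orientations", "cell_size", "cells_per_block", "input_side"):
            d.attrs[k] = getattr(config, k)


def load_hog_h5(path) -> tuple[np.ndarray, HOGConfig]:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["hog"]
        cfg = HOGConfig(orientations=int(d.attrs["orientations"]),
                        cell_size=int(d.attrs["cell_size"]),
                        cells_per_block=int(d.attrs["cells_per_block"]),
                        input_side=int(d.attrs["input_side"]))
        return d[...].astype(np.float64), cfg
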