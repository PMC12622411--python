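"""Keypoint QC and facial-geometry kinematics.

The ten geometric features measured from the 37-point track:

- ``pupil_size``: distance between top and bottom pupil points;
- ``eye_opening``: distance between upper and lower eyelid points;
- ``mouth_inclination``: interior angle at the inner eye corner between the
  nostril and the anterior lower-lip edge (larger = more open mouth);
- ``snout_mouth_length``: nose tip to lower lip (smaller = retracted snout);
- ``nose_position``: nose tip to nose bridge (larger = extended nose);
- ``whisker_angle``: whisker base-to-tip direction vs the -x axis (smaller =
  protracted whiskers);
- ``ear_length``: posterior pinna edge to ear root;
- ``ear_angle``: ear-root -> posterior-pinna direction vs the +x axis
  (larger = raised ears);
- ``ear_width``: distance between the two mid-ear points;
- ``ear_fold``: interior angle at the posterior pinna edge between the ear
  root and the mid-ear point (smaller = more folded).

Image coordinates are y-down; angles are computed after converting to a y-up
mathematical frame, and directional angles are folded into [0, 180] degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from sklearn.decomposition import PCA

from .synthgen.render import KEYPOINT_NAMES

__all__ = [
    "GEOMETRY_FEATURES",
    "KeypointTrack",
    "ChangeScore",
    "qc_track",
    "compute_geometry",
    "change_from_baseline",
    "water_correct",
    "keypoint_pca",
    "response_latency",
    "read_dlc_csv",
]

GEOMETRY_FEATURES = (
    "pupil_size", "eye_opening", "mouth_inclination", "snout_mouth_length",
    "nose_position", "whisker_angle", "ear_length", "ear_angle", "ear_width", "ear_fold",
)


@dataclass
class KeypointTrack:
    """Per-frame named keypoints with confidences.

    ``xy``: (T, K, 2) image coordinates; ``confidence``: (T, K) in [0, 1];
    ``names``: K keypoint names mapping into the six facial regions.
    """

    xy: np.ndarray
    confidence: np.ndarray
    names: list[str] = field(default_factory=lambda: list(KEYPOINT_NAMES))
    fps: float = 30.0

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.xy.shape[:2] != self.confidence.shape:
            raise ValueError("xy and confidence shapes disagree")
        if np.nanmin(self.confidence, initial=1.0) < 0 or np.nanmax(self.confidence, initial=0.0) > 1:
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def point(self, name: str) -> np.ndarray:
        return self.xy[:, self.index(name), :]


def read_dlc_csv(path, fps: float = 30.0) -> KeypointTrack:
    """Read a pose-estimation CSV in the three-header-row dialect."""
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
    t = len(df)
    xy = np.empty((t, len(bodyparts), 2))
    conf = np.empty((t, len(bodyparts)))
    scorer = df.columns.get_level_values(0)[0]
    for k, bp in enumerate(bodyparts):
        xy[:, k, 0] = df[(scorer, bp, "x")].to_numpy()
        xy[:, k, 1] = df[(scorer, bp, "y")].to_numpy()
        conf[:, k] = df[(scorer, bp, "likelihood")].to_numpy()
    return KeypointTrack(xy=xy, confidence=conf, names=bodyparts, fps=fps)


def _interp_series(x: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linear interpolation over invalid samples; edge gaps held at nearest."""
    out = x.copy()
    idx = np.arange(len(x))
    if valid.all():
        return out
    out[~valid] = np.interp(idx[~valid], idx[valid], x[valid])
    return out


def qc_track(track: KeypointTrack, conf_threshold: float = 0.9,
             median_window: int = 5) -> KeypointTrack:
    """Confidence filtering and median smoothing.

    Coordinates with confidence below ``conf_threshold`` are replaced by
    linear interpolation between the nearest flanking confident frames (edge
    gaps held at the nearest confident value), then every coordinate series
    is smoothed with a centered ``median_window``-frame median filter.
    Keypoints with no confident frame at all are dropped (set to NaN) with a
    warning. Cleaned confidences are 1, which makes the operation idempotent
    up to repeated median filtering.
    """
    if median_window % 2 == 0:
        raise ValueError("median_window must be odd")
    xy = track.xy.copy()
    conf = np.ones_like(track.confidence)
    for k in range(xy.shape[1]):
        valid = track.confidence[:, k] >= conf_threshold
        if not valid.any():
            warnings.warn(f"keypoint {track.names[k]!r} has no confident frames; dropping")
            xy[:, k, :] = np.nan
            conf[:, k] = 0.0
            continue
        for c in range(2):
            series = _interp_series(xy[:, k, c], valid)
            xy[:, k, c] = median_filter(series, size=median_window, mode="nearest")
    return replace(track, xy=xy, confidence=conf)


def _yup(p: np.ndarray) -> np.ndarray:
    return np.stack([p[..., 0], -p[..., 1]], axis=-1)


def _dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.linalg.norm(a - b, axis=-1)


def _interior_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Interior angle at vertex b of the triplet (a, b, c), degrees."""
    u, v = a - b, c - b
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (u * v).sum(-1) / (nu * nv)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ang[(nu == 0) | (nv == 0)] = np.nan
    return ang


def _directional_angle(vec_yup: np.ndarray, axis: np.ndarray, signed: bool = False) -> np.ndarray:
    """Angle of y-up vectors vs a reference axis, folded into [0, 180]."""
    ang = np.degrees(np.arctan2(vec_yup[..., 1], vec_yup[..., 0])
                     - np.arctan2(axis[1], axis[0]))
    ang = (ang + 180.0) % 360.0 - 180.0
    ang[np.linalg.norm(vec_yup, axis=-1) == 0] = np.nan
    return ang if signed else np.abs(ang)


def compute_geometry(track: KeypointTrack, whisker: int = 1,
                     signed_angles: bool = False) -> pd.DataFrame:
    """Per-frame values of the ten geometric features.

    Frames with degenerate (coincident) defining points yield NaN for the
    affected feature. ``signed_angles`` reports directional angles in
    (-180, 180] instead of folding into [0, 180].
    """
    p = {n: track.point(n) for n in track.names}
    yup = {n: _yup(v) for n, v in p.items()}

    out = pd.DataFrame(index=np.arange(track.n_frames))
    out["pupil_size"] = _dist(p["pupil_top"], p["pupil_bottom"])
    out["eye_opening"] = _dist(p["eye_top"], p["eye_bottom"])
    out["mouth_inclination"] = _interior_angle(
        yup["nostril_bottom"], yup["eye_inner_corner"], yup["lower_lip_anterior"])
    out["snout_mouth_length"] = _dist(p["nose_tip"], p["lower_lip_anterior"])
    out["nose_position"] = _dist(p["nose_tip"], p["nose_bridge"])
    wv = yup[f"whisker{whisker}_3"] - yup[f"whisker{whisker}_0"]
    out["whisker_angle"] = _directional_angle(wv, np.array([-1.0, 0.0]), signed_angles)
    out["ear_length"] = _dist(p["pinna_posterior_edge"], p["ear_root"])
    ev = yup["pinna_posterior_edge"] - yup["ear_root"]
    out["ear_angle"] = _directional_angle(ev, np.array([1.0, 0.0]), signed_angles)
    out["ear_width"] = _dist(p["mid_ear_a"], p["mid_ear_b"])
    out["ear_fold"] = _interior_angle(
        yup["ear_root"], yup["pinna_posterior_edge"], yup["mid_ear_a"])
    return out


@dataclass
class ChangeScore:
    """Baseline-relative proportional change of one feature in one trial."""

    value: float  # peak (signed extremum) proportional change
    baseline: float
    timecourse: np.ndarray | None = None  # per-frame proportional change
    flagged: bool = False  # True when baseline == 0 (value undefined)


def change_from_baseline(series: np.ndarray, onset: int, fps: float,
                         mode: str = "peak", baseline_s: float = 4.0,
                         window_s: float | None = None) -> ChangeScore:
    """Proportional change relative to the pre-stimulus baseline.

    Baseline is the mean over the ``baseline_s`` (default 4 s) window before
    ``onset`` (a frame index). ``mode='peak'`` reports the signed extremum
    (largest absolute change) within the post-onset window of ``window_s``
    seconds (default: to the end of the series); ``mode='timecourse'`` keeps
    the per-frame trace in ``timecourse`` as well.
    """
    series = np.asarray(series, dtype=float)
    nb = int(round(baseline_s * fps))
    if onset < nb:
        raise ValueError(f"need {baseline_s} s of pre-stimulus data ({nb} frames)")
    baseline = float(np.nanmean(series[onset - nb:onset]))
    if baseline == 0.0 or not np.isfinite(baseline):
        return ChangeScore(value=np.nan, baseline=baseline, flagged=True)
    change = (series - baseline) / baseline
    stop = len(series) if window_s is None else min(len(series), onset + int(round(window_s * fps)))
    post = change[onset:stop]
    finite = post[np.isfinite(post)]
    if finite.size == 0:
        return ChangeScore(value=np.nan, baseline=baseline, flagged=True)
    peak = float(finite[np.argmax(np.abs(finite))])
    return ChangeScore(value=peak, baseline=baseline,
                       timecourse=change if mode == "timecourse" else None)


def water_correct(changes: pd.DataFrame, feature_cols: list[str] | None = None) -> pd.DataFrame:
    """Subtract the temporally nearest water trial's change, per feature.

    ``changes`` must have columns ``stimulus``, ``onset_s`` and one column
    per feature (trial rows). Equidistant water trials break toward the
    earlier one. Raises when the session has no water trial.
    """
    if feature_cols is None:
        feature_cols = [c for c in changes.columns if c in GEOMETRY_FEATURES]
    water = changes[changes["stimulus"] == "water"]
    if len(water) == 0:
        raise ValueError("no water control trials in session")
    w_onsets = water["onset_s"].to_numpy(dtype=float)
    out = changes.copy()
    for i, row in changes.iterrows():
        d = np.abs(w_onsets - float(row["onset_s"]))
        # ties toward the earlier water trial: stable argmin over (distance, onset)
        j = np.lexsort((w_onsets, d))[0]
        out.loc[i, feature_cols] = (
            row[feature_cols].astype(float) - water.iloc[j][feature_cols].astype(float))
    return out


def keypoint_pca(trial_tensor: np.ndarray, z_score: bool = True):
    """PCA of per-trial keypoint feature vectors.

    ``trial_tensor``: (n_trials, n_features) with keypoint x/y columns.
    Columns are z-scored first (the convention for keypoint PCA here);
    zero-variance columns are dropped with a warning.

    Returns (components, explained_variance_ratio, kept_columns).
    """
    x = np.asarray(trial_tensor, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D array with at least two trials")
    keep = np.arange(x.shape[1])
    if z_score:
        sd = x.std(axis=0, ddof=0)
        zero = sd == 0
        if zero.any():
            warnings.warn(f"dropping {int(zero.sum())} zero-variance columns before PCA")
            keep = np.flatnonzero(~zero)
            x = x[:, keep]
            sd = sd[keep]
        x = (x - x.mean(axis=0)) / sd
    n_comp = min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp)
    pca.fit(x)
    return pca.components_, pca.explained_variance_ratio_, keep


def response_latency(series: np.ndarray, onset: int, fps: float,
                     threshold_sd: float = 2.0, sustain_frames: int = 3,
                     baseline_s: float = 4.0,
                     abs_fallback: float = 1e-6) -> tuple[float, bool]:
    """First sustained threshold crossing after onset, in seconds.

    The deviation from the baseline mean must exceed ``threshold_sd`` baseline
    standard deviations for at least ``sustain_frames`` consecutive frames.
    Returns (latency_s, flagged); latency is NaN when never crossed, and
    ``flagged`` marks the zero-baseline-SD absolute-threshold fallback.
    """
    series = np.asarray(series, dtype=float)
    nb = int(round(baseline_s * fps))
    if onset < nb:
        raise ValueError("baseline window unavailable")
    base = series[onset - nb:onset]
    mu, sd = float(np.nanmean(base)), float(np.nanstd(base))
    flagged = sd == 0.0
    thr = threshold_sd * sd if not flagged else abs_fallback
    dev = np.abs(series[onset:] - mu) > thr
    run = 0
    for i, hit in enumerate(dev):
        run = run + 1 if hit else 0
        if run >= sustain_frames:
            return (i - sustain_frames + 1) / fps, flagged
    return float("nan"), flagged
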