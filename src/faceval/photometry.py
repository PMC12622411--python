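"""Dual-channel fiber-photometry processing and neural-facial coupling.

Pipeline: (1) photobleaching removal per channel with adaptive iteratively
reweighted penalized least squares (airPLS); (2) motion correction by
ordinary least-squares fit of the detrended 410 nm isosbestic control onto
the detrended 470 nm calcium signal, with dF/F = (signal - fitted control) /
fitted control; (3) event-aligned PSTHs with 4 s pre-stimulus baseline
subtraction; (4) per-stimulus peak ratios against the neutral water
response; (5) Spearman correlation between the z-scored neural signal and
the facial valence-similarity readout on a shared 15 Hz clock, tested with a
one-sided permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.stats import spearmanr

from .synthgen.photosim import PhotometryRecording

__all__ = [
    "CorrectedTrace",
    "PSTHResult",
    "ShuffleCorrResult",
    "airpls_baseline",
    "motion_correct",
    "process_recording",
    "compute_psth",
    "peak_ratio_vs_water",
    "resample_to_rate",
    "neural_facial_correlation",
]


def airpls_baseline(trace: np.ndarray, lam: float = 1e8, max_iter: int = 50,
                    tol: float = 1e-3) -> tuple[np.ndarray, bool]:
    """Adaptive iteratively reweighted penalized least squares baseline.

    Fits a smooth Whittaker baseline whose weights shrink exponentially where
    the trace exceeds the current baseline, so positive transients are
    ignored while slow drift is followed. ``lam`` controls smoothness
    (default 1e8 at 15 Hz). Returns (baseline, converged).
    """
    y = np.asarray(trace, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("trace too short for baseline estimation")
    d = sparse.eye(n, format="csc")
    d = d[1:] - d[:-1]
    d = d[1:] - d[:-1]  # second difference
    h = lam * (d.T @ d)
    w = np.ones(n)
    z = y
    for i in range(1, max_iter + 1):
        w_mat = sparse.diags(w, 0, shape=(n, n), format="csc")
        z = spsolve(w_mat + h, w * y)
        resid = y - z
        neg = resid < 0
        dssn = float(np.abs(resid[neg].sum()))
        if dssn < tol * np.abs(y).sum():
            return z, True
        # points above the baseline (transients) get zero weight; points
        # below get exponentially growing weights with iteration number
        w[~neg] = 0.0
        w[neg] = np.exp(i * np.abs(resid[neg]) / dssn)
        edge = np.exp(i * np.abs(resid[neg]).max() / dssn) if neg.any() else 1.0
        w[0] = edge
        w[-1] = edge
    return z, False


@dataclass
class CorrectedTrace:
    """Detrended channels, fitted control and dF/F."""

    time_s: np.ndarray
    f470_detrended: np.ndarray
    f410_detrended: np.ndarray
    fitted_control: np.ndarray
    dff: np.ndarray
    rate_hz: float = 15.0
    events: pd.DataFrame | None = None
    regression: tuple[float, float] = (np.nan, np.nan)  # slope, intercept
    flagged: bool = False  # degenerate 410 regression fallback


def motion_correct(f470: np.ndarray, f410: np.ndarray, time_s: np.ndarray | None = None,
                   rate_hz: float = 15.0, events: pd.DataFrame | None = None,
                   offset: float | None = None) -> CorrectedTrace:
    """OLS fit of the 410 nm control onto the 470 nm signal, then dF/F.

    ``corrected = f470 - (a*f410 + b)`` and ``dff = corrected / fitted``;
    ``offset`` shifts both detrended channels before the fit (used by
    :func:`process_recording` to keep the fitted control away from zero
    after detrending). A constant 410 channel degrades the regression to a
    mean-only fit, flagged on the result.
    """
    f470 = np.asarray(f470, dtype=float)
    f410 = np.asarray(f410, dtype=float)
    if f470.shape != f410.shape:
        raise ValueError("channel length mismatch")
    if offset is not None:
        f470 = f470 + offset
        f410 = f410 + offset
    flagged = False
    if np.ptp(f410) == 0.0:
        warnings.warn("constant 410 nm channel; falling back to mean-only fit")
        a, b = 0.0, float(f470.mean())
        flagged = True
    else:
        a, b = np.polyfit(f410, f470, 1)
    fitted = a * f410 + b
    corrected = f470 - fitted
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = np.where(fitted != 0.0, corrected / fitted, np.nan)
    if time_s is None:
        time_s = np.arange(len(f470)) / rate_hz
    return CorrectedTrace(time_s=np.asarray(time_s, float), f470_detrended=f470,
                          f410_detrended=f410, fitted_control=fitted, dff=dff,
                          rate_hz=rate_hz, events=events, regression=(float(a), float(b)),
                          flagged=flagged)


def process_recording(rec: PhotometryRecording, lam: float = 1e8,
                      max_iter: int = 50) -> CorrectedTrace:
    """Full pipeline on a recording: airPLS detrend both channels, then
    motion-correct. The detrended channels are re-anchored at the mean raw
    470 level so dF/F keeps a physiological denominator."""
    base470, _ = airpls_baseline(rec.f470, lam=lam, max_iter=max_iter)
    base410, _ = airpls_baseline(rec.f410, lam=lam, max_iter=max_iter)
    det470 = rec.f470 - base470
    det410 = rec.f410 - base410
    return motion_correct(det470, det410, time_s=rec.time_s, rate_hz=rec.rate_hz,
                          events=rec.events, offset=float(np.mean(rec.f470)))


@dataclass
class PSTHResult:
    """Event-aligned, baseline-subtracted responses."""

    times: np.ndarray  # (n_samples,), 0 = event onset
    trials: np.ndarray  # (n_events, n_samples), baseline-subtracted dF/F
    mean: np.ndarray
    peaks: np.ndarray  # per-trial maximum in the post window
    peak_times: np.ndarray
    stimuli: list[str] = field(default_factory=list)


def compute_psth(dff: np.ndarray, events: pd.DataFrame, rate_hz: float = 15.0,
                 pre_s: float = 4.0, post_s: float = 6.0) -> PSTHResult:
    """Per-trial baseline subtraction (mean of ``pre_s`` pre-onset) and mean PSTH.

    Every event must have a full pre window; overlapping trial windows only
    warn. The per-trial peak is the maximum within (0, post_s].
    """
    dff = np.asarray(dff, dtype=float)
    n_pre = int(round(pre_s * rate_hz))
    n_post = int(round(post_s * rate_hz))
    onsets = events["onset_s"].to_numpy(dtype=float)
    idx = np.round(onsets * rate_hz).astype(int)
    if np.any(idx - n_pre < 0) or np.any(idx + n_post > len(dff)):
        raise ValueError("an event lacks a full pre/post window")
    if len(idx) > 1 and np.any(np.diff(np.sort(idx)) < n_pre + n_post):
        warnings.warn("event windows overlap; trials kept")
    trials = np.stack([dff[i - n_pre:i + n_post] for i in idx])
    trials = trials - trials[:, :n_pre].mean(axis=1, keepdims=True)
    times = (np.arange(n_pre + n_post) - n_pre) / rate_hz
    post = trials[:, n_pre:]
    peaks = post.max(axis=1)
    peak_times = times[n_pre:][post.argmax(axis=1)]
    stimuli = list(events["stimulus"]) if "stimulus" in events else []
    return PSTHResult(times=times, trials=trials, mean=trials.mean(axis=0),
                      peaks=peaks, peak_times=peak_times, stimuli=stimuli)


def peak_ratio_vs_water(stimulus_peaks: np.ndarray, water_peaks: np.ndarray) -> float:
    """Mean stimulus peak divided by mean water peak (water peak must be > 0)."""
    sp = np.asarray(stimulus_peaks, dtype=float)
    wp = np.asarray(water_peaks, dtype=float)
    if wp.size == 0 or wp.mean() <= 0:
        raise ValueError("nonpositive or missing water peak; ratio undefined")
    return float(sp.mean() / wp.mean())


def resample_to_rate(values: np.ndarray, src_hz: float, dst_hz: float) -> np.ndarray:
    """Map a series to a slower clock by averaging consecutive sample groups
    (30 fps facial similarity -> 15 Hz neural clock uses frame-pair means)."""
    ratio = src_hz / dst_hz
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError("source rate must be an integer multiple of target rate")
    r = int(round(ratio))
    n = (len(values) // r) * r
    return np.asarray(values, dtype=float)[:n].reshape(-1, r).mean(axis=1)


@dataclass
class ShuffleCorrResult:
    observed_rho: float
    p_value: float
    null_distribution: np.ndarray
    n_shuffles: int
    seed: int
    n_points: int


def neural_facial_correlation(z_dff: np.ndarray, similarity: np.ndarray,
                              events: pd.DataFrame, rate_hz: float = 15.0,
                              window_s: float = 2.0, n_shuffles: int = 1000,
                              seed: int = 0, mode: str = "permute") -> ShuffleCorrResult:
    """Rank correlation between neural and facial readouts in event windows.

    Both inputs must share the ``rate_hz`` clock and be z-scored across the
    session. All samples within the ``window_s`` post-onset window of every
    event are pooled; Spearman's rho is computed; the null permutes (or
    circularly shifts, ``mode='shift'``) the facial samples within each
    window; one-sided p = (1 + #{null >= observed}) / (1 + n_shuffles).
    """
    z_dff = np.asarray(z_dff, dtype=float)
    sim = np.asarray(similarity, dtype=float)
    if z_dff.shape != sim.shape:
        raise ValueError("series must share the same clock and length")
    nw = int(round(window_s * rate_hz))
    windows = []
    for onset in events["onset_s"].to_numpy(dtype=float):
        i0 = int(round(onset * rate_hz))
        i1 = min(i0 + nw, len(sim))
        if i1 > i0:
            windows.append((i0, i1))
    pooled_n = np.concatenate([z_dff[i0:i1] for i0, i1 in windows])
    pooled_f = np.concatenate([sim[i0:i1] for i0, i1 in windows])
    if pooled_n.size < 10:
        raise ValueError("fewer than 10 pooled samples")
    rho = float(spearmanr(pooled_n, pooled_f).statistic)

    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    segments = [sim[i0:i1].copy() for i0, i1 in windows]
    for s in range(n_shuffles):
        parts = []
        for seg in segments:
            if mode == "permute":
                parts.append(rng.permutation(seg))
            elif mode == "shift":
                parts.append(np.roll(seg, rng.integers(1, len(seg)) if len(seg) > 1 else 0))
            else:
                raise ValueError("mode must be 'permute' or 'shift'")
        null[s] = spearmanr(pooled_n, np.concatenate(parts)).statistic
    p = (1.0 + np.sum(null >= rho)) / (1.0 + n_shuffles)
    return ShuffleCorrResult(observed_rho=rho, p_value=float(p), null_distribution=null,
                             n_shuffles=n_shuffles, seed=seed, n_points=int(pooled_n.size))
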