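"""Trial dynamics: phenotype trajectories and rendered frame stacks.

Each phenotype field follows baseline -> latency-delayed saturating rise
toward (baseline + stimulus offset) during stimulation -> exponential return
after stimulus offset, plus optional white frame noise. The whisker response
is the fastest (0.1 s latency), ear/mouth/snout intermediate (0.3 s), pupil
slowest (1.0 s), emulating the latency ordering of real facial reactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phenotype import (
    PHENOTYPE_FIELDS,
    STIMULI,
    VALENCE_OF,
    FacePhenotype,
    SyntheticCohortSpec,
    ValenceEffectSpec,
)
from .render import KEYPOINT_NAMES, render_face

__all__ = ["TrialSegment", "simulate_trial", "feature_envelope"]


@dataclass
class TrialSegment:
    """One simulated trial: frames, ground truth, and event metadata."""

    frames: np.ndarray  # (T, H, W) float32
    keypoints: np.ndarray  # (T, 37, 2) image coordinates
    features: pd.DataFrame  # (T, 10) ground-truth phenotype trajectories
    times: np.ndarray  # (T,) seconds, 0 = stimulus onset
    stimulus: str
    valence: str
    onset_s: float  # within-trial onset (== pre window)
    duration_s: float
    mouse_id: str = "m0"
    trial_id: str = "t0"

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def feature_envelope(times: np.ndarray, latency_s: float, duration_s: float,
                     rise_tau_s: float, decay_s: float) -> np.ndarray:
    """Normalized response envelope g(t) in [0, 1]; t is time from onset."""
    g = np.zeros_like(times, dtype=float)
    t = times - latency_s
    rising = (t >= 0) & (times <= duration_s)
    g[rising] = 1.0 - np.exp(-t[rising] / rise_tau_s)
    after = times > duration_s
    if np.any(after):
        t_end = duration_s - latency_s
        g_end = (1.0 - np.exp(-t_end / rise_tau_s)) if t_end > 0 else 0.0
        g[after] = g_end * np.exp(-(times[after] - duration_s) / decay_s)
    return g


def simulate_trial(
    base: FacePhenotype,
    effects: ValenceEffectSpec,
    stimulus: str,
    spec: SyntheticCohortSpec,
    rng: np.random.Generator,
    render: bool = True,
) -> TrialSegment:
    """Simulate one stimulus trial of ``pre + stimulus + post`` duration.

    Parameters
    ----------
    base
        Baseline phenotype of this mouse (already at canvas scale).
    effects
        Stimulus effect specification; offsets are scaled internally to the
        canvas of ``spec``.
    stimulus
        One of :data:`~faceval.synthgen.STIMULI`.
    rng
        Numpy generator; the sole source of randomness (frame noise).
    render
        When False, skip rasterization and return only keypoints/features
        (frames has shape (T, 0, 0)); useful for keypoint-only analyses.
    """
    if stimulus not in STIMULI:
        raise ValueError(f"unknown stimulus {stimulus!r}; expected one of {STIMULI}")
    n = spec.trial_n_frames
    times = np.arange(n) / spec.fps - spec.pre_window_s
    offs = effects.scaled(spec.canvas_scale).effect_vector(stimulus)
    from .phenotype import _ANGLE_FIELDS
    scale_vec = np.array([1.0 if f in _ANGLE_FIELDS else spec.canvas_scale
                          for f in PHENOTYPE_FIELDS])
    sigma = effects.frame_noise * effects.field_sigma() * scale_vec

    traj = np.empty((n, len(PHENOTYPE_FIELDS)))
    base_vec = base.as_vector()
    for j, f in enumerate(PHENOTYPE_FIELDS):
        g = feature_envelope(times, effects.latency_s[f], spec.stimulus_duration_s,
                             effects.rise_tau_s, effects.decay_s)
        traj[:, j] = base_vec[j] + offs[j] * g
    if effects.frame_noise > 0:
        traj += rng.normal(0.0, 1.0, traj.shape) * sigma

    kps = np.empty((n, 37, 2))
    if render:
        frames = np.empty((n, spec.frame_size, spec.frame_size), dtype=np.float32)
    else:
        frames = np.empty((n, 0, 0), dtype=np.float32)
    for t in range(n):
        ph = FacePhenotype.from_vector(traj[t])
        if render:
            frames[t], kps[t] = render_face(ph, spec.frame_size)
        else:
            from .render import _construct_keypoints  # construction only
            pts = _construct_keypoints(ph, spec.canvas_scale)
            kps[t] = [[pts[nm][0], (spec.frame_size - 1) - pts[nm][1]] for nm in KEYPOINT_NAMES]

    features = pd.DataFrame(traj, columns=list(PHENOTYPE_FIELDS))
    features.insert(0, "time_s", times)
    return TrialSegment(
        frames=frames, keypoints=kps, features=features, times=times,
        stimulus=stimulus, valence=VALENCE_OF[stimulus],
        onset_s=spec.pre_window_s, duration_s=spec.stimulus_duration_s,
    )
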