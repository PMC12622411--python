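"""Shared fixtures: small synthetic cohorts generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from faceval.synthgen import (
    FacePhenotype,
    SyntheticCohortSpec,
    ValenceEffectSpec,
    build_cohort,
    render_face,
)


@pytest.fixture(scope="session")
def default_face():
    """Default phenotype rendered at 256 px with its ground-truth keypoints."""
    img, kp = render_face(FacePhenotype(), 256)
    return img, kp


@pytest.fixture(scope="session")
def clean_cohort():
    """3 mice x 1 trial/stimulus, zero frame noise, zero latency: every
    stimulus frame carries the full effect (separable by construction)."""
    spec = SyntheticCohortSpec(n_mice=3, trials_per_stimulus=1, frame_size=128,
                               seed=11, pre_window_s=1.0, post_window_s=1.0)
    eff = ValenceEffectSpec(frame_noise=0.0)
    eff.latency_s = {k: 0.0 for k in eff.latency_s}
    eff.rise_tau_s = 1e-6
    return build_cohort(spec, eff)


@pytest.fixture(scope="session")
def noisy_cohort():
    """4 mice x 2 trials/stimulus with default noise/latency dynamics."""
    spec = SyntheticCohortSpec(n_mice=4, trials_per_stimulus=2, frame_size=128,
                               seed=7, pre_window_s=1.0, post_window_s=1.0)
    return build_cohort(spec, ValenceEffectSpec())


@pytest.fixture(scope="session")
def keypoint_cohort():
    """Keypoints-only cohort (no rasterization): 5 mice x 4 trials/stimulus."""
    spec = SyntheticCohortSpec(n_mice=5, trials_per_stimulus=4, frame_size=256,
                               seed=5, pre_window_s=4.0, post_window_s=2.0)
    return build_cohort(spec, ValenceEffectSpec(), render=False)


@pytest.fixture(scope="session")
def ear_only_cohort():
    """Class signal confined to the ear: all non-ear offsets are zero.

    Classes remain mutually distinguishable through distinct ear-field
    offsets only; used by the saliency/occlusion ground-truth checks.
    """
    eff = ValenceEffectSpec(frame_noise=0.2)
    for stim, d in eff.effects.items():
        for f in list(d):
            if not f.startswith("ear"):
                d[f] = 0.0
    # keep the pupil-dilation invariant satisfied by a tiny uniform offset
    for stim in ("sucrose", "NaCl", "bitterness", "shock"):
        eff.effects[stim]["pupil_diameter"] = 0.2
    eff.latency_s = {k: 0.0 for k in eff.latency_s}
    eff.rise_tau_s = 1e-6
    spec = SyntheticCohortSpec(n_mice=3, trials_per_stimulus=2, frame_size=128,
                               seed=21, pre_window_s=0.0, post_window_s=0.0,
                               stimulus_duration_s=1.0)
    return build_cohort(spec, eff)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
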