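"""Synthetic dual-channel fiber-photometry traces.

The 470 nm channel carries slow photobleaching (decaying exponential), a
motion artifact shared with the 410 nm isosbestic channel, white noise, and
per-event calcium transients (instant rise, exponential decay) whose
amplitudes follow the tuning of the recorded population:

- ``DA`` (dopaminergic): positive-valence-tuned, sucrose > NaCl > water >
  bitterness/shock;
- ``GABA``: negative-valence-tuned, shock/bitterness > water > sucrose/NaCl;
- ``Glu`` (glutamatergic): arousal-tuned, {sucrose, shock} > {NaCl,
  bitterness};
- ``pan`` (pan-neuronal): equal amplitude for every stimulus.

The 410 nm channel is a scaled copy of the bleaching trend plus the same
motion artifact and independent noise, with no transients. Both channels are
sampled on a shared 15 Hz clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PhotometryRecording", "TRANSIENT_AMPLITUDE", "simulate_photometry"]

#: Relative transient amplitude (ΔF units) per neuron type and stimulus.
TRANSIENT_AMPLITUDE = {
    "DA": {"sucrose": 1.0, "NaCl": 0.7, "water": 0.4, "bitterness": 0.15, "shock": 0.12},
    "GABA": {"shock": 1.0, "bitterness": 0.9, "water": 0.45, "sucrose": 0.15, "NaCl": 0.18},
    "Glu": {"sucrose": 0.9, "shock": 0.85, "NaCl": 0.45, "bitterness": 0.4, "water": 0.45},
    "pan": {s: 0.5 for s in ("sucrose", "NaCl", "bitterness", "shock", "water")},
}


@dataclass
class PhotometryRecording:
    """Paired 470/410 nm traces with stimulus events at 15 Hz per channel."""

    time_s: np.ndarray
    f470: np.ndarray
    f410: np.ndarray
    events: pd.DataFrame  # columns: onset_s, stimulus (and optionally more)
    rate_hz: float = 15.0
    neuron_type: str = "DA"
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.f470) != len(self.f410) or len(self.f470) != len(self.time_s):
            raise ValueError("time and channel arrays must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "f470": self.f470, "f410": self.f410})


def simulate_photometry(
    neuron_type: str,
    events: pd.DataFrame,
    duration_s: float | None = None,
    rate_hz: float = 15.0,
    rng: np.random.Generator | None = None,
    f0: float = 100.0,
    bleach_tau_s: float = 600.0,
    bleach_frac: float = 0.3,
    transient_scale: float = 8.0,
    transient_tau_s: float = 1.5,
    artifact_sd: float = 1.5,
    noise_sd: float = 0.3,
    isosbestic_gain: float = 0.6,
) -> PhotometryRecording:
    """Simulate one photometry session.

    ``events`` needs columns ``onset_s`` and ``stimulus``. The shared motion
    artifact is smooth low-pass noise added identically to both channels;
    ``transient_scale`` converts the relative amplitude table to raw
    fluorescence units.
    """
    if neuron_type not in TRANSIENT_AMPLITUDE:
        raise ValueError(f"unknown neuron_type {neuron_type!r}; "
                         f"expected one of {sorted(TRANSIENT_AMPLITUDE)}")
    if len(events) == 0:
        raise ValueError("events must be non-empty")
    rng = np.random.default_rng(0) if rng is None else rng

    if duration_s is None:
        duration_s = float(events["onset_s"].max()) + 20.0
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz

    bleach = f0 * ((1.0 - bleach_frac) + bleach_frac * np.exp(-t / bleach_tau_s))

    # Smooth shared motion artifact: white noise filtered by a moving average.
    if artifact_sd > 0:
        raw = rng.normal(0.0, 1.0, n + 30)
        kernel = np.hanning(31)
        kernel /= kernel.sum()
        art = np.convolve(raw, kernel, mode="valid")[:n]
        sd = art.std()
        art = artifact_sd * (art / sd) if sd > 0 else np.zeros(n)
    else:
        art = np.zeros(n)

    transients = np.zeros(n)
    amp_table = TRANSIENT_AMPLITUDE[neuron_type]
    for _, ev in events.iterrows():
        stim = ev["stimulus"]
        if stim not in amp_table:
            raise ValueError(f"unknown stimulus {stim!r} in events")
        i0 = int(round(float(ev["onset_s"]) * rate_hz))
        if i0 >= n:
            continue
        amp = transient_scale * amp_table[stim]
        dt = t[i0:] - t[i0]
        transients[i0:] += amp * np.exp(-dt / transient_tau_s)

    f470 = bleach + art + transients + rng.normal(0.0, noise_sd, n)
    f410 = isosbestic_gain * bleach + art + rng.normal(0.0, noise_sd, n)

    return PhotometryRecording(
        time_s=t, f470=f470, f410=f410, events=events.reset_index(drop=True),
        rate_hz=rate_hz, neuron_type=neuron_type,
        ground_truth={
            "bleach": bleach, "artifact": art, "transients": transients,
            "amp_table": dict(amp_table), "transient_scale": transient_scale,
        },
    )
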