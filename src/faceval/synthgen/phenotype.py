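"""Phenotype and cohort parameter containers.

All lengths are in pixels on the configured canvas and all angles in degrees,
measured in a y-up mathematical frame (image rows are flipped once at render
time). Directional angles live in [0, 180]; the ear angle is measured from
the +x axis, the whisker angle from the -x axis (the mouse faces -x).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

#: The five stimulus labels used throughout the package. "water" is the
#: neutral control delivered through the same spout.
STIMULI = ("sucrose", "NaCl", "bitterness", "shock", "water")

#: Valence grouping of the stimuli: appetitive tastants are positive,
#: aversive tastant and tail shock negative, water neutral.
VALENCE_OF = {
    "sucrose": "positive",
    "NaCl": "positive",
    "bitterness": "negative",
    "shock": "negative",
    "water": "neutral",
}

#: Phenotype fields, in a fixed order shared by effect vectors and noise.
PHENOTYPE_FIELDS = (
    "ear_angle",
    "ear_length",
    "ear_width",
    "ear_fold",
    "whisker_angle",
    "mouth_inclination",
    "snout_mouth_length",
    "nose_extension",
    "pupil_diameter",
    "eye_opening",
)

_ANGLE_FIELDS = frozenset({"ear_angle", "ear_fold", "whisker_angle", "mouth_inclination"})


@dataclass(frozen=True)
class FacePhenotype:
    """Ten interpretable geometric quantities of the schematic face.

    Defaults describe a relaxed, neutral face on a 256-px canvas; lengths
    scale linearly with canvas size via :meth:`scaled`.
    """

    ear_angle: float = 60.0  # deg, pinna vector vs +x axis
    ear_length: float = 55.0  # px, ear root -> posterior pinna edge
    ear_width: float = 30.0  # px, between the two mid-ear points
    ear_fold: float = 35.0  # deg, interior angle at the posterior pinna edge
    whisker_angle: float = 25.0  # deg vs -x axis; smaller = protracted
    mouth_inclination: float = 21.0  # deg at the inner eye corner
    snout_mouth_length: float = 52.0  # px, nose tip -> lower lip
    nose_extension: float = 28.0  # px, nose tip -> nose bridge
    pupil_diameter: float = 14.0  # px
    eye_opening: float = 20.0  # px, upper -> lower eyelid

    def validate(self) -> None:
        for name in PHENOTYPE_FIELDS:
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if name in _ANGLE_FIELDS:
                if not 0.0 <= v <= 180.0:
                    raise ValueError(f"{name} must lie in [0, 180] deg, got {v}")
            elif v <= 0.0:
                raise ValueError(f"{name} must be > 0, got {v}")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in PHENOTYPE_FIELDS], dtype=float)

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "FacePhenotype":
        return cls(**dict(zip(PHENOTYPE_FIELDS, map(float, vec))))

    def shifted(self, offsets: dict[str, float] | np.ndarray) -> "FacePhenotype":
        """Return a copy with per-field additive offsets applied."""
        if isinstance(offsets, dict):
            vec = self.as_vector() + np.array(
                [offsets.get(f, 0.0) for f in PHENOTYPE_FIELDS], dtype=float
            )
        else:
            vec = self.as_vector() + np.asarray(offsets, dtype=float)
        return FacePhenotype.from_vector(vec)

    def scaled(self, factor: float) -> "FacePhenotype":
        """Scale all length fields by ``factor`` (angles unchanged)."""
        kw = {}
        for name in PHENOTYPE_FIELDS:
            v = getattr(self, name)
            kw[name] = v if name in _ANGLE_FIELDS else v * factor
        return replace(self, **kw)


# Per-field dispersion used for both identity offsets and frame noise,
# expressed at the 256-px canvas (angles in deg, lengths in px).
_FIELD_SCALE = {
    "ear_angle": 2.0,
    "ear_length": 1.5,
    "ear_width": 1.0,
    "ear_fold": 1.5,
    "whisker_angle": 2.0,
    "mouth_inclination": 1.0,
    "snout_mouth_length": 1.2,
    "nose_extension": 0.8,
    "pupil_diameter": 0.6,
    "eye_opening": 0.8,
}

# Stimulus-evoked additive offsets at the 256-px canvas. Sign structure is the
# ground truth downstream analyses must recover: sucrose/NaCl agree in sign,
# bitterness/shock agree in sign, ear angle flips sign between valences, and
# the pupil dilates for every non-neutral stimulus.
_DEFAULT_EFFECTS = {
    "sucrose": {
        "ear_angle": 14.0, "ear_length": 5.0, "ear_width": 3.0, "ear_fold": 5.0,
        "whisker_angle": -9.0, "mouth_inclination": 4.0, "snout_mouth_length": 4.0,
        "nose_extension": 2.0, "pupil_diameter": 4.0, "eye_opening": 1.5,
    },
    "NaCl": {
        "ear_angle": 10.0, "ear_length": 3.5, "ear_width": 2.0, "ear_fold": 3.5,
        "whisker_angle": -6.5, "mouth_inclination": 3.0, "snout_mouth_length": 3.0,
        "nose_extension": 1.5, "pupil_diameter": 3.5, "eye_opening": 1.0,
    },
    "bitterness": {
        "ear_angle": -12.0, "ear_length": -4.0, "ear_width": -2.5, "ear_fold": -6.0,
        "whisker_angle": 9.0, "mouth_inclination": 5.0, "snout_mouth_length": -4.5,
        "nose_extension": -1.5, "pupil_diameter": 4.0, "eye_opening": -2.0,
    },
    "shock": {
        "ear_angle": -15.0, "ear_length": -5.0, "ear_width": -3.0, "ear_fold": -7.5,
        "whisker_angle": 11.0, "mouth_inclination": 6.5, "snout_mouth_length": -5.5,
        "nose_extension": -2.0, "pupil_diameter": 5.0, "eye_opening": -2.5,
    },
    "water": {f: 0.0 for f in PHENOTYPE_FIELDS},
}

# Response latency per feature family (s); the whisker reaction is fastest,
# the pupil slowest, intermediate features in between.
_DEFAULT_LATENCY = {
    "ear_angle": 0.3, "ear_length": 0.3, "ear_width": 0.3, "ear_fold": 0.3,
    "whisker_angle": 0.1, "mouth_inclination": 0.3, "snout_mouth_length": 0.3,
    "nose_extension": 0.3, "pupil_diameter": 1.0, "eye_opening": 0.3,
}


def _deep_copy_effects(d):
    return {s: dict(v) for s, v in d.items()}


@dataclass
class ValenceEffectSpec:
    """Per-stimulus phenotype offsets plus identity/noise/dynamics settings.

    Parameters
    ----------
    effects
        Mapping stimulus -> {field -> additive offset}. Defaults carry the
        valence sign structure described in the module docstring.
    identity_scale
        Multiplier on the per-field dispersion used to draw one static
        phenotype offset per mouse (0 disables identity variation).
    frame_noise
        Multiplier on the per-field dispersion for i.i.d. per-frame jitter.
    latency_s, decay_s, rise_tau_s
        Response dynamics: offset onset latency per field, exponential
        return time constant after stimulus offset, and the rise time
        constant toward the full offset.
    """

    effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: _deep_copy_effects(_DEFAULT_EFFECTS)
    )
    identity_scale: float = 1.0
    frame_noise: float = 0.5
    latency_s: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_LATENCY))
    decay_s: float = 2.0
    rise_tau_s: float = 0.15

    def effect_vector(self, stimulus: str) -> np.ndarray:
        if stimulus not in self.effects:
            raise KeyError(f"unknown stimulus {stimulus!r}; expected one of {sorted(self.effects)}")
        eff = self.effects[stimulus]
        return np.array([eff.get(f, 0.0) for f in PHENOTYPE_FIELDS], dtype=float)

    def field_sigma(self) -> np.ndarray:
        return np.array([_FIELD_SCALE[f] for f in PHENOTYPE_FIELDS], dtype=float)

    def validate(self) -> None:
        def sgn(x):
            return 0 if x == 0 else (1 if x > 0 else -1)

        for f in PHENOTYPE_FIELDS:
            su, na = self.effects["sucrose"].get(f, 0), self.effects["NaCl"].get(f, 0)
            bi, sh = self.effects["bitterness"].get(f, 0), self.effects["shock"].get(f, 0)
            if sgn(su) * sgn(na) < 0:
                raise ValueError(f"sucrose/NaCl offsets disagree in sign for {f}")
            if sgn(bi) * sgn(sh) < 0:
                raise ValueError(f"bitterness/shock offsets disagree in sign for {f}")
        if sgn(self.effects["sucrose"]["ear_angle"]) * sgn(self.effects["shock"]["ear_angle"]) >= 0:
            raise ValueError("ear_angle offsets must have opposite signs across valences")
        for s in ("sucrose", "NaCl", "bitterness", "shock"):
            if self.effects[s].get("pupil_diameter", 0.0) <= 0:
                raise ValueError(f"pupil_diameter offset must be > 0 for {s}")

    def scaled(self, factor: float) -> "ValenceEffectSpec":
        """Scale all length-field offsets for a different canvas size."""
        eff = {
            s: {
                f: (v if f in _ANGLE_FIELDS else v * factor)
                for f, v in d.items()
            }
            for s, d in self.effects.items()
        }
        return replace(self, effects=eff)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Size, timing and reproducibility parameters of a synthetic cohort."""

    n_mice: int = 3
    trials_per_stimulus: int = 2
    fps: float = 30.0
    frame_size: int = 256
    stimulus_duration_s: float = 2.0
    pre_window_s: float = 2.0
    post_window_s: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        if self.frame_size < 128:
            raise ValueError("frame_size must be >= 128")

    @property
    def trial_n_frames(self) -> int:
        dur = self.pre_window_s + self.stimulus_duration_s + self.post_window_s
        return int(round(dur * self.fps))

    @property
    def canvas_scale(self) -> float:
        return self.frame_size / 256.0
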