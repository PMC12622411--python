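"""Cohort assembly and on-disk layout.

A cohort is a list of per-mouse sessions. Each mouse gets one static identity
offset on its baseline phenotype (drawn once per mouse), then contributes
``trials_per_stimulus`` trials of each of the five stimuli, laid out
sequentially on a session clock with a fixed inter-trial gap. Sessions can be
materialized to disk as per-frame PNGs, DeepLabCut-dialect keypoint CSVs,
events/photometry CSVs, and a YAML manifest carrying the generating spec,
seed and per-file checksums.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .dynamics import TrialSegment, simulate_trial
from .phenotype import STIMULI, VALENCE_OF, FacePhenotype, SyntheticCohortSpec, ValenceEffectSpec
from .photosim import PhotometryRecording, simulate_photometry
from .render import KEYPOINT_NAMES

__all__ = ["SessionFixture", "build_cohort", "write_cohort", "keypoints_to_dlc", "INTER_TRIAL_GAP_S"]

#: Seconds of dead time inserted between consecutive trials on the session clock.
INTER_TRIAL_GAP_S = 2.0


@dataclass
class SessionFixture:
    """One mouse's synthetic session: trials, events, optional photometry."""

    mouse_id: str
    baseline: FacePhenotype
    trials: list[TrialSegment]
    events: pd.DataFrame
    photometry: PhotometryRecording | None
    spec: SyntheticCohortSpec
    provenance: dict = field(default_factory=dict)


def build_cohort(
    spec: SyntheticCohortSpec,
    effects: ValenceEffectSpec | None = None,
    neuron_type: str | None = None,
    render: bool = True,
    stimuli: tuple[str, ...] = STIMULI,
    out_dir: str | Path | None = None,
) -> list[SessionFixture]:
    """Generate a full cohort; optionally write it to ``out_dir``.

    All randomness flows from ``spec.seed`` through one seed sequence, so a
    fixed spec regenerates bit-identical cohorts. ``neuron_type`` switches on
    per-session photometry simulation with the corresponding tuning.
    """
    effects = ValenceEffectSpec() if effects is None else effects
    effects.validate()
    base = FacePhenotype().scaled(spec.canvas_scale)
    sigma = effects.field_sigma()
    # Length-field dispersions scale with the canvas, angles do not.
    from .phenotype import PHENOTYPE_FIELDS, _ANGLE_FIELDS
    scale_vec = np.array([1.0 if f in _ANGLE_FIELDS else spec.canvas_scale
                          for f in PHENOTYPE_FIELDS])

    root_ss = np.random.SeedSequence(spec.seed)
    mouse_seeds = root_ss.spawn(spec.n_mice)

    trial_len_s = spec.pre_window_s + spec.stimulus_duration_s + spec.post_window_s
    sessions: list[SessionFixture] = []
    for m in range(spec.n_mice):
        mouse_id = f"m{m:02d}"
        rng = np.random.default_rng(mouse_seeds[m])
        identity = rng.normal(0.0, 1.0, len(sigma)) * effects.identity_scale * sigma * scale_vec
        mouse_base = base.shifted(identity)

        trials: list[TrialSegment] = []
        rows = []
        t_cursor = INTER_TRIAL_GAP_S
        k = 0
        for rep in range(spec.trials_per_stimulus):
            for stim in stimuli:
                seg = simulate_trial(mouse_base, effects, stim, spec, rng, render=render)
                seg.mouse_id = mouse_id
                seg.trial_id = f"{mouse_id}_t{k:03d}"
                trials.append(seg)
                rows.append({
                    "trial_id": seg.trial_id, "mouse_id": mouse_id, "stimulus": stim,
                    "valence": VALENCE_OF[stim],
                    "onset_s": t_cursor + spec.pre_window_s,
                    "duration_s": spec.stimulus_duration_s,
                })
                t_cursor += trial_len_s + INTER_TRIAL_GAP_S
                k += 1
        events = pd.DataFrame(rows)

        photometry = None
        if neuron_type is not None:
            photometry = simulate_photometry(
                neuron_type, events, duration_s=t_cursor + 10.0, rng=rng)

        sessions.append(SessionFixture(
            mouse_id=mouse_id, baseline=mouse_base, trials=trials, events=events,
            photometry=photometry, spec=spec,
            provenance={"seed": spec.seed, "mouse_index": m,
                        "identity_offsets": identity.tolist()},
        ))

    if out_dir is not None:
        write_cohort(sessions, out_dir)
    return sessions


def keypoints_to_dlc(keypoints: np.ndarray, scorer: str = "synthetic") -> pd.DataFrame:
    """Pack a (T, 37, 2) array into a DeepLabCut-dialect table.

    The result has the three-level column header (scorer / bodyparts /
    coords) used by pose-estimation exports; likelihood is 1 for ground
    truth.
    """
    n = keypoints.shape[0]
    cols = pd.MultiIndex.from_product(
        [[scorer], KEYPOINT_NAMES, ["x", "y", "likelihood"]],
        names=["scorer", "bodyparts", "coords"])
    data = np.empty((n, 37 * 3))
    data[:, 0::3] = keypoints[:, :, 0]
    data[:, 1::3] = keypoints[:, :, 1]
    data[:, 2::3] = 1.0
    return pd.DataFrame(data, columns=cols)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_cohort(sessions: list[SessionFixture], out_dir: str | Path,
                 write_frames: bool = True) -> Path:
    """Materialize a cohort to disk and return the manifest path."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create cohort directory {out}: {e}") from e

    files: dict[str, str] = {}
    for ses in sessions:
        mdir = out / ses.mouse_id
        mdir.mkdir(exist_ok=True)
        ses.events.to_csv(mdir / "events.csv", index=False)
        files[str((mdir / "events.csv").relative_to(out))] = _sha256(mdir / "events.csv")
        if ses.photometry is not None:
            ses.photometry.to_frame().to_csv(mdir / "photometry.csv", index=False)
            files[str((mdir / "photometry.csv").relative_to(out))] = _sha256(
                mdir / "photometry.csv")
        for seg in ses.trials:
            tdir = mdir / seg.trial_id
            tdir.mkdir(exist_ok=True)
            dlc = keypoints_to_dlc(seg.keypoints)
            dlc.to_csv(tdir / "keypoints.csv")
            files[str((tdir / "keypoints.csv").relative_to(out))] = _sha256(
                tdir / "keypoints.csv")
            if write_frames and seg.frames.size:
                fdir = tdir / "frames"
                fdir.mkdir(exist_ok=True)
                for i in range(seg.n_frames):
                    fp = fdir / f"frame_{i:05d}.png"
                    iio.imwrite(fp, (np.clip(seg.frames[i], 0, 1) * 255).astype(np.uint8))
                    files[str(fp.relative_to(out))] = _sha256(fp)

    spec = sessions[0].spec
    manifest = {
        "spec": {k: getattr(spec, k) for k in (
            "n_mice", "trials_per_stimulus", "fps", "frame_size",
            "stimulus_duration_s", "pre_window_s", "post_window_s", "seed")},
        "seed": spec.seed,
        "n_sessions": len(sessions),
        "prototype_mouse": sessions[0].mouse_id,
        "files": dict(sorted(files.items())),
    }
    mpath = out / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return mpath
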