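"""Generator ground truth: keypoint layout, oracles, dynamics, photometry."""

import numpy as np
import pandas as pd
import pytest

from faceval.kinematics import KeypointTrack, compute_geometry
from faceval.synthgen import (
    KEYPOINT_NAMES,
    KEYPOINT_REGIONS,
    REGION_COUNTS,
    FacePhenotype,
    RenderError,
    SyntheticCohortSpec,
    ValenceEffectSpec,
    build_cohort,
    render_face,
    simulate_photometry,
    simulate_trial,
    write_cohort,
)

# geometry feature -> phenotype field (two names differ)
FEATURE_TO_FIELD = {
    "pupil_size": "pupil_diameter",
    "nose_position": "nose_extension",
}


def geometry_of(kp):
    track = KeypointTrack(xy=kp[None], confidence=np.ones((1, 37)))
    return compute_geometry(track).iloc[0]


class TestRenderFace:
    def test_region_counts(self, default_face):
        _, kp = default_face
        assert kp.shape == (37, 2)
        counts = {}
        for n in KEYPOINT_NAMES:
            counts[KEYPOINT_REGIONS[n]] = counts.get(KEYPOINT_REGIONS[n], 0) + 1
        assert counts == {"pupil": 8, "eye": 4, "ear": 5, "nose": 5,
                          "mouth": 3, "whisker": 12}
        assert counts == REGION_COUNTS

    def test_vertical_ear_angle(self):
        _, kp = render_face(FacePhenotype(ear_angle=90.0), 256)
        names = {n: i for i, n in enumerate(KEYPOINT_NAMES)}
        v = kp[names["pinna_posterior_edge"]] - kp[names["ear_root"]]
        assert abs(v[0]) < 1e-9  # vertical in image coords too
        assert geometry_of(kp)["ear_angle"] == pytest.approx(90.0, abs=1e-9)

    def test_deterministic(self):
        a, ka = render_face(FacePhenotype(), 256)
        b, kb = render_face(FacePhenotype(), 256)
        assert np.array_equal(a, b) and np.array_equal(ka, kb)

    @pytest.mark.parametrize("field,value", [
        ("ear_angle", 72.0), ("ear_length", 40.0), ("ear_width", 22.0),
        ("ear_fold", 50.0), ("whisker_angle", 40.0), ("mouth_inclination", 27.0),
        ("snout_mouth_length", 60.0), ("nose_extension", 20.0),
        ("pupil_diameter", 18.0), ("eye_opening", 16.0),
    ])
    def test_oracle_recovers_each_field(self, field, value):
        ph = FacePhenotype(**{field: value})
        _, kp = render_face(ph, 256)
        geo = geometry_of(kp)
        for feat in geo.index:
            truth = getattr(ph, FEATURE_TO_FIELD.get(feat, feat))
            assert geo[feat] == pytest.approx(truth, abs=1e-6)

    def test_off_canvas_raises(self):
        with pytest.raises(RenderError):
            render_face(FacePhenotype(ear_length=150.0), 256)

    def test_invalid_phenotype(self):
        with pytest.raises(ValueError):
            render_face(FacePhenotype(ear_angle=200.0), 256)
        with pytest.raises(ValueError):
            render_face(FacePhenotype(pupil_diameter=-1.0), 256)


class TestEffectSpec:
    def test_default_sign_structure(self):
        eff = ValenceEffectSpec()
        eff.validate()
        ear = {s: eff.effects[s]["ear_angle"] for s in eff.effects}
        assert ear["sucrose"] > 0 and ear["NaCl"] > 0
        assert ear["bitterness"] < 0 and ear["shock"] < 0
        for s in ("sucrose", "NaCl", "bitterness", "shock"):
            assert eff.effects[s]["pupil_diameter"] > 0

    def test_invalid_sign_structure_rejected(self):
        eff = ValenceEffectSpec()
        eff.effects["NaCl"]["ear_angle"] = -1.0
        with pytest.raises(ValueError):
            eff.validate()


class TestSimulateTrial:
    SPEC = SyntheticCohortSpec(n_mice=1, trials_per_stimulus=1, frame_size=128,
                               pre_window_s=1.0, post_window_s=1.0)

    def test_null_effects_constant_frames(self, rng):
        eff = ValenceEffectSpec(frame_noise=0.0)
        eff.effects = {s: {} for s in eff.effects}
        base = FacePhenotype().scaled(0.5)
        seg = simulate_trial(base, eff, "sucrose", self.SPEC, rng)
        assert np.array_equal(seg.frames[0], seg.frames[-1])
        base_img, _ = render_face(base, 128)
        assert np.array_equal(seg.frames[0], base_img)

    def test_opposite_ear_deviation(self, rng):
        eff = ValenceEffectSpec(frame_noise=0.0)
        base = FacePhenotype().scaled(0.5)
        pos = simulate_trial(base, eff, "sucrose", self.SPEC, rng)
        neg = simulate_trial(base, eff, "shock", self.SPEC, rng)
        b = base.ear_angle
        dev_pos = pos.features["ear_angle"].to_numpy()[-30:].mean() - b
        dev_neg = neg.features["ear_angle"].to_numpy()[-30:].mean() - b
        assert dev_pos > 0 > dev_neg

    def test_seeded_determinism(self):
        eff = ValenceEffectSpec(frame_noise=0.5)
        base = FacePhenotype().scaled(0.5)
        a = simulate_trial(base, eff, "NaCl", self.SPEC, np.random.default_rng(3))
        b = simulate_trial(base, eff, "NaCl", self.SPEC, np.random.default_rng(3))
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(a.keypoints, b.keypoints)

    def test_unknown_stimulus(self, rng):
        with pytest.raises(ValueError):
            simulate_trial(FacePhenotype().scaled(0.5), ValenceEffectSpec(),
                           "coffee", self.SPEC, rng)


EVENTS = pd.DataFrame({
    "onset_s": [10.0, 30.0, 50.0, 70.0, 90.0],
    "stimulus": ["sucrose", "NaCl", "water", "bitterness", "shock"],
})


class TestSimulatePhotometry:
    def test_null_nuisances_single_transient(self, rng):
        ev = EVENTS.iloc[:1]
        rec = simulate_photometry("DA", ev, duration_s=30, rng=rng, artifact_sd=0,
                                  noise_sd=0, bleach_frac=0)
        assert np.ptp(rec.f410) == 0.0
        i0 = int(10.0 * rec.rate_hz)
        assert np.ptp(rec.f470[:i0]) == 0.0
        assert rec.f470.argmax() == i0
        # exponential decay after the peak
        post = rec.f470[i0:] - rec.f470[0]
        assert np.all(np.diff(post) <= 1e-12)

    def test_pan_amplitudes_equal(self, rng):
        rec = simulate_photometry("pan", EVENTS, duration_s=110, rng=rng,
                                  artifact_sd=0, noise_sd=0, bleach_frac=0)
        peaks = [rec.f470[int(t * 15)] - rec.f470[0] for t in EVENTS["onset_s"]]
        # equal up to the ~1e-6 residual tails of preceding transients
        assert np.allclose(peaks, peaks[0], atol=1e-4)

    def test_da_amplitude_ordering_in_raw_peaks(self, rng):
        rec = simulate_photometry("DA", EVENTS, duration_s=110, rng=rng,
                                  artifact_sd=0, noise_sd=0, bleach_frac=0)
        peak = {s: rec.f470[int(t * 15)] - rec.f470[0]
                for t, s in zip(EVENTS["onset_s"], EVENTS["stimulus"])}
        assert peak["sucrose"] > peak["NaCl"] > peak["water"]
        assert peak["water"] > peak["bitterness"] and peak["water"] > peak["shock"]

    def test_seeded_determinism(self):
        a = simulate_photometry("Glu", EVENTS, rng=np.random.default_rng(4))
        b = simulate_photometry("Glu", EVENTS, rng=np.random.default_rng(4))
        assert np.array_equal(a.f470, b.f470) and np.array_equal(a.f410, b.f410)

    def test_unknown_neuron_type(self, rng):
        with pytest.raises(ValueError):
            simulate_photometry("serotonin", EVENTS, rng=rng)


class TestBuildCohort:
    def test_trial_count(self, noisy_cohort):
        segs = [seg for ses in noisy_cohort for seg in ses.trials]
        assert len(segs) == 4 * 2 * 5
        assert len({s.trial_id for s in segs}) == len(segs)

    def test_bitwise_regeneration(self):
        spec = SyntheticCohortSpec(n_mice=2, trials_per_stimulus=1, frame_size=128,
                                   seed=9, pre_window_s=0.5, post_window_s=0.5)
        a = build_cohort(spec)
        b = build_cohort(spec)
        for sa, sb in zip(a, b):
            for ta, tb in zip(sa.trials, sb.trials):
                assert np.array_equal(ta.frames, tb.frames)
            pd.testing.assert_frame_equal(sa.events, sb.events)

    def test_zero_identity_scale_shares_baseline(self):
        spec = SyntheticCohortSpec(n_mice=3, trials_per_stimulus=1, frame_size=128,
                                   seed=2, pre_window_s=0.5, post_window_s=0.5)
        cohort = build_cohort(spec, ValenceEffectSpec(identity_scale=0.0),
                              render=False)
        assert len({tuple(s.baseline.as_vector()) for s in cohort}) == 1

    def test_manifest_checksums_reproducible(self, tmp_path):
        spec = SyntheticCohortSpec(n_mice=1, trials_per_stimulus=1, frame_size=128,
                                   seed=4, pre_window_s=0.25, post_window_s=0.25,
                                   stimulus_duration_s=0.5)
        m1 = write_cohort(build_cohort(spec), tmp_path / "a")
        m2 = write_cohort(build_cohort(spec), tmp_path / "b")
        import yaml
        f1 = yaml.safe_load(m1.read_text())["files"]
        f2 = yaml.safe_load(m2.read_text())["files"]
        assert f1 == f2 and len(f1) > 0
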