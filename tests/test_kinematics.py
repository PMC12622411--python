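"""Keypoint QC, geometry battery, change scores, PCA, response latency."""

import numpy as np
import pandas as pd
import pytest

from faceval.kinematics import (
    ChangeScore,
    KeypointTrack,
    change_from_baseline,
    compute_geometry,
    keypoint_pca,
    qc_track,
    read_dlc_csv,
    response_latency,
    water_correct,
)
from faceval.synthgen import KEYPOINT_NAMES, FacePhenotype, render_face
from faceval.synthgen.cohort import keypoints_to_dlc


def make_track(n=20, names=("a", "b"), value=5.0):
    xy = np.full((n, len(names), 2), value)
    conf = np.ones((n, len(names)))
    return KeypointTrack(xy=xy, confidence=conf, names=list(names))


class TestQcTrack:
    def test_noop_on_confident_constant_track(self):
        track = make_track()
        out = qc_track(track)
        assert np.array_equal(out.xy, track.xy)

    def test_low_confidence_interpolated(self):
        track = make_track(n=7, names=("p",), value=10.0)
        track.xy[:, 0, 0] = [10, 10, 10, 999, 14, 14, 14]
        track.confidence[3, 0] = 0.2
        out = qc_track(track, median_window=1)
        assert out.xy[3, 0, 0] == pytest.approx(12.0)  # linear midpoint of 10 and 14

    def test_impulse_removed_by_median(self):
        track = make_track(n=15, names=("p",), value=3.0)
        track.xy[7, 0, 1] = 53.0  # 50 px impulse, confidence stays high
        out = qc_track(track, median_window=5)
        assert np.allclose(out.xy[:, 0, 1], 3.0)

    def test_idempotent_on_smooth_series(self):
        t = np.linspace(0, 2 * np.pi, 60)
        track = make_track(n=60, names=("p",))
        track.xy[:, 0, 0] = 10 + np.sin(t)
        track.xy[:, 0, 1] = 20 + np.cos(t)
        once = qc_track(track)
        twice = qc_track(once)
        assert np.allclose(once.xy, twice.xy)

    def test_dead_keypoint_dropped_with_warning(self):
        track = make_track(n=5, names=("p", "q"))
        track.confidence[:, 1] = 0.1
        with pytest.warns(UserWarning):
            out = qc_track(track)
        assert np.isnan(out.xy[:, 1]).all()
        assert np.isfinite(out.xy[:, 0]).all()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            qc_track(make_track(), median_window=4)


class TestComputeGeometry:
    def test_pupil_distance(self):
        names = list(KEYPOINT_NAMES)
        xy = np.zeros((1, 37, 2))
        xy[0, names.index("pupil_top")] = [0.0, 10.0]
        xy[0, names.index("pupil_bottom")] = [0.0, 2.0]
        track = KeypointTrack(xy=xy, confidence=np.ones((1, 37)))
        assert compute_geometry(track)["pupil_size"][0] == pytest.approx(8.0)

    def test_collinear_mouth_angle_straight(self):
        names = list(KEYPOINT_NAMES)
        xy = np.zeros((1, 37, 2))
        xy[0, names.index("nostril_bottom")] = [0.0, 0.0]
        xy[0, names.index("eye_inner_corner")] = [5.0, 0.0]
        xy[0, names.index("lower_lip_anterior")] = [11.0, 0.0]
        track = KeypointTrack(xy=xy, confidence=np.ones((1, 37)))
        assert compute_geometry(track)["mouth_inclination"][0] == pytest.approx(180.0)

    def test_ear_angle_yup_convention(self):
        # image coords are y-down: (1, -1) offset means up-right in y-up
        names = list(KEYPOINT_NAMES)
        xy = np.zeros((1, 37, 2))
        xy[0, names.index("ear_root")] = [0.0, 0.0]
        xy[0, names.index("pinna_posterior_edge")] = [1.0, -1.0]
        track = KeypointTrack(xy=xy, confidence=np.ones((1, 37)))
        geo = compute_geometry(track)
        assert geo["ear_angle"][0] == pytest.approx(45.0)
        # independent atan2 oracle in the y-up frame
        assert np.degrees(np.arctan2(1.0, 1.0)) == pytest.approx(45.0)

    def test_degenerate_points_yield_nan(self):
        names = list(KEYPOINT_NAMES)
        xy = np.zeros((1, 37, 2))  # all keypoints coincide
        track = KeypointTrack(xy=xy, confidence=np.ones((1, 37)))
        geo = compute_geometry(track)
        assert np.isnan(geo["ear_fold"][0])
        assert np.isnan(geo["ear_angle"][0])

    def test_recovers_generator_phenotype(self):
        ph = FacePhenotype(ear_angle=48.0, whisker_angle=33.0, ear_fold=55.0)
        _, kp = render_face(ph, 256)
        track = KeypointTrack(xy=kp[None], confidence=np.ones((1, 37)))
        geo = compute_geometry(track).iloc[0]
        assert geo["ear_angle"] == pytest.approx(48.0, abs=1e-6)
        assert geo["whisker_angle"] == pytest.approx(33.0, abs=1e-6)
        assert geo["ear_fold"] == pytest.approx(55.0, abs=1e-6)
        assert geo["snout_mouth_length"] == pytest.approx(ph.snout_mouth_length, abs=1e-6)

    def test_rigid_motion_invariance(self, default_face):
        _, kp = default_face
        ang = np.deg2rad(17.0)
        r = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = kp @ r.T + [30.0, -10.0]
        g0 = compute_geometry(KeypointTrack(xy=kp[None], confidence=np.ones((1, 37)))).iloc[0]
        g1 = compute_geometry(KeypointTrack(xy=moved[None], confidence=np.ones((1, 37)))).iloc[0]
        for feat in ("pupil_size", "eye_opening", "snout_mouth_length",
                     "nose_position", "ear_length", "ear_width",
                     "mouth_inclination", "ear_fold"):
            assert g1[feat] == pytest.approx(g0[feat], abs=1e-9)
        # directional angles shift by exactly the applied rotation
        # (CCW by +ang in image coords is CW, i.e. -ang, in the y-up frame)
        assert g1["ear_angle"] == pytest.approx(
            (g0["ear_angle"] - np.degrees(ang)) % 180.0, abs=1e-9)

    def test_dlc_roundtrip(self, tmp_path, default_face):
        _, kp = default_face
        df = keypoints_to_dlc(np.stack([kp, kp + 1.0]))
        path = tmp_path / "kp.csv"
        df.to_csv(path)
        track = read_dlc_csv(path)
        assert track.names == list(KEYPOINT_NAMES)
        assert np.allclose(track.xy[0], kp)
        assert np.allclose(track.confidence, 1.0)


class TestChangeFromBaseline:
    def test_constant_series_zero_change(self):
        series = np.full(300, 7.0)
        cs = change_from_baseline(series, onset=150, fps=30.0)
        assert cs.value == pytest.approx(0.0)

    def test_twenty_percent_peak(self):
        series = np.full(300, 10.0)
        series[200] = 12.0
        cs = change_from_baseline(series, onset=150, fps=30.0)
        assert cs.value == pytest.approx(0.20)

    def test_signed_extremum_prefers_larger_decrease(self):
        series = np.full(300, 10.0)
        series[180] = 11.0
        series[200] = 7.0
        cs = change_from_baseline(series, onset=150, fps=30.0)
        assert cs.value == pytest.approx(-0.30)

    def test_zero_baseline_flagged(self):
        series = np.zeros(300)
        cs = change_from_baseline(series, onset=150, fps=30.0)
        assert cs.flagged and np.isnan(cs.value)

    def test_recovers_generated_offset(self, keypoint_cohort):
        # ear-angle trials carry a known proportional offset; after the
        # standard QC (median smoothing) the mean recovered peak change
        # across trials matches the generated offset within 3 points
        values, truths = [], []
        for ses in keypoint_cohort:
            for seg in ses.trials:
                if seg.stimulus != "sucrose":
                    continue
                track = qc_track(KeypointTrack(
                    xy=seg.keypoints, confidence=np.ones(seg.keypoints.shape[:2])))
                geo = compute_geometry(track)
                onset = int(round(seg.onset_s * 30.0))
                cs = change_from_baseline(geo["ear_angle"].to_numpy(), onset, 30.0,
                                          window_s=seg.duration_s)
                values.append(cs.value)
                truths.append(14.0 / ses.baseline.ear_angle)
        assert len(values) == 20
        assert np.mean(values) == pytest.approx(np.mean(truths), abs=0.03)


class TestWaterCorrect:
    def frame(self):
        return pd.DataFrame({
            "trial_id": ["t0", "t1", "t2"],
            "stimulus": ["sucrose", "water", "water"],
            "onset_s": [180.0, 100.0, 500.0],
            "ear_angle": [0.30, 0.10, -0.40],
        })

    def test_subtracts_nearest_water(self):
        out = water_correct(self.frame(), ["ear_angle"])
        assert out.loc[0, "ear_angle"] == pytest.approx(0.30 - 0.10)

    def test_water_self_subtraction_zero(self):
        out = water_correct(self.frame(), ["ear_angle"])
        assert out.loc[1, "ear_angle"] == pytest.approx(0.0)

    def test_equidistant_tie_prefers_earlier(self):
        df = self.frame()
        df.loc[0, "onset_s"] = 300.0  # equidistant from 100 and 500
        out = water_correct(df, ["ear_angle"])
        assert out.loc[0, "ear_angle"] == pytest.approx(0.30 - 0.10)

    def test_no_water_raises(self):
        df = self.frame()
        df["stimulus"] = "sucrose"
        with pytest.raises(ValueError):
            water_correct(df, ["ear_angle"])

    def test_sign_pattern_matches_generator(self, keypoint_cohort):
        # water-corrected ear-angle changes: positive for sucrose/NaCl,
        # negative for bitterness/shock, in >= 90% of trials
        good = total = 0
        for ses in keypoint_cohort:
            rows = []
            for seg in ses.trials:
                track = KeypointTrack(xy=seg.keypoints,
                                      confidence=np.ones(seg.keypoints.shape[:2]))
                geo = compute_geometry(track)
                onset = int(round(seg.onset_s * 30.0))
                cs = change_from_baseline(geo["ear_angle"].to_numpy(), onset, 30.0,
                                          window_s=seg.duration_s)
                ev = ses.events[ses.events.trial_id == seg.trial_id].iloc[0]
                rows.append({"trial_id": seg.trial_id, "stimulus": seg.stimulus,
                             "onset_s": ev.onset_s, "ear_angle": cs.value})
            out = water_correct(pd.DataFrame(rows), ["ear_angle"])
            for _, r in out.iterrows():
                if r.stimulus in ("sucrose", "NaCl"):
                    good += r.ear_angle > 0
                    total += 1
                elif r.stimulus in ("bitterness", "shock"):
                    good += r.ear_angle < 0
                    total += 1
        assert total == 80
        assert good / total >= 0.90


class TestKeypointPCA:
    def test_rank_one_data(self, rng):
        t = rng.normal(size=50)
        x = np.outer(t, [1.0, 2.0, -1.0])
        comps, evr, kept = keypoint_pca(x, z_score=False)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_column_dropped(self, rng):
        x = rng.normal(size=(20, 4))
        x[:, 2] = 3.0
        with pytest.warns(UserWarning):
            comps, evr, kept = keypoint_pca(x)
        assert 2 not in kept and len(kept) == 3

    def test_ear_variance_mode_dominates_loadings(self, rng):
        n = 60
        ear_mode = rng.normal(size=n)
        other = rng.normal(size=(n, 6)) * 0.05
        ear_cols = np.outer(ear_mode, [1.0, -0.8, 0.9, -1.1])
        x = np.hstack([ear_cols, other])
        comps, evr, kept = keypoint_pca(x)
        top2 = comps[:2]
        mass = (top2 ** 2)[:, :4].sum(axis=1) / (top2 ** 2).sum(axis=1)
        assert mass.max() > 0.5


class TestResponseLatency:
    def test_never_deviating_missing(self):
        series = np.ones(300)
        lat, flagged = response_latency(series, onset=150, fps=30.0)
        assert np.isnan(lat) and flagged  # zero baseline SD fallback

    def test_step_at_half_second(self, rng):
        series = np.concatenate([rng.normal(0, 0.1, 165), np.full(135, 5.0)])
        lat, flagged = response_latency(series, onset=150, fps=30.0)
        assert not flagged
        assert lat == pytest.approx(0.5, abs=1e-9)

    def test_whisker_faster_than_pupil(self, keypoint_cohort):
        wins = total = 0
        for ses in keypoint_cohort:
            for seg in ses.trials:
                if seg.stimulus == "water":
                    continue
                onset = int(round(seg.onset_s * 30.0))
                w = seg.features["whisker_angle"].to_numpy()
                p = seg.features["pupil_diameter"].to_numpy()
                lw, _ = response_latency(w, onset, 30.0)
                lp, _ = response_latency(p, onset, 30.0)
                if np.isfinite(lw) and np.isfinite(lp):
                    total += 1
                    wins += lw < lp
        assert total >= 40
        assert wins / total >= 0.95
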