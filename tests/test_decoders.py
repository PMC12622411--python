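"""Learned decoders: splits, classifier, pairs/Siamese, saliency, occlusion, LSTM."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from faceval.decoders import (
    ClassifierConfig,
    ContrastiveConfig,
    auto_margin,
    frames_from_cohort,
    gradcam,
    lstm_region_decoder,
    make_pairs,
    occlusion_cv,
    region_masks_for_dataset,
    similarity_gradcam,
    split_by_trial,
    train_frame_classifier,
    train_siamese,
    trajectories_from_cohort,
)
from faceval.synthgen import (
    SyntheticCohortSpec,
    ValenceEffectSpec,
    build_cohort,
)


@pytest.fixture(scope="module")
def clean_frames(clean_cohort):
    return frames_from_cohort(clean_cohort, input_side=32, keep_keypoints=True)


@pytest.fixture(scope="module")
def noisy_frames(noisy_cohort):
    return frames_from_cohort(noisy_cohort, input_side=32, keep_keypoints=True)




class TestSplitByTrial:
    def test_kfold_partitions_trials(self, rng):
        trial_ids = np.repeat([f"t{i}" for i in range(20)], 6)
        labels = np.repeat(np.arange(5).repeat(4), 6)
        splits = split_by_trial(trial_ids, labels, scheme="kfold", k=10,
                                stratify=False, seed=0)
        assert len(splits) == 10
        for tr, te in splits:
            assert len(set(trial_ids[tr]) & set(trial_ids[te])) == 0
            assert len(set(trial_ids[te])) == 2

    def test_stratified_folds_cover_all_classes(self):
        trial_ids = np.repeat([f"t{i}" for i in range(50)], 3)
        labels = np.repeat(np.arange(5).repeat(10), 3)
        splits = split_by_trial(trial_ids, labels, scheme="kfold", k=10, seed=1)
        for _, te in splits:
            assert set(labels[te]) == set(range(5))

    def test_deterministic_given_seed(self):
        trial_ids = np.repeat([f"t{i}" for i in range(12)], 2)
        labels = np.repeat(np.arange(3).repeat(4), 2)
        a = split_by_trial(trial_ids, labels, k=3, seed=5)
        b = split_by_trial(trial_ids, labels, k=3, seed=5)
        for (tra, tea), (trb, teb) in zip(a, b):
            assert np.array_equal(tra, trb) and np.array_equal(tea, teb)

    def test_too_few_trials_raises(self):
        with pytest.raises(ValueError):
            split_by_trial(np.array(["t0", "t1"]), np.array([0, 1]), k=10)


class TestFrameClassifier:
    def test_separable_classes_high_accuracy(self, clean_frames):
        cfg = ClassifierConfig(epochs=10, seed=0, augment=False)
        res = train_frame_classifier(clean_frames, cfg)
        assert res.accuracy >= 0.95

    def test_confusion_rows_sum_to_test_counts(self, clean_frames):
        cfg = ClassifierConfig(epochs=2, seed=1, augment=False)
        res = train_frame_classifier(clean_frames, cfg)
        truth = clean_frames.labels[res.test_idx]
        for c in range(5):
            assert res.confusion[c].sum() == (truth == c).sum()

    def test_shuffled_labels_at_chance(self, clean_frames):
        # at this tiny scale whole test trials get a single predicted class,
        # so single-run accuracy is lumpy in steps of 1/5; average a few
        # shuffle seeds and allow a generous band around chance (the tight
        # full-scale version of this check lives in the acceptance suite)
        split = split_by_trial(clean_frames.trial_ids, clean_frames.labels,
                               scheme="kfold", k=3, seed=0)[0]
        accs = []
        for s in range(3):
            cfg = ClassifierConfig(epochs=4, seed=s, augment=False)
            res = train_frame_classifier(clean_frames, cfg, shuffle_labels=True,
                                         split=split)
            accs.append(res.accuracy)
        assert abs(np.mean(accs) - 0.2) <= 0.15

    def test_single_class_training_rejected(self, clean_frames):
        from faceval.decoders.classifier import fit_classifier
        sel = clean_frames.labels == 0
        with pytest.raises(ValueError):
            fit_classifier(clean_frames.images[sel], clean_frames.labels[sel],
                           ClassifierConfig(epochs=1))


class TestMakePairs:
    def test_sanctioned_pair_categories_only(self, noisy_frames):
        pairs = make_pairs(noisy_frames, n_pairs=200, seed=0)
        ds = pairs.dataset
        val = {"sucrose": "positive", "NaCl": "positive",
               "bitterness": "negative", "shock": "negative", "water": "neutral"}
        for i, j, y in zip(pairs.idx1, pairs.idx2, pairs.labels):
            vi = val[ds.classes[ds.labels[i]]]
            vj = val[ds.classes[ds.labels[j]]]
            mi, mj = ds.mouse_ids[i], ds.mouse_ids[j]
            assert "neutral" not in (vi, vj)
            if y == 1:
                assert vi == vj and mi != mj  # same valence, different mice
            else:
                assert vi != vj and mi == mj  # different valence, same mouse

    def test_balanced_and_no_same_mouse_same_valence(self, noisy_frames):
        pairs = make_pairs(noisy_frames, n_pairs=100, seed=3)
        assert pairs.labels.sum() == 50

    def test_single_mouse_rejected(self, noisy_frames):
        one = noisy_frames.subset(np.flatnonzero(noisy_frames.mouse_ids == "m00"))
        with pytest.raises(ValueError):
            make_pairs(one, n_pairs=10, seed=0)


class TestAutoMargin:
    def test_mean_of_distances(self):
        assert auto_margin(np.array([1.0, 3.0]))[0] == pytest.approx(2.0)

    def test_constant_distances(self):
        assert auto_margin(np.array([0.7, 0.7, 0.7]))[0] == pytest.approx(0.7)

    def test_squared_variant(self):
        m, _ = auto_margin(np.array([1.0, 3.0]), squared=True)
        assert m == pytest.approx(5.0)

    def test_all_zero_falls_back_flagged(self):
        m, flagged = auto_margin(np.zeros(4))
        assert m == 1.0 and flagged


class TestTrainSiamese:
    def test_held_out_mouse_separation(self, noisy_frames):
        train_ds = noisy_frames.subset(
            np.flatnonzero(np.isin(noisy_frames.mouse_ids, ["m00", "m01", "m02"])))
        ho_ds = noisy_frames.subset(
            np.flatnonzero(np.isin(noisy_frames.mouse_ids, ["m02", "m03"])))
        pairs = make_pairs(train_ds, n_pairs=240, seed=0)
        ho_pairs = make_pairs(ho_ds, n_pairs=120, seed=1)
        res = train_siamese(pairs, ContrastiveConfig(epochs=6, seed=0),
                            held_out_pairs=ho_pairs)
        assert res.held_out_diff.mean() > res.held_out_same.mean()
        p = mannwhitneyu(res.held_out_diff, res.held_out_same,
                         alternative="greater").pvalue
        assert p < 0.01

    def test_shuffled_pairs_create_no_separation(self, noisy_frames):
        """Label-shuffled training must not build valence structure.

        An untrained encoder already separates different-valence pairs
        somewhat, because the underlying expressions genuinely differ in
        appearance; the null property is therefore that shuffled-label
        training yields no *more* separation than that passive baseline
        (and far less than a properly trained model achieves).
        """
        train_ds = noisy_frames.subset(
            np.flatnonzero(np.isin(noisy_frames.mouse_ids, ["m00", "m01"])))
        ho_ds = noisy_frames.subset(
            np.flatnonzero(np.isin(noisy_frames.mouse_ids, ["m02", "m03"])))
        pairs = make_pairs(train_ds, n_pairs=240, seed=0)
        rng = np.random.default_rng(0)
        pairs.labels = rng.permutation(pairs.labels)
        ho_pairs = make_pairs(ho_ds, n_pairs=500, seed=2)

        def cohen(same, diff):
            pooled = np.concatenate([same, diff])
            return (diff.mean() - same.mean()) / pooled.std()

        from faceval.nn import SiameseEncoder
        enc = SiameseEncoder(seed=0)
        e1 = enc.embed(noisy_frames.images[ho_pairs.idx1])
        e2 = enc.embed(noisy_frames.images[ho_pairs.idx2])
        d0 = np.linalg.norm(e1 - e2, axis=1)
        d_untrained = cohen(d0[ho_pairs.labels == 1], d0[ho_pairs.labels == 0])

        res = train_siamese(pairs, ContrastiveConfig(epochs=4, seed=0),
                            held_out_pairs=ho_pairs)
        d_shuffled = cohen(res.held_out_same, res.held_out_diff)
        assert d_shuffled < d_untrained
        assert d_shuffled < 0.6


class TestGradCAM:
    def test_map_contract(self, clean_frames):
        res = train_frame_classifier(clean_frames,
                                     ClassifierConfig(epochs=2, seed=0, augment=False))
        sm = gradcam(res.model, clean_frames.images[0], int(clean_frames.labels[0]))
        assert sm.values.shape == clean_frames.images[0, 0].shape
        assert sm.values.min() >= 0.0 and sm.values.max() <= 1.0

    def test_toy_network_peak_location(self):
        # one conv layer with a single active unit at a known position
        from faceval.nn import SmallResNet
        net = SmallResNet(n_classes=2, stem_channels=4, plan=((4, 4, 1),),
                          stem_stride=1, seed=0)
        x = np.zeros((1, 1, 16, 16), dtype=np.float32)
        x[0, 0, 4, 11] = 5.0  # single bright pixel
        sm = gradcam(net, x[0], target=0)
        peak = np.unravel_index(np.argmax(sm.values), sm.values.shape)
        assert abs(peak[0] - 4) <= 2 and abs(peak[1] - 11) <= 2

    def test_target_out_of_range(self, clean_frames):
        res = train_frame_classifier(clean_frames,
                                     ClassifierConfig(epochs=1, seed=0, augment=False))
        with pytest.raises(ValueError):
            gradcam(res.model, clean_frames.images[0], target=7)

@pytest.fixture(scope="module")
def siamese(noisy_frames):
    train_ds = noisy_frames.subset(
        np.flatnonzero(np.isin(noisy_frames.mouse_ids, ["m00", "m01", "m02"])))
    pairs = make_pairs(train_ds, n_pairs=160, seed=0)
    return train_siamese(pairs, ContrastiveConfig(epochs=4, seed=0)).model


class TestSimilarityGradCAM:

    def test_identical_pair_flagged_zero(self, siamese, noisy_frames):
        img = noisy_frames.images[0]
        a, b = similarity_gradcam(siamese, img, img, pair_label=1)
        assert a.flagged and b.flagged
        assert not a.values.any() and not b.values.any()

    def test_branch_swap_symmetry(self, siamese, noisy_frames):
        i, j = 0, 400
        a1, b1 = similarity_gradcam(siamese, noisy_frames.images[i],
                                    noisy_frames.images[j], pair_label=0)
        a2, b2 = similarity_gradcam(siamese, noisy_frames.images[j],
                                    noisy_frames.images[i], pair_label=0)
        assert np.allclose(a1.values, b2.values, atol=1e-5)
        assert np.allclose(b1.values, a2.values, atol=1e-5)


class TestOcclusionCV:
    def test_oversized_mask_warns(self, clean_frames):
        big = np.ones((32, 32), dtype=bool)
        with pytest.warns(UserWarning):
            occlusion_cv(clean_frames, {"all": big}, k=3,
                         cfg=ClassifierConfig(epochs=1, seed=0, augment=False))


class TestLSTMRegionDecoder:
    def test_trajectory_tensor_is_200d(self, noisy_cohort):
        td = trajectories_from_cohort(noisy_cohort, "ear")
        assert td.tensors.shape[1:] == (25, 8)
        assert td.flat_dim == 200

    def test_ear_beats_pupil_when_signal_is_in_the_ear(self, ear_only_cohort):
        k = 3
        # this cohort has no pre-stimulus window; decode the 0-1 s response
        ear = trajectories_from_cohort(ear_only_cohort, "ear", pre_s=0.0, post_s=1.0)
        pupil = trajectories_from_cohort(ear_only_cohort, "pupil", pre_s=0.0, post_s=1.0)
        out_ear = lstm_region_decoder(ear, k=k, seed=0, hidden=48, n_layers=2, epochs=40)
        out_pupil = lstm_region_decoder(pupil, k=k, seed=0, hidden=48, n_layers=2, epochs=40)
        assert out_ear["accuracy"] >= 0.8
        n = len(pupil.labels) / k
        sd = np.sqrt(0.2 * 0.8 / n)
        assert abs(out_pupil["accuracy"] - 0.2) <= max(3 * sd, 0.25)

    def test_shuffled_labels_at_chance(self, noisy_cohort):
        td = trajectories_from_cohort(noisy_cohort, "ear")
        out = lstm_region_decoder(td, k=2, seed=0, hidden=32, n_layers=2,
                                  epochs=25, shuffle_labels=True)
        assert abs(out["accuracy"] - 0.2) <= 0.25  # 40 trials: wide binomial band
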