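"""Classifier stage: augmentation, the training loop, overfit/checkpoint
logic, hard-example harvesting."""

import numpy as np
import pandas as pd
import pytest

from walkaudit.classify import (
    AugmentationError,
    ClassifierConfig,
    TrainingDataError,
    augment,
    detect_overfit,
    harvest_hard_examples,
    select_best_checkpoint,
    train_classifier,
)
from walkaudit.features import PRIMITIVE_FEATURES, StreetFeature
from walkaudit.scenes import generate_scene_dataset


@pytest.fixture(scope="module")
def trained_sidewalk(clean_scenes_split):
    train, val, loader = clean_scenes_split
    cfg = ClassifierConfig(seed=5, epochs=12)
    return train_classifier(train, val, StreetFeature.SIDEWALK, cfg, loader)


@pytest.fixture(scope="module")
def clean_scenes_split():
    prev = {f: 0.5 for f in PRIMITIVE_FEATURES}
    train = generate_scene_dataset(150, prev, seed=301)
    val = generate_scene_dataset(80, prev, seed=302)
    images = {**train.images, **val.images}
    return train.manifest, val.manifest, (lambda sid: images[sid].image)


class TestAugment:
    def test_empty_policy_is_identity(self, clean_scenes):
        img = next(iter(clean_scenes.images.values())).image
        np.testing.assert_array_equal(augment(img, (), seed=3), img)

    def test_flip_is_involution(self, clean_scenes):
        img = next(iter(clean_scenes.images.values())).image
        once = augment(img, ("horizontal_flip",), seed=9)
        twice = augment(once, ("horizontal_flip",), seed=9)
        np.testing.assert_array_equal(twice, img)

    def test_brightness_replay_oracle(self, clean_scenes):
        """The brightness factor can be replayed from the seed and applied
        by hand: pixel-wise clip(image * b)."""
        img = next(iter(clean_scenes.images.values())).image
        seed = 123
        out = augment(img, ("brightness",), seed=seed)
        b = np.random.default_rng(seed).uniform(0.8, 1.2)
        expected = np.clip(img.astype(np.float32) * b, 0, 255).astype(np.uint8)
        np.testing.assert_array_equal(out, expected)

    def test_deterministic_per_seed(self, clean_scenes):
        img = next(iter(clean_scenes.images.values())).image
        a = augment(img, ("horizontal_flip", "brightness", "contrast"), seed=4)
        b = augment(img, ("horizontal_flip", "brightness", "contrast"), seed=4)
        np.testing.assert_array_equal(a, b)

    def test_preserves_dimensions(self, clean_scenes):
        img = next(iter(clean_scenes.images.values())).image
        assert augment(img, ("contrast",), seed=1).shape == img.shape

    def test_disallowed_transform_rejected(self, clean_scenes):
        img = next(iter(clean_scenes.images.values())).image
        with pytest.raises(AugmentationError, match="rotate"):
            augment(img, ("rotate",), seed=0)

    def test_config_rejects_disallowed_policy(self):
        with pytest.raises(AugmentationError):
            ClassifierConfig(augmentation=("crop",))


class TestDetectOverfit:
    def test_hand_traced_divergence(self):
        # validation rises at epochs 2,3,4 while training keeps falling:
        # the divergence starts at 0-based epoch 1
        train = [0.5, 0.4, 0.3, 0.2, 0.1]
        val = [0.5, 0.4, 0.45, 0.5, 0.55]
        assert detect_overfit(train, val, patience=2) == 1

    def test_monotone_decreasing_never_flags(self):
        train = [0.5, 0.4, 0.3, 0.2]
        val = [0.6, 0.5, 0.4, 0.3]
        assert detect_overfit(train, val, patience=2) is None

    def test_transient_rise_shorter_than_patience_not_flagged(self):
        train = [0.5, 0.4, 0.3, 0.2]
        val = [0.5, 0.4, 0.45, 0.40]
        assert detect_overfit(train, val, patience=2) is None

    def test_empty_trace_rejected(self):
        with pytest.raises(TrainingDataError):
            detect_overfit([], [], patience=1)

    def test_rise_with_rising_train_error_not_overfitting(self):
        # both errors rising = instability, not overfitting
        train = [0.5, 0.6, 0.7]
        val = [0.5, 0.6, 0.7]
        assert detect_overfit(train, val, patience=2) is None


class TestSelectBestCheckpoint:
    def test_plain_argmin(self):
        assert select_best_checkpoint([0.5, 0.3, 0.4]) == 1

    def test_restricted_argmin_before_overfit(self):
        assert select_best_checkpoint([0.5, 0.3, 0.2, 0.25, 0.3], overfit_epoch=3) == 2

    def test_tie_breaks_to_earlier_epoch(self):
        assert select_best_checkpoint([0.4, 0.4, 0.4]) == 0

    def test_empty_rejected(self):
        with pytest.raises(TrainingDataError):
            select_best_checkpoint([])


class TestTrainClassifier:
    def test_single_class_rejected_names_missing_class(self, clean_scenes_split):
        train, val, loader = clean_scenes_split
        degenerate = train[train["zebra_crosswalk"] == 0]
        with pytest.raises(TrainingDataError, match="present.*zebra"):
            train_classifier(degenerate, val, StreetFeature.ZEBRA_CROSSWALK, ClassifierConfig(), loader)

    def test_max_epochs_one(self, clean_scenes_split):
        train, val, loader = clean_scenes_split
        cfg = ClassifierConfig(epochs=1, seed=1)
        _, trace = train_classifier(train, val, StreetFeature.SIDEWALK, cfg, loader)
        assert len(trace.epochs) == 1
        assert trace.stop_reason == "max_epochs"

    def test_identical_train_and_validation_fits_without_overfit_flag(self, clean_scenes_split):
        train, _, loader = clean_scenes_split
        tiny = train.head(10)
        assert tiny["sidewalk"].nunique() == 2
        cfg = ClassifierConfig(epochs=40, seed=2, augmentation=())
        _, trace = train_classifier(tiny, tiny, StreetFeature.SIDEWALK, cfg, loader)
        assert trace.stop_reason != "overfit_detected"
        assert trace.train_errors[-1] < 0.2
        # validation error tracks training error on the identical split
        np.testing.assert_allclose(trace.train_errors, trace.validation_errors, rtol=1e-6)

    def test_reproducible_traces(self, clean_scenes_split):
        train, val, loader = clean_scenes_split
        cfg = ClassifierConfig(epochs=4, seed=7)
        _, t1 = train_classifier(train, val, StreetFeature.CURB_CUT, cfg, loader)
        _, t2 = train_classifier(train, val, StreetFeature.CURB_CUT, cfg, loader)
        assert t1.train_errors == t2.train_errors
        assert t1.validation_errors == t2.validation_errors

    def test_chosen_epoch_exists_in_trace(self, trained_sidewalk):
        clf, trace = trained_sidewalk
        assert 0 <= clf.provenance["chosen_epoch"] < len(trace.epochs)

    def test_errors_finite_and_nonnegative(self, trained_sidewalk):
        _, trace = trained_sidewalk
        errs = trace.train_errors + trace.validation_errors
        assert all(np.isfinite(e) and e >= 0 for e in errs)


class TestPredictProba:
    def test_probability_in_unit_interval_and_deterministic(self, trained_sidewalk, clean_scenes):
        clf, _ = trained_sidewalk
        img = next(iter(clean_scenes.images.values())).image
        p1 = clf.predict_proba(img)
        p2 = clf.predict_proba(img)
        assert 0.0 <= p1 <= 1.0
        assert p1 == p2

    def test_dimension_mismatch_rejected(self, trained_sidewalk):
        clf, _ = trained_sidewalk
        with pytest.raises(ValueError, match="shape"):
            clf.predict_proba(np.zeros((64, 64, 3), dtype=np.uint8))


class FixedProbClassifier:
    """Test double with preassigned probabilities per scene id."""

    def __init__(self, feature, probs):
        self.feature = feature
        self.probs = probs
        self.backbone = None

    def predict_proba(self, key):
        return self.probs[key]


class TestHarvestHardExamples:
    def _pool(self, labels):
        rows = [{"scene_id": sid, "path": f"{sid}.png", **{f.value: 0 for f in PRIMITIVE_FEATURES}} for sid in labels]
        df = pd.DataFrame(rows)
        df["zebra_crosswalk"] = [labels[sid] for sid in labels]
        return df

    def test_perfect_classifier_returns_empty(self):
        pool = self._pool({"a": 1, "b": 0})
        clf = FixedProbClassifier(StreetFeature.ZEBRA_CROSSWALK, {"a": 0.9, "b": 0.1})
        out = harvest_hard_examples(clf, pool, lambda sid: sid, k=5)
        assert len(out) == 0

    def test_k_truncation_returns_all_when_fewer(self):
        pool = self._pool({"a": 0, "b": 0, "c": 0, "d": 1})
        clf = FixedProbClassifier(StreetFeature.ZEBRA_CROSSWALK, {"a": 0.8, "b": 0.7, "c": 0.6, "d": 0.9})
        out = harvest_hard_examples(clf, pool, lambda sid: sid, k=10)
        assert len(out) == 3  # 3 false positives, no false negatives

    def test_ordered_by_confidence_descending(self):
        pool = self._pool({"a": 0, "b": 0, "c": 1})
        clf = FixedProbClassifier(StreetFeature.ZEBRA_CROSSWALK, {"a": 0.9, "b": 0.6, "c": 0.95})
        out = harvest_hard_examples(clf, pool, lambda sid: sid, k=10)
        assert list(out["scene_id"]) == ["a", "b"]
        assert list(out["prob"]) == [0.9, 0.6]


class TestPerFeatureIndependence:
    def test_training_ignores_other_feature_labels(self, clean_scenes_split):
        """Scrambling every other feature's label column leaves the trained
        model unchanged: one classifier per feature, no cross-reads."""
        train, val, loader = clean_scenes_split
        cfg = ClassifierConfig(epochs=3, seed=11)
        clf_a, _ = train_classifier(train, val, StreetFeature.WALK_SIGNAL, cfg, loader)

        rng = np.random.default_rng(0)
        scrambled_tr = train.copy()
        scrambled_va = val.copy()
        for f in PRIMITIVE_FEATURES:
            if f != StreetFeature.WALK_SIGNAL:
                scrambled_tr[f.value] = rng.integers(0, 2, len(scrambled_tr))
                scrambled_va[f.value] = rng.integers(0, 2, len(scrambled_va))
        clf_b, _ = train_classifier(scrambled_tr, scrambled_va, StreetFeature.WALK_SIGNAL, cfg, loader)
        np.testing.assert_array_equal(clf_a.weights, clf_b.weights)
        assert clf_a.bias == clf_b.bias
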