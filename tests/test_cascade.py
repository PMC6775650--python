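"""Two-stage SVM cascade: routing, determinism, fold structure."""

import numpy as np
import pandas as pd
import pytest

from drscascade import cascade as cc
from drscascade import evaluation as ev
from drscascade.errors import FoldError, GridMismatchError, TrainingError


def gaussian_classes(rng, n_per_class=40, spread=0.3):
    """Three well-separated Gaussian blobs in 5 dimensions."""
    centers = {
        "fat": np.array([3.0, 0.0, 0.0, 0.0, 0.0]),
        "wall": np.array([0.0, 3.0, 0.0, 0.0, 0.0]),
        "tumor": np.array([0.0, 0.0, 3.0, 0.0, 0.0]),
    }
    X, labels = [], []
    for cls, center in centers.items():
        X.append(center + spread * rng.standard_normal((n_per_class, 5)))
        labels += [cls] * n_per_class
    return np.vstack(X), np.array(labels)


def meta_for(labels, spectra_per_location=1):
    n = len(labels)
    ids = np.arange(n) // spectra_per_location
    return pd.DataFrame(
        {
            "measurement_id": [f"m{i}" for i in range(n)],
            "location_id": [f"L{i}" for i in ids],
            "patient_id": [f"P{i % 7}" for i in ids],
        }
    )


class TestTrainAndPredict:
    def test_separable_classes_reach_training_accuracy_one(self, rng):
        X, labels = gaussian_classes(rng)
        model = cc.train_cascade(X, labels)
        predicted = cc.score_cascade(model, X)["predicted_class"]
        assert (predicted.to_numpy() == labels).all()

    def test_training_is_deterministic(self, rng):
        X, labels = gaussian_classes(rng)
        a = cc.train_cascade(X, labels)
        b = cc.train_cascade(X, labels)
        np.testing.assert_array_equal(a.svm_fat.weights, b.svm_fat.weights)
        np.testing.assert_array_equal(a.svm_tumor.weights, b.svm_tumor.weights)
        assert a.svm_fat.bias == b.svm_fat.bias

    def test_missing_class_raises_training_error(self, rng):
        X, labels = gaussian_classes(rng)
        keep = labels != "tumor"
        with pytest.raises(TrainingError, match="tumor"):
            cc.train_cascade(X[keep], labels[keep])

    def test_fat_centroid_routes_to_fat_without_stage2_score(self, rng):
        X, labels = gaussian_classes(rng)
        model = cc.train_cascade(X, labels)
        record = cc.predict(model, np.array([3.0, 0.0, 0.0, 0.0, 0.0]))
        assert record.predicted_class == "fat"
        assert record.score_tumor is None

    def test_tie_at_threshold_goes_to_wall(self):
        # Hand-built discriminants: stage 1 pushes everything to non-fat,
        # stage 2 score is exactly the threshold -> wall by the strict rule.
        model = cc.CascadeModel(
            svm_fat=cc.LinearDiscriminant(np.array([0.0, 0.0]), -1.0),
            svm_tumor=cc.LinearDiscriminant(np.array([1.0, 0.0]), 0.0),
            tumor_threshold=0.5,
        )
        record = cc.predict(model, np.array([0.5, 0.0]))
        assert record.predicted_class == "wall"
        assert record.score_tumor == pytest.approx(0.5)

    def test_raising_threshold_never_creates_tumor_calls(self, rng):
        X, labels = gaussian_classes(rng, spread=1.5)
        model = cc.train_cascade(X, labels)
        low = cc.score_cascade(model, X)["predicted_class"].to_numpy()
        model_high = cc.CascadeModel(model.svm_fat, model.svm_tumor, tumor_threshold=1.0)
        high = cc.score_cascade(model_high, X)["predicted_class"].to_numpy()
        became_tumor = (low != "tumor") & (high == "tumor")
        assert not became_tumor.any()

    def test_dimension_mismatch_rejected(self, rng):
        X, labels = gaussian_classes(rng)
        model = cc.train_cascade(X, labels)
        with pytest.raises(GridMismatchError):
            cc.predict(model, np.zeros(7))

    def test_model_json_round_trip(self, rng):
        X, labels = gaussian_classes(rng)
        model = cc.train_cascade(X, labels, wavelengths=np.arange(5.0))
        restored = cc.CascadeModel.from_json(model.to_json())
        np.testing.assert_allclose(restored.svm_fat.weights, model.svm_fat.weights)
        np.testing.assert_allclose(restored.svm_tumor.weights, model.svm_tumor.weights)
        assert restored.tumor_threshold == model.tumor_threshold
        np.testing.assert_allclose(restored.wavelengths, model.wavelengths)


class TestCrossValidate:
    def test_each_spectrum_gets_one_prediction_per_repeat(self, rng):
        X, labels = gaussian_classes(rng, n_per_class=15)
        meta = meta_for(labels)
        preds = cc.cross_validate(X, meta, labels, k=5, repeats=3, seed=0)
        counts = preds.groupby("measurement_id").size()
        assert (counts == 3).all()
        per_repeat = preds.groupby(["repeat", "measurement_id"]).size()
        assert (per_repeat == 1).all()

    def test_folds_partition_locations_within_repeat(self, rng):
        X, labels = gaussian_classes(rng, n_per_class=15)
        meta = meta_for(labels)
        preds = cc.cross_validate(X, meta, labels, k=5, repeats=2, seed=0)
        for _, frame in preds.groupby("repeat"):
            fold_sets = frame.groupby("fold")["location_id"].apply(set)
            union = set().union(*fold_sets)
            assert union == set(meta["location_id"])
            assert sum(len(s) for s in fold_sets) == len(union)  # disjoint

    def test_replicates_stay_in_one_fold(self, rng):
        X, labels0 = gaussian_classes(rng, n_per_class=12)
        labels = np.repeat(labels0, 3, axis=0)
        X = np.repeat(X, 3, axis=0)
        meta = meta_for(labels, spectra_per_location=3)
        meta["measurement_id"] = [f"m{i}" for i in range(len(meta))]
        preds = cc.cross_validate(X, meta, labels, k=4, repeats=2, seed=1)
        spread = preds.groupby(["repeat", "location_id"])["fold"].nunique()
        assert (spread == 1).all()

    def test_leave_one_location_out(self, rng):
        X, labels = gaussian_classes(rng, n_per_class=4)
        meta = meta_for(labels)
        preds = cc.cross_validate(X, meta, labels, k=4, repeats=1, seed=0)
        assert preds["fold"].nunique() == 4

    def test_same_seed_reproduces_predictions(self, rng):
        X, labels = gaussian_classes(rng, n_per_class=15)
        meta = meta_for(labels)
        a = cc.cross_validate(X, meta, labels, k=5, repeats=2, seed=42)
        b = cc.cross_validate(X, meta, labels, k=5, repeats=2, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_patient_grouping_prevents_leakage(self, rng):
        X, labels = gaussian_classes(rng, n_per_class=21)
        meta = meta_for(labels)
        preds = cc.cross_validate(
            X, meta, labels, k=3, repeats=2, seed=0, group_by_patient=True
        )
        for _, frame in preds.groupby("repeat"):
            spread = frame.groupby("patient_id")["fold"].nunique()
            assert (spread == 1).all()

    def test_class_smaller_than_k_raises(self, rng):
        X, labels = gaussian_classes(rng, n_per_class=5)
        meta = meta_for(labels)
        with pytest.raises(FoldError):
            cc.cross_validate(X, meta, labels, k=8, repeats=1, seed=0)

    def test_permuted_labels_give_chance_level_mcc(self):
        # Null behaviour: with labels shuffled independently of the features
        # the cross-validated MCC must sit near zero (n = 600 spectra).
        rng = np.random.default_rng(7)
        X, labels = gaussian_classes(rng, n_per_class=200)
        permuted = rng.permutation(labels)
        meta = meta_for(permuted)
        preds = cc.cross_validate(X, meta, permuted, k=5, repeats=1, seed=0)
        for cls in ("fat", "wall", "tumor"):
            c = ev.confusion(preds["predicted_class"], preds["true_class"], cls)
            assert abs(ev.mcc(c)) < 0.15


def test_location_majority_vote_breaks_ties_toward_tumor():
    frame = pd.DataFrame(
        {
            "repeat": [0, 0, 0],
            "location_id": ["L0"] * 3,
            "patient_id": ["P0"] * 3,
            "predicted_class": ["fat", "wall", "tumor"],
            "tumor_score": [-1.0, 0.0, 1.0],
            "true_class": ["tumor"] * 3,
        }
    )
    out = cc.location_predictions(frame)
    assert out.loc[0, "predicted_class"] == "tumor"
    assert out.loc[0, "tumor_score"] == pytest.approx(0.0)
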