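"""Split protocol, metric suite vs brute-force oracle, training sanity and
modality subsetting."""

import numpy as np
import pytest

import gaitmotion as gm
from gaitmotion.models import ModelHandle
from gaitmotion.train_eval import (TrainConfig, metrics_from_predictions,
                                   modality_subset, repeat_runs,
                                   split_dataset)


def metrics_oracle(y_true, y_pred, n_classes=5):
    """Per-sample counting loops, independent of the implementation."""
    n = len(y_true)
    tc = sum(1 for t, p in zip(y_true, y_pred) if t == p)
    acc = tc / n
    precision, recall, f1 = [], [], []
    for c in range(n_classes):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        precision.append(prec)
        recall.append(rec)
        f1.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return acc, precision, recall, f1


class TestSplit:
    def test_stratified_80_20(self, two_subject_proc):
        train, test = split_dataset(two_subject_proc, 0.8, 0)
        n = len(two_subject_proc)
        assert len(train) == int(0.8 * n) and len(test) == n - int(0.8 * n)
        per_class = n // 5
        assert set(train.class_counts().values()) == {int(0.8 * per_class)}
        assert set(test.class_counts().values()) == {per_class - int(0.8 * per_class)}

    def test_same_seed_same_split(self, two_subject_proc):
        a_train, _ = split_dataset(two_subject_proc, 0.8, 5)
        b_train, _ = split_dataset(two_subject_proc, 0.8, 5)
        assert [id(t) for t in a_train.trials] == [id(t) for t in b_train.trials]

    def test_disjoint(self, two_subject_proc):
        train, test = split_dataset(two_subject_proc, 0.8, 1)
        assert {id(t) for t in train.trials} & {id(t) for t in test.trials} == set()

    def test_tiny_class_rejected(self, tiny_collection):
        one = tiny_collection.select([0])
        with pytest.raises(ValueError, match="need >= 2"):
            split_dataset(one, 0.8, 0)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.tile(np.arange(5), 4)
        rep = metrics_from_predictions(y, y)
        assert rep.accuracy == 1.0
        assert rep.macro_precision == rep.macro_recall == rep.macro_f1 == 1.0

    def test_binary_hand_computed_example(self):
        """TP=8, FP=2, FN=1 for the positive class."""
        y_true = [1] * 8 + [0] * 2 + [1] * 1 + [0] * 9
        y_pred = [1] * 8 + [1] * 2 + [0] * 1 + [0] * 9
        rep = metrics_from_predictions(y_true, y_pred, n_classes=2)
        assert round(rep.precision[1], 4) == 0.8
        assert round(rep.recall[1], 4) == 0.8889
        assert round(rep.f1[1], 4) == 0.8421

    def test_degenerate_single_prediction_class(self):
        y_true = np.tile(np.arange(5), 10)
        y_pred = np.zeros(50, dtype=int)
        rep = metrics_from_predictions(y_true, y_pred)
        assert rep.accuracy == 0.2
        assert rep.macro_recall == 0.2
        assert rep.macro_precision == 0.04

    def test_matches_counting_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(5, 1000))
            y_true = rng.integers(0, 5, n)
            y_pred = rng.integers(0, 5, n)
            rep = metrics_from_predictions(y_true, y_pred)
            acc, prec, rec, f1 = metrics_oracle(y_true, y_pred)
            assert rep.accuracy == pytest.approx(acc)
            np.testing.assert_allclose(rep.precision, prec)
            np.testing.assert_allclose(rep.recall, rec)
            np.testing.assert_allclose(rep.f1, f1)
            assert rep.confusion.sum() == n

    def test_macro_f1_is_mean_of_per_class_f1(self):
        """Pin the convention: macro-F1 averages per-class F1s, it is not
        the F1 of the macro precision/recall."""
        rng = np.random.default_rng(7)
        y_true = rng.integers(0, 5, 400)
        y_pred = rng.integers(0, 5, 400)
        rep = metrics_from_predictions(y_true, y_pred)
        assert rep.macro_f1 == pytest.approx(rep.f1.mean())
        alt = (2 * rep.macro_precision * rep.macro_recall
               / (rep.macro_precision + rep.macro_recall))
        assert rep.macro_f1 != pytest.approx(alt, abs=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_predictions(np.array([]), np.array([]))


class _ConstantScorer:
    """Stub estimator always scoring class 0 highest."""

    def fit(self, x, y):
        return self

    def decision_function(self, x):
        scores = np.zeros((x.shape[0], 5))
        scores[:, 0] = 1.0
        return scores


class TestTraining:
    def test_loss_decreases_over_training(self, cnn_runs):
        for run in cnn_runs:
            trace = run["model"].loss_trace
            assert trace[-1] < trace[0]

    def test_zero_epochs_is_identity(self, two_subject_proc):
        model = gm.build_cnn(seed=0)
        before = model.net.state()
        gm.train_model(model, two_subject_proc, TrainConfig(epochs=0), 0)
        after = model.net.state()
        for key in before:
            np.testing.assert_array_equal(before[key], after[key])
        assert model.loss_trace == []

    def test_single_class_training_rejected(self, two_subject_proc):
        squats = two_subject_proc.select(
            [i for i, t in enumerate(two_subject_proc.trials)
             if t.label == gm.MotionClass.squat])
        with pytest.raises(ValueError, match="2 classes"):
            gm.train_model(gm.build_cnn(), squats)

    def test_channel_mismatch_names_widths(self, two_subject_proc):
        model = gm.build_cnn(gm.CnnConfig(in_channels=22))
        with pytest.raises(ValueError, match="22.*35"):
            gm.train_model(model, two_subject_proc)


class TestRepeatRuns:
    def test_deterministic_metric_has_zero_std(self, two_subject_proc):
        def factory(seed):
            return ModelHandle(kind="svm", config={"in_channels": 35},
                               estimator=_ConstantScorer(), fitted=True)

        result = repeat_runs(factory, two_subject_proc,
                             TrainConfig(epochs=0), seeds=(0, 1, 2))
        acc = result["summary"]["accuracy"]
        assert acc["mean"] == pytest.approx(0.2)
        assert acc["std"] == pytest.approx(0.0, abs=1e-12)

    def test_aggregate_mean_is_arithmetic_mean(self, two_subject_proc):
        result = repeat_runs(lambda s: gm.random_classifier(seed=s),
                             two_subject_proc, TrainConfig(epochs=0),
                             seeds=(0, 1, 2))
        acc = result["summary"]["accuracy"]
        assert acc["mean"] == pytest.approx(np.mean(acc["per_seed"]))
        assert acc["std"] == pytest.approx(np.std(acc["per_seed"], ddof=1))

    def test_single_seed_rejected(self, two_subject_proc):
        with pytest.raises(ValueError, match="2 seeds"):
            repeat_runs(lambda s: gm.random_classifier(seed=s),
                        two_subject_proc, seeds=(0,))


class TestModalitySubset:
    def test_emg_all_keeps_8_channels(self, tiny_collection):
        sub = modality_subset(tiny_collection, "emg_all")
        assert len(sub.channel_names) == 8
        assert all(t.signal.shape[1] == 8 for t in sub.trials)
        assert all(n.startswith("emg_") for n in sub.channel_names)

    def test_right_leg_keeps_22_channels(self, tiny_collection):
        sub = modality_subset(tiny_collection, "leg_right")
        assert len(sub.channel_names) == 22

    def test_idempotent(self, tiny_collection):
        once = modality_subset(tiny_collection, "imu_all")
        twice = modality_subset(once, "imu_all")
        assert once.channel_names == twice.channel_names
        np.testing.assert_array_equal(once.trials[0].signal,
                                      twice.trials[0].signal)

    def test_columns_match_direct_indexing(self, tiny_collection):
        from gaitmotion.channels import DEFAULT_LAYOUT
        sub = modality_subset(tiny_collection, "imu_right_foot")
        cols = DEFAULT_LAYOUT.group("imu_right_foot")
        np.testing.assert_array_equal(sub.trials[0].signal,
                                      tiny_collection.trials[0].signal[:, cols])

    def test_unknown_group_lists_valid(self, tiny_collection):
        with pytest.raises(KeyError, match="leg_right"):
            modality_subset(tiny_collection, "torso")
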