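"""Windowing, metrics, training protocol and LOSO integrity."""

import numpy as np
import pytest
from sklearn.metrics import (accuracy_score, confusion_matrix,
                             precision_recall_fscore_support)

from sitskill.classifier import (EvalReport, MTSSample, TrainedClassifier,
                                 TrainingConfig, WindowedBatch,
                                 contingency_metrics, evaluate,
                                 loso_cross_validate, predict_trial,
                                 sliding_window, train_classifier)
from sitskill.features import MotionSeries
from sitskill.resnet import ResNetSpec


def make_sample(length, label=0, subject="S01", trial=1, seed=0, offset=0.0):
    rng = np.random.default_rng(seed)
    data = rng.normal(size=(length, 6)) + offset
    return MTSSample(series=MotionSeries(data=data, label=label), label=label,
                     subject_id=subject, trial_index=trial)


class TestSlidingWindow:
    def test_count_formula(self):
        batch = sliding_window(make_sample(100), window_length=30, stride=10)
        assert len(batch) == 8  # floor((100 - 30)/10) + 1

    def test_window_equal_to_series(self):
        s = make_sample(50)
        batch = sliding_window(s, 50, 10)
        assert len(batch) == 1
        assert np.array_equal(batch.windows[0], s.series.data)

    def test_provenance_reconstructs_windows(self):
        s = make_sample(64, subject="S07", trial=3)
        batch = sliding_window(s, 20, 7)
        for win, (sid, start) in zip(batch.windows, batch.provenance):
            assert sid == "S07:3"
            assert np.array_equal(win, s.series.data[start:start + 20])

    def test_short_series_skipped(self):
        batch = sliding_window(make_sample(10), 30, 10)
        assert len(batch) == 0

    def test_labels_inherited(self):
        batch = sliding_window(make_sample(60, label=2), 30, 15)
        assert np.all(batch.labels == 2)


class TestMetrics:
    def test_contingency_example(self):
        m = contingency_metrics(tp=9, fp=1, fn=2, tn=8)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["precision"] == pytest.approx(0.90)
        assert m["recall"] == pytest.approx(9 / 11)
        assert m["f1"] == pytest.approx(2 * 0.9 * (9 / 11) / (0.9 + 9 / 11))

    def test_perfect_predictions(self):
        rep = evaluate([0, 1, 2, 0, 1, 2], [0, 1, 2, 0, 1, 2])
        assert rep.accuracy == 1.0
        assert np.all(rep.precision == 1.0)
        assert np.all(rep.recall == 1.0)
        assert np.all(rep.f1 == 1.0)
        assert np.array_equal(rep.confusion, 2 * np.eye(3, dtype=int))

    def test_against_sklearn_oracle(self):
        """One hundred random prediction vectors agree with scikit-learn."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(5, 60))
            k = int(rng.integers(2, 5))
            truth = rng.integers(0, k, n)
            pred = rng.integers(0, k, n)
            rep = evaluate(pred, truth, n_classes=k)
            assert rep.accuracy == pytest.approx(
                accuracy_score(truth, pred), abs=1e-12)
            p, r, f, _ = precision_recall_fscore_support(
                truth, pred, labels=range(k), zero_division=0)
            assert np.allclose(rep.precision, p, atol=1e-12)
            assert np.allclose(rep.recall, r, atol=1e-12)
            assert np.allclose(rep.f1, f, atol=1e-12)
            assert np.array_equal(rep.confusion,
                                  confusion_matrix(truth, pred,
                                                   labels=range(k)))

    def test_random_predictions_near_chance(self):
        rng = np.random.default_rng(7)
        truth = np.repeat([0, 1, 2], 100)
        pred = rng.integers(0, 3, 300)
        rep = evaluate(pred, truth)
        assert abs(rep.accuracy - 1 / 3) <= 0.08

    def test_undefined_denominators_flagged(self):
        rep = evaluate([0, 0, 0], [0, 0, 1], n_classes=3)
        assert rep.precision[1] == 0.0 and rep.undefined[1]
        assert rep.undefined[2]  # class 2 absent from truth and predictions

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [])

    def test_confusion_sums_to_sample_count(self):
        rng = np.random.default_rng(1)
        truth = rng.integers(0, 3, 50)
        pred = rng.integers(0, 3, 50)
        rep = evaluate(pred, truth, n_classes=3)
        assert rep.confusion.sum() == 50


class _VoteStub(TrainedClassifier):
    """Deterministic window-level predictions for vote-rule tests."""

    def __init__(self, votes):
        self._votes = np.asarray(votes)

    def predict_windows(self, windows):
        return self._votes[:len(windows)]


class TestPredictTrial:
    def _sample(self, n_windows, window=10, stride=10):
        return make_sample(window + stride * (n_windows - 1), label=0)

    def test_unanimous(self):
        s = self._sample(4)
        assert predict_trial(_VoteStub([2, 2, 2, 2]), s, 10, 10) == 2

    def test_majority(self):
        s = self._sample(5)
        assert predict_trial(_VoteStub([0, 1, 0, 1, 0]), s, 10, 10) == 0

    def test_tie_breaks_to_lower_code(self):
        s = self._sample(4)
        assert predict_trial(_VoteStub([2, 1, 2, 1]), s, 10, 10) == 1

    def test_no_windows_raises(self):
        s = make_sample(5)
        with pytest.raises(ValueError):
            predict_trial(_VoteStub([0]), s, 100, 10)


def separable_windows(n_per_class=8, length=30, classes=2, seed=0):
    rng = np.random.default_rng(seed)
    X = np.concatenate([np.full((n_per_class, length, 6), 2.0 * c)
                        for c in range(classes)])
    X += 0.01 * rng.normal(size=X.shape)
    y = np.repeat(np.arange(classes), n_per_class)
    return WindowedBatch(windows=X, labels=y,
                         provenance=[("s", i) for i in range(len(X))])


class TestTrainClassifier:
    def test_overfits_separable_windows(self):
        batch = separable_windows()
        cfg = TrainingConfig(max_epochs=50, seed=0, runs=1,
                             spec=ResNetSpec().scaled(8))
        model = train_classifier(batch, cfg)
        preds = model.predict_windows(batch.windows)
        assert np.mean(preds == batch.labels) == 1.0

    def test_loss_decreases(self):
        batch = separable_windows()
        cfg = TrainingConfig(max_epochs=20, seed=0, runs=1,
                             spec=ResNetSpec().scaled(8))
        model = train_classifier(batch, cfg)
        assert min(model.loss_history) < model.loss_history[0]

    def test_seed_reproducibility(self):
        batch = separable_windows()
        cfg = TrainingConfig(max_epochs=10, seed=3, runs=1,
                             spec=ResNetSpec().scaled(8))
        a = train_classifier(batch, cfg)
        b = train_classifier(batch, cfg)
        assert a.loss_history == b.loss_history
        assert np.array_equal(a.predict_windows(batch.windows),
                              b.predict_windows(batch.windows))

    def test_single_class_rejected(self):
        batch = separable_windows(classes=2)
        batch.labels[:] = 0
        with pytest.raises(ValueError):
            train_classifier(batch, TrainingConfig())

    def test_standardization_uses_training_stats_only(self):
        """Frozen stats: shifting later (test) data must not change them."""
        batch = separable_windows()
        cfg = TrainingConfig(max_epochs=5, seed=0, runs=1,
                             spec=ResNetSpec().scaled(8))
        model = train_classifier(batch, cfg)
        assert np.allclose(model.mean, batch.windows.mean(axis=(0, 1)))
        assert np.allclose(model.std, batch.windows.std(axis=(0, 1)))
        test = batch.windows + 100.0
        shifted = model.standardize(test)
        # standardization is the frozen affine map, not re-estimated
        assert np.allclose(
            shifted, (test - model.mean) / model.std, atol=1e-12)
        assert shifted.mean() > 10.0  # a re-fit would have re-centered to ~0


def tiny_dataset(trials=5, length=260, gap=4.0, seed=0):
    """Six subjects x `trials`, three classes separated by channel offsets."""
    samples = []
    i = 0
    for label in (0, 1, 2):
        for subject in range(2):
            for trial in range(1, trials + 1):
                i += 1
                samples.append(make_sample(length, label=label,
                                           subject=f"C{label}S{subject}",
                                           trial=trial, seed=seed + i,
                                           offset=gap * label))
    return samples


class TestLOSO:
    def test_fold_structure_and_no_leakage(self):
        samples = tiny_dataset()
        subjects = {s.subject_id for s in samples}
        for fold in range(1, 6):
            test = [s for s in samples if s.trial_index == fold]
            train = [s for s in samples if s.trial_index != fold]
            assert {s.subject_id for s in test} == subjects
            assert len(test) == len(subjects)
            train_ids = {(s.subject_id, s.trial_index) for s in train}
            test_ids = {(s.subject_id, s.trial_index) for s in test}
            assert not train_ids & test_ids

    def test_separable_classes_classified(self):
        samples = tiny_dataset()
        cfg = TrainingConfig(max_epochs=8, seed=0, runs=1,
                             spec=ResNetSpec().scaled(8))
        res = loso_cross_validate(samples, cfg, window_length=90, stride=60)
        assert res.mean_accuracy >= 0.9
        # every fold's confusion counts one trial per subject
        for rep in res.fold_reports[0]:
            assert rep.confusion.sum() == 6

    def test_two_class_mode_drops_intermediates(self):
        samples = tiny_dataset()
        cfg = TrainingConfig(max_epochs=3, seed=0, runs=1,
                             spec=ResNetSpec().scaled(8))
        res = loso_cross_validate(samples, cfg, window_length=90, stride=60,
                                  classes=2)
        assert res.classes == 2
        pooled = res.pooled
        assert pooled.confusion.shape == (2, 2)
        # 4 subjects remain (novice + expert), 5 folds, 1 run
        assert pooled.confusion.sum() == 20

    def test_missing_trial_rejected(self):
        samples = tiny_dataset()[:-1]  # drop one trial
        with pytest.raises(ValueError):
            loso_cross_validate(samples, TrainingConfig())

    def test_report_serializes(self):
        samples = tiny_dataset()
        cfg = TrainingConfig(max_epochs=2, seed=1, runs=1,
                             spec=ResNetSpec().scaled(8))
        res = loso_cross_validate(samples, cfg, window_length=90, stride=90)
        d = res.to_dict()
        assert d["mean_accuracy"] == pytest.approx(res.mean_accuracy)
        assert len(d["per_fold"][0]) == 5
        assert len(d["run_seeds"]) == 1
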