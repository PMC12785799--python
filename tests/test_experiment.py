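import numpy as np
import pytest

from ecgfusion.experiment import (
    AblationConfig,
    TrainingConfig,
    confusion_and_metrics,
    records_to_segments,
    run_experiment,
    run_fold,
    stratified_kfold,
)
from ecgfusion.nn.model import ArchitectureSpec
from ecgfusion.synthetic import NO_NOISE, default_profiles, make_dataset

TINY_SPEC = ArchitectureSpec(input_shape=(32, 32, 3), stem_filters=8,
                             stage_filters=(8, 12, 16), stage_strides=(1, 2, 2),
                             n_classes=3, dropout_rate=0.0)


def separable_images(n_per_class=40, size=32, channels=3, seed=0):
    """Three classes with disjoint bright quadrants: separable by design."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for cls in range(3):
        for _ in range(n_per_class):
            img = 0.1 * rng.random((size, size, channels))
            sl = [slice(0, size // 2), slice(size // 2, size), slice(None)][cls]
            img[sl, sl if cls < 2 else slice(0, size // 2), :] += 0.8
            X.append(img)
            y.append(cls)
    return np.asarray(X, dtype=np.float32), np.asarray(y)


class TestStratifiedKFold:
    def test_even_folds_for_balanced_classes(self):
        labels = np.repeat(np.arange(10), 10)
        plan = stratified_kfold(labels, k=5, seed=0)
        for fold in range(5):
            sel = labels[plan.assignments == fold]
            _, counts = np.unique(sel, return_counts=True)
            assert np.all(counts == 2)

    def test_partition_property(self):
        labels = np.repeat(["x", "y"], 25)
        plan = stratified_kfold(labels, k=5, seed=1)
        assert sorted(np.unique(plan.assignments)) == [0, 1, 2, 3, 4]
        assert len(plan.assignments) == 50

    def test_deterministic_under_seed(self):
        labels = np.repeat(np.arange(5), 8)
        a = stratified_kfold(labels, seed=3).assignments
        b = stratified_kfold(labels, seed=3).assignments
        assert np.array_equal(a, b)

    def test_small_class_rejected_with_name(self):
        labels = np.array(["big"] * 20 + ["tiny"] * 3)
        with pytest.raises(ValueError, match="tiny"):
            stratified_kfold(labels, k=5)


class TestConfusionAndMetrics:
    def test_perfect_predictions_all_ones(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        probs = np.eye(3)[y]
        counts, rep = confusion_and_metrics(y, probs)
        for m in ("accuracy", "precision", "recall", "f1"):
            assert rep.macro[m] == pytest.approx(1.0)
        assert np.trace(counts.matrix) == 6

    def test_binary_counts_reproduce_formulas(self):
        # TP=50 FP=10 FN=5 TN=35 for class 1
        y = np.array([1] * 55 + [0] * 45)
        probs = np.zeros((100, 2))
        probs[:50, 1] = 1.0  # TP
        probs[50:55, 0] = 1.0  # FN
        probs[55:65, 1] = 1.0  # FP
        probs[65:, 0] = 1.0  # TN
        probs[probs.sum(axis=1) == 0] += 0.5
        _, rep = confusion_and_metrics(y, probs)
        c1 = rep.per_class["1"]
        assert c1["precision"] == pytest.approx(50 / 60)
        assert c1["recall"] == pytest.approx(50 / 55)
        assert c1["f1"] == pytest.approx(2 * 50 / (2 * 50 + 10 + 5))
        assert c1["accuracy"] == pytest.approx(0.85)

    def test_all_one_class_precision_equals_prevalence(self):
        y = np.array([0] * 30 + [1] * 70)
        probs = np.tile([0.0, 1.0], (100, 1))
        _, rep = confusion_and_metrics(y, probs)
        assert rep.per_class["1"]["precision"] == pytest.approx(0.7)

    def test_f1_is_harmonic_mean_identity(self, rng):
        y = rng.integers(0, 4, 200)
        logits = rng.standard_normal((200, 4))
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        _, rep = confusion_and_metrics(y, probs)
        for stats in rep.per_class.values():
            p, r = stats["precision"], stats["recall"]
            expected = 2 * p * r / (p + r) if p + r else 0.0
            assert stats["f1"] == pytest.approx(expected)

    def test_micro_precision_equals_overall_accuracy(self, rng):
        y = rng.integers(0, 3, 150)
        logits = rng.standard_normal((150, 3))
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        counts, _ = confusion_and_metrics(y, probs)
        micro_p = counts.tp.sum() / (counts.tp.sum() + counts.fp.sum())
        overall_acc = np.trace(counts.matrix) / len(y)
        assert micro_p == pytest.approx(overall_acc)

    def test_absent_class_flagged_and_excluded(self):
        y = np.array([0, 0, 1, 1])
        probs = np.eye(3)[[0, 0, 1, 2]]
        _, rep = confusion_and_metrics(y, probs)
        assert rep.undefined_recall_classes == ["2"]

    def test_confusion_row_sums_equal_true_counts(self, rng):
        y = rng.integers(0, 3, 90)
        probs = np.exp(rng.standard_normal((90, 3)))
        probs /= probs.sum(axis=1, keepdims=True)
        counts, _ = confusion_and_metrics(y, probs)
        np.testing.assert_array_equal(counts.matrix.sum(axis=1), np.bincount(y, minlength=3))


class TestRunFold:
    def test_separable_data_trains_to_high_accuracy(self):
        X, y = separable_images(seed=1)
        cfg = TrainingConfig(max_epochs=5, seed=1)
        model, hist = run_fold((X, y), (X[:30], y[:30]), TINY_SPEC, cfg)
        assert hist["train_acc"][-1] >= 0.9

    def test_early_stopping_on_plateau(self):
        X, y = separable_images(n_per_class=10, seed=2)
        # constant zero images: validation accuracy can never improve
        Xz = np.zeros_like(X)
        cfg = TrainingConfig(max_epochs=40, early_stop_patience=3, seed=2)
        _, hist = run_fold((Xz, y), (Xz[:10], y[:10]), TINY_SPEC, cfg)
        assert len(hist["val_acc"]) < 40

    def test_best_weights_restored(self):
        X, y = separable_images(n_per_class=12, seed=3)
        cfg = TrainingConfig(max_epochs=4, seed=3)
        model, hist = run_fold((X, y), (X[:18], y[:18]), TINY_SPEC, cfg)
        pv = model.predict_proba(X[:18])
        acc = float((pv.argmax(axis=1) == y[:18]).mean())
        assert acc == pytest.approx(max(hist["val_acc"]), abs=1e-6)


class TestRunExperiment:
    def test_hybrid_confusion_conserves_dataset(self):
        X, y = separable_images(n_per_class=15, seed=4)
        counts, rep, _ = run_experiment(
            X, y, AblationConfig("hybrid"), model_spec=TINY_SPEC,
            training=TrainingConfig(max_epochs=2, seed=4), n_folds=3, seed=4)
        assert counts.matrix.sum() == len(y)

    def test_single_channel_variant_runs_end_to_end(self):
        X, y = separable_images(n_per_class=15, seed=5)
        spec = ArchitectureSpec(input_shape=(32, 32, 1), stem_filters=8,
                                stage_filters=(8, 12, 16), stage_strides=(1, 2, 2),
                                n_classes=3, dropout_rate=0.0)
        counts, _, _ = run_experiment(
            X, y, AblationConfig("morl_only"), model_spec=spec,
            training=TrainingConfig(max_epochs=1, seed=5), n_folds=3,
            max_folds=1, seed=5)
        assert counts.matrix.sum() == 15

    def test_same_master_seed_reproduces_confusion(self):
        X, y = separable_images(n_per_class=12, seed=6)
        kw = dict(model_spec=TINY_SPEC, training=TrainingConfig(max_epochs=1, seed=6),
                  n_folds=3, max_folds=1, seed=6)
        a = run_experiment(X, y, AblationConfig("hybrid"), **kw)[0].matrix
        b = run_experiment(X, y, AblationConfig("hybrid"), **kw)[0].matrix
        assert np.array_equal(a, b)


def test_records_to_segments_labels_carried(profiles):
    recs = make_dataset(profiles, {"N": 1, "MI": 1}, duration=5.0, noise=NO_NOISE, seed=0)
    segs, labels = records_to_segments(recs, use_true_rpeaks=True)
    assert len(segs) == len(labels) > 0
    assert set(labels) == {"N", "MI"}
    assert all(len(s.samples) == 82 for s in segs)


def test_report_table_layout(rng):
    y = rng.integers(0, 3, 60)
    probs = np.exp(rng.standard_normal((60, 3)))
    probs /= probs.sum(axis=1, keepdims=True)
    from ecgfusion.experiment import report_table

    _, rep = confusion_and_metrics(y, probs)
    df = report_table(rep)
    assert list(df.columns) == ["accuracy", "precision", "recall", "f1"]
    assert df.index[-1] == "Average"
    assert (df.values <= 100.0).all()
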