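"""Splitting, metrics, ROC, the CV harness, and the baseline suite."""

import numpy as np
import pytest

from drowseeg.augment import AugmentSpec
from drowseeg.evaluate import (
    BaselinePipeline,
    ConfusionMatrix,
    SplitSpec,
    compute_metrics,
    holdout_split,
    kfold_split,
    roc_curve,
    run_baseline_suite,
    run_cv,
)
from drowseeg.features import FeatureMatrix
from tests.conftest import make_epochset


class TestHoldoutSplit:
    def test_1000_balanced_epochs_fraction_point2(self):
        es = make_epochset(n_epochs=1000, n_samples=20)
        train, held = holdout_split(es, SplitSpec(kind="holdout", test_fraction=0.2))
        assert len(held) == 200
        assert held.labels.count("sleepy") == 100
        assert held.labels.count("normal") == 100
        assert len(train) == 800

    def test_fraction_zero_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(kind="holdout", test_fraction=0.0)

    def test_same_seed_identical_membership(self):
        es = make_epochset(n_epochs=50, n_samples=20)
        spec = SplitSpec(kind="holdout", test_fraction=0.2, seed=3)
        _, a = holdout_split(es, spec)
        _, b = holdout_split(es, spec)
        assert [id(e) for e in a.epochs] == [id(e) for e in b.epochs]

    def test_group_by_subject_keeps_subjects_on_one_side(self):
        es = make_epochset(n_epochs=100, n_samples=20)
        spec = SplitSpec(kind="holdout", test_fraction=0.2, group_by_subject=True)
        train, held = holdout_split(es, spec)
        assert set(train.subject_ids).isdisjoint(held.subject_ids)

    def test_sides_are_disjoint_and_cover(self):
        es = make_epochset(n_epochs=40, n_samples=20)
        train, held = holdout_split(es, SplitSpec(kind="holdout", test_fraction=0.25))
        ids = [id(e) for e in train.epochs] + [id(e) for e in held.epochs]
        assert sorted(ids) == sorted(id(e) for e in es.epochs)


class TestKFoldSplit:
    def test_100_epochs_10_folds_of_10(self):
        es = make_epochset(n_epochs=100, n_samples=20)
        folds = kfold_split(es, SplitSpec(kind="kfold", k=10))
        assert len(folds) == 10
        assert all(len(te) == 10 for _, te in folds)
        union = np.sort(np.concatenate([te for _, te in folds]))
        assert np.array_equal(union, np.arange(100))

    def test_leave_one_out_when_k_equals_n(self):
        es = make_epochset(n_epochs=12, n_samples=20)
        folds = kfold_split(es, SplitSpec(kind="kfold", k=12))
        assert all(len(te) == 1 for _, te in folds)

    def test_95_epochs_10_folds_sizes(self):
        es = make_epochset(n_epochs=95, n_samples=20, labels=["normal"] * 48 + ["sleepy"] * 47)
        folds = kfold_split(es, SplitSpec(kind="kfold", k=10))
        sizes = sorted(len(te) for _, te in folds)
        assert sizes == [9] * 5 + [10] * 5

    def test_stratification_within_one_epoch(self):
        es = make_epochset(n_epochs=100, n_samples=20)
        folds = kfold_split(es, SplitSpec(kind="kfold", k=10))
        labels = np.array(es.labels)
        for _, te in folds:
            n_sleepy = np.sum(labels[te] == "sleepy")
            assert abs(n_sleepy - len(te) / 2) <= 1

    def test_k_larger_than_n_rejected(self):
        es = make_epochset(n_epochs=5, n_samples=20)
        with pytest.raises(ValueError):
            kfold_split(es, SplitSpec(kind="kfold", k=10))

    def test_k_one_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(kind="kfold", k=1)


class TestComputeMetrics:
    def _scores_for_confusion(self, tp, fp, fn, tn):
        y_true = ["sleepy"] * (tp + fn) + ["normal"] * (fp + tn)
        y_score = [0.9] * tp + [0.1] * fn + [0.9] * fp + [0.1] * tn
        return y_true, y_score

    def test_hand_computed_confusion_nine_one(self):
        y_true, y_score = self._scores_for_confusion(tp=9, fp=1, fn=1, tn=9)
        rep = compute_metrics(y_true, y_score)
        assert rep.accuracy == pytest.approx(0.9)
        assert rep.precision["sleepy"] == pytest.approx(0.9)
        assert rep.f1["sleepy"] == pytest.approx(0.9)
        assert (rep.confusion.tp, rep.confusion.fp, rep.confusion.fn, rep.confusion.tn) == (9, 1, 1, 9)

    def test_perfect_scores(self):
        y_true, y_score = self._scores_for_confusion(tp=5, fp=0, fn=0, tn=5)
        rep = compute_metrics(y_true, y_score)
        assert rep.accuracy == 1.0
        assert all(v == 1.0 for v in rep.precision.values())
        assert all(v == 1.0 for v in rep.f1.values())
        assert rep.auc == pytest.approx(1.0)

    def test_all_negative_predictions_flag_undefined_precision(self):
        y_true = ["sleepy", "sleepy", "normal", "normal"]
        rep = compute_metrics(y_true, [0.1, 0.2, 0.1, 0.2])
        assert "sleepy" in rep.undefined_precision
        assert rep.precision["sleepy"] == 0.0
        assert rep.accuracy == pytest.approx(0.5)  # tn / n

    def test_f1_is_harmonic_mean_identity(self):
        y_true, y_score = self._scores_for_confusion(tp=7, fp=3, fn=2, tn=8)
        rep = compute_metrics(y_true, y_score)
        for cls in ("sleepy", "normal"):
            p, r = rep.precision[cls], rep.recall[cls]
            assert rep.f1[cls] == pytest.approx(2 * p * r / (p + r))

    def test_accuracy_invariant_to_class_relabeling(self):
        y_true, y_score = self._scores_for_confusion(tp=7, fp=3, fn=2, tn=8)
        rep = compute_metrics(y_true, y_score)
        flipped_true = ["normal" if t == "sleepy" else "sleepy" for t in y_true]
        flipped = compute_metrics(flipped_true, [1 - s for s in y_score])
        assert flipped.accuracy == pytest.approx(rep.accuracy)
        assert (flipped.confusion.tp, flipped.confusion.tn) == (rep.confusion.tn, rep.confusion.tp)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_metrics([], [])

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(["sleepy"], [1.5])


class TestRocCurve:
    def test_perfect_separation_auc_one(self):
        y_true = ["normal"] * 5 + ["sleepy"] * 5
        y_score = [0.1, 0.2, 0.15, 0.05, 0.3, 0.7, 0.9, 0.8, 0.95, 0.75]
        points, auc = roc_curve(y_true, y_score)
        assert auc == pytest.approx(1.0)
        fprs = [p[0] for p in points]
        tprs = [p[1] for p in points]
        assert fprs == sorted(fprs) and tprs == sorted(tprs)
        assert points[0][:2] == (0.0, 0.0) and points[-1][:2] == (1.0, 1.0)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(0)
        y_true = ["sleepy" if b else "normal" for b in rng.integers(0, 2, 1000)]
        y_score = rng.random(1000)
        _, auc = roc_curve(y_true, y_score)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_score_reversal_maps_auc_to_complement(self):
        rng = np.random.default_rng(1)
        y_true = ["sleepy" if b else "normal" for b in rng.integers(0, 2, 200)]
        y_score = np.clip(rng.random(200) + 0.2 * (np.array(y_true) == "sleepy"), 0, 1)
        _, auc = roc_curve(y_true, y_score)
        _, auc_rev = roc_curve(y_true, 1 - y_score)
        assert auc_rev == pytest.approx(1 - auc, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve(["sleepy", "sleepy"], [0.1, 0.9])


class _ConstantModel:
    """Predicts the positive class with probability 0.5 + eps for everyone."""

    def fit(self, es):
        return self

    def predict_scores(self, es):
        return np.full(len(es), 0.51)


class TestRunCv:
    def test_k_folds_yield_k_fitted_models(self, toy_epochs):
        result = run_cv(toy_epochs, SplitSpec(kind="kfold", k=5), _ConstantModel)
        assert len(result.fitted_models) == 5
        assert len(result.fold_reports) == 5

    def test_constant_model_on_balanced_data_scores_half(self):
        es = make_epochset(n_epochs=100, n_samples=20)
        result = run_cv(es, SplitSpec(kind="kfold", k=10), _ConstantModel)
        assert result.mean_accuracy == pytest.approx(0.5, abs=0.01)

    def test_mean_sd_recomputable_from_fold_reports(self, toy_epochs):
        result = run_cv(toy_epochs, SplitSpec(kind="kfold", k=4), _ConstantModel)
        accs = np.array([r.accuracy for r in result.fold_reports])
        assert result.mean_accuracy == pytest.approx(accs.mean())
        assert result.sd_accuracy == pytest.approx(accs.std(ddof=0))

    def test_augmentation_confined_to_training_side(self):
        es = make_epochset(n_epochs=60, n_samples=40)
        seen_train_sizes = []

        class Spy(_ConstantModel):
            def fit(self, train_es):
                seen_train_sizes.append(len(train_es))
                assert any(e.augmented for e in train_es.epochs)
                return self

        run_cv(es, SplitSpec(kind="kfold", k=3),
               Spy, augment_spec=AugmentSpec(sigma=0.1, copies_per_epoch=2))
        assert seen_train_sizes == [120, 120, 120]  # 40 originals x 3 per fold

    def test_fold_train_test_disjoint(self):
        es = make_epochset(n_epochs=30, n_samples=20)
        folds = kfold_split(es, SplitSpec(kind="kfold", k=5))
        for tr, te in folds:
            assert set(tr).isdisjoint(te)


def _gaussian_features(n=200, separation=6.0, seed=0):
    rng = np.random.default_rng(seed)
    labels = ["sleepy" if i % 2 else "normal" for i in range(n)]
    shift = np.array([(separation if l == "sleepy" else 0.0) for l in labels])
    values = rng.standard_normal((n, 4)) + shift[:, None]
    return FeatureMatrix(values=values, feature_names=[f"f{i}" for i in range(4)],
                         labels=labels)


class TestBaselineSuite:
    def test_table_shape_rows_and_columns(self):
        fm = _gaussian_features()
        table = run_baseline_suite({"bp": fm, "csp": fm, "bp+csp": fm},
                                   SplitSpec(kind="kfold", k=4))
        assert list(table.index) == ["BP", "CSP", "BP+CSP"]
        assert list(table.columns) == ["Tree", "LDA", "SVM", "KNN"]

    def test_separable_features_all_cells_high(self):
        fm = _gaussian_features(separation=6.0)
        table = run_baseline_suite({"bp": fm}, SplitSpec(kind="kfold", k=4))
        assert (table.to_numpy() >= 0.95).all()

    def test_label_shuffled_features_near_chance(self):
        rng = np.random.default_rng(4)
        fm = _gaussian_features(n=1000, separation=0.0, seed=4)
        table = run_baseline_suite({"bp": fm}, SplitSpec(kind="kfold", k=5))
        assert np.all(np.abs(table.to_numpy() - 0.5) <= 0.07)

    def test_mismatched_epochs_rejected(self):
        a = _gaussian_features(n=100)
        b = _gaussian_features(n=80)
        with pytest.raises(ValueError, match="different epochs"):
            run_baseline_suite({"bp": a, "csp": b}, SplitSpec(kind="kfold", k=4))


class TestBaselinePipeline:
    def test_fit_predict_on_spectral_epochs(self, small_dataset):
        from drowseeg.preprocess import bandpass_filter, segment_dataset, zero_center_epochs

        es = segment_dataset([bandpass_filter(r) for r in small_dataset.recordings], 2.0)
        es = zero_center_epochs(es)
        clf = BaselinePipeline(feature_set="bp+csp", classifier="lda").fit(es)
        scores = clf.predict_scores(es)
        rep = compute_metrics(es.labels, scores)
        assert rep.accuracy > 0.8  # alpha- vs beta-dominant classes separate in-sample

    def test_invalid_feature_set_rejected(self):
        with pytest.raises(ValueError):
            BaselinePipeline(feature_set="psd")


def test_confusion_matrix_rejects_negative_counts():
    with pytest.raises(ValueError):
        ConfusionMatrix(tp=-1, fp=0, fn=0, tn=0)
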