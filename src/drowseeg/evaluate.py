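"""Evaluation harness: holdout and k-fold splitting, classification
metrics (accuracy, per-class precision and F1, ROC/AUC, confusion matrix),
cross-validated model runs, and the classical baseline suite.

The k-fold harness follows the usual shuffled 10-fold scheme with a fixed
random state; stratification keeps per-fold class proportions within one
epoch of the global proportions.  Data augmentation, when requested, is
applied strictly after splitting and only to the training side of each
fold, so no augmented copy of a test epoch can leak into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import (
    GroupShuffleSplit,
    KFold,
    StratifiedGroupKFold,
    StratifiedKFold,
    train_test_split,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from drowseeg.augment import AugmentSpec, augment_epochset
from drowseeg.deepnet import NetworkConfig, train_network
from drowseeg.features import (
    FeatureMatrix,
    apply_csp,
    band_power_features,
    concat_features,
    fit_csp,
)
from drowseeg.preprocess import EpochSet
from drowseeg.synth import SLEEPY

#: label treated as the positive detection target
POSITIVE_LABEL = SLEEPY


@dataclass
class SplitSpec:
    """How to split epochs for evaluation."""

    kind: str = "kfold"  # {holdout, kfold}
    test_fraction: float = 0.2
    k: int = 10
    shuffle: bool = True
    seed: int = 0
    group_by_subject: bool = False
    stratify: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("holdout", "kfold"):
            raise ValueError("kind must be holdout or kfold")
        if self.kind == "holdout" and not 0 < self.test_fraction < 1:
            raise ValueError("holdout needs test_fraction in (0, 1)")
        if self.kind == "kfold" and self.k < 2:
            raise ValueError("kfold needs k >= 2")


def holdout_split(es: EpochSet, spec: SplitSpec) -> tuple[EpochSet, EpochSet]:
    """Stratified holdout: the heldout side gets ``test_fraction`` of each
    class (within one epoch); with ``group_by_subject`` no subject spans
    both sides."""
    if spec.kind != "holdout":
        raise ValueError("spec.kind must be holdout")
    n = len(es)
    if n < 2:
        raise ValueError("need at least two epochs to split")
    indices = np.arange(n)
    labels = np.array(es.labels)
    if spec.group_by_subject:
        gss = GroupShuffleSplit(n_splits=1, test_size=spec.test_fraction, random_state=spec.seed)
        train_idx, test_idx = next(gss.split(indices, labels, groups=es.subject_ids))
    else:
        train_idx, test_idx = train_test_split(
            indices,
            test_size=spec.test_fraction,
            stratify=labels if spec.stratify else None,
            shuffle=spec.shuffle,
            random_state=spec.seed,
        )
    if len(train_idx) == 0 or len(test_idx) == 0:
        raise ValueError("split leaves an empty side")
    return es.subset(np.sort(train_idx)), es.subset(np.sort(test_idx))


def kfold_split(es: EpochSet, spec: SplitSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled k-fold index partitions, stratified by default.

    When k exceeds the smallest class count (e.g. leave-one-out),
    stratification is infeasible and plain shuffled folds are used.
    """
    if spec.kind != "kfold":
        raise ValueError("spec.kind must be kfold")
    n = len(es)
    if spec.k > n:
        raise ValueError(f"k={spec.k} exceeds epoch count {n}")
    labels = np.array(es.labels)
    rs = spec.seed if spec.shuffle else None
    min_class = min(np.bincount(np.unique(labels, return_inverse=True)[1]))
    if spec.group_by_subject:
        splitter = StratifiedGroupKFold(n_splits=spec.k, shuffle=spec.shuffle, random_state=rs)
        gen = splitter.split(np.zeros(n), labels, groups=es.subject_ids)
    elif spec.stratify and spec.k <= min_class:
        splitter = StratifiedKFold(n_splits=spec.k, shuffle=spec.shuffle, random_state=rs)
        gen = splitter.split(np.zeros(n), labels)
    else:
        splitter = KFold(n_splits=spec.k, shuffle=spec.shuffle, random_state=rs)
        gen = splitter.split(np.zeros(n))
    return [(np.asarray(tr), np.asarray(te)) for tr, te in gen]


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class EvalReport:
    """Metrics of one evaluated split."""

    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    confusion: ConfusionMatrix
    roc: list[tuple[float, float, float]]
    auc: float
    positive_threshold: float
    undefined_precision: list[str] = field(default_factory=list)


@dataclass
class CVResult:
    fold_reports: list[EvalReport]
    mean_accuracy: float
    sd_accuracy: float
    fitted_models: list

    def __post_init__(self) -> None:
        accs = np.array([r.accuracy for r in self.fold_reports])
        if accs.size and not (
            np.isclose(self.mean_accuracy, accs.mean())
            and np.isclose(self.sd_accuracy, accs.std(ddof=0))
        ):
            raise ValueError("mean/sd inconsistent with fold accuracies")


def _binary_counts(truth_pos: np.ndarray, pred_pos: np.ndarray) -> ConfusionMatrix:
    return ConfusionMatrix(
        tp=int(np.sum(truth_pos & pred_pos)),
        fp=int(np.sum(~truth_pos & pred_pos)),
        fn=int(np.sum(truth_pos & ~pred_pos)),
        tn=int(np.sum(~truth_pos & ~pred_pos)),
    )


def roc_curve(y_true, y_score, positive_label: str = POSITIVE_LABEL):
    """ROC points (fpr, tpr, threshold) swept over the unique scores, plus
    the trapezoid-rule AUC."""
    truth = np.array([t == positive_label for t in y_true])
    if truth.all() or not truth.any():
        raise ValueError("ROC needs both classes present in the truth")
    fpr, tpr, thresholds = skmetrics.roc_curve(truth.astype(int), np.asarray(y_score))
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist(), thresholds.tolist())), auc


def compute_metrics(
    y_true,
    y_score,
    positive_threshold: float = 0.5,
    positive_label: str = POSITIVE_LABEL,
) -> EvalReport:
    """Threshold the scores and compute accuracy, per-class precision,
    recall and F1 (each class in turn taken as positive), the confusion
    matrix for the positive class, and the ROC/AUC when both classes are
    present.  Undefined precision (no positive predictions) is reported as
    0 and flagged."""
    y_true = list(y_true)
    y_score = np.asarray(y_score, dtype=float)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_score):
        raise ValueError("y_true and y_score lengths differ")
    if np.any((y_score < 0) | (y_score > 1)):
        raise ValueError("scores must lie in [0, 1]")
    classes = sorted(set(y_true) | {positive_label})
    truth_pos = np.array([t == positive_label for t in y_true])
    pred_pos = y_score >= positive_threshold
    cm = _binary_counts(truth_pos, pred_pos)
    accuracy = (cm.tp + cm.tn) / cm.total

    precision, recall, f1, undefined = {}, {}, {}, []
    for cls in classes:
        t = np.array([x == cls for x in y_true])
        p = pred_pos if cls == positive_label else ~pred_pos
        c = _binary_counts(t, p)
        if c.tp + c.fp == 0:
            precision[cls] = 0.0
            undefined.append(cls)
        else:
            precision[cls] = c.tp / (c.tp + c.fp)
        recall[cls] = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
        pr, rc = precision[cls], recall[cls]
        f1[cls] = 2 * pr * rc / (pr + rc) if (pr + rc) else 0.0

    if truth_pos.any() and not truth_pos.all():
        roc, auc = roc_curve(y_true, y_score, positive_label)
    else:
        roc, auc = [], float("nan")
    return EvalReport(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        confusion=cm, roc=roc, auc=auc, positive_threshold=positive_threshold,
        undefined_precision=undefined,
    )


# ---------------------------------------------------------------------------
# Classifier adapters


def _make_classifier(name: str, seed: int = 0):
    name = name.lower()
    if name == "tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "lda":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    if name == "svm":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    raise ValueError(f"unknown classifier {name!r}")


class BaselinePipeline:
    """Classical pipeline: feature extraction (BP, CSP, or both) fitted on
    the training epochs only, feature standardization, and one of the four
    baseline classifiers."""

    def __init__(self, feature_set: str = "bp+csp", classifier: str = "svm",
                 n_csp_components: int = 4, seed: int = 0):
        if feature_set not in ("bp", "csp", "bp+csp"):
            raise ValueError("feature_set must be bp, csp, or bp+csp")
        self.feature_set = feature_set
        self.classifier_name = classifier
        self.n_csp_components = n_csp_components
        self.seed = seed
        self._csp = None
        self._clf = None
        self._classes: list[str] = []

    def _features(self, es: EpochSet) -> FeatureMatrix:
        parts = []
        if "bp" in self.feature_set:
            parts.append(band_power_features(es))
        if "csp" in self.feature_set:
            parts.append(apply_csp(self._csp, es))
        fm = parts[0]
        for p in parts[1:]:
            fm = concat_features(fm, p)
        return fm

    def fit(self, es: EpochSet) -> "BaselinePipeline":
        if "csp" in self.feature_set:
            self._csp = fit_csp(es, n_components=self.n_csp_components)
        fm = self._features(es)
        self._classes = sorted(set(fm.labels))
        self._clf = make_pipeline(StandardScaler(), _make_classifier(self.classifier_name, self.seed))
        self._clf.fit(fm.values, fm.labels)
        return self

    def predict_scores(self, es: EpochSet) -> np.ndarray:
        fm = self._features(es)
        proba = self._clf.predict_proba(fm.values)
        cols = list(self._clf.classes_)
        if POSITIVE_LABEL in cols:
            return proba[:, cols.index(POSITIVE_LABEL)]
        return proba[:, -1]


class CompactCNNClassifier:
    """Harness adapter for the compact CNN: carves a validation share out
    of the training epochs (for early stopping and the training log) and
    trains the network on the rest."""

    def __init__(self, config: NetworkConfig, val_fraction: float = 0.1):
        self.config = config
        self.val_fraction = val_fraction
        self.trained = None

    def fit(self, es: EpochSet) -> "CompactCNNClassifier":
        spec = SplitSpec(kind="holdout", test_fraction=self.val_fraction, seed=self.config.seed)
        train, val = holdout_split(es, spec)
        self.trained = train_network(self.config, train, val)
        return self

    def predict_scores(self, es: EpochSet) -> np.ndarray:
        proba = self.trained.predict_proba(es)
        if POSITIVE_LABEL in self.trained.classes:
            return proba[:, self.trained.classes.index(POSITIVE_LABEL)]
        return proba[:, -1]


def run_cv(
    es: EpochSet,
    spec: SplitSpec,
    model_builder,
    augment_spec: AugmentSpec | None = None,
    positive_threshold: float = 0.5,
) -> CVResult:
    """k-fold cross-validation: one model per fold, trained on the fold's
    training side (augmented there and only there, if requested) and
    evaluated on the untouched test side."""
    folds = kfold_split(es, spec)
    reports, models = [], []
    for fold_no, (train_idx, test_idx) in enumerate(folds):
        train_es = es.subset(train_idx)
        test_es = es.subset(test_idx)
        if len(set(train_es.labels)) < 2:
            raise ValueError(f"fold {fold_no}: training side is single-class")
        if augment_spec is not None and augment_spec.copies_per_epoch > 0:
            fold_aug = replace(augment_spec, seed=int(augment_spec.seed + fold_no))
            train_es = augment_epochset(train_es, fold_aug)
        assert not any(e.augmented for e in test_es.epochs), "augmented epoch leaked into test"
        model = model_builder()
        model.fit(train_es)
        scores = model.predict_scores(test_es)
        reports.append(compute_metrics(test_es.labels, scores, positive_threshold))
        models.append(model)
    accs = np.array([r.accuracy for r in reports])
    return CVResult(
        fold_reports=reports,
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=0)),
        fitted_models=models,
    )


BASELINE_ROWS = {"bp": "BP", "csp": "CSP", "bp+csp": "BP+CSP"}
BASELINE_COLUMNS = {"tree": "Tree", "lda": "LDA", "svm": "SVM", "knn": "KNN"}


def run_baseline_suite(
    features_by_set: dict[str, FeatureMatrix], spec: SplitSpec
) -> pd.DataFrame:
    """Mean k-fold accuracy of Tree/LDA/SVM/KNN on each precomputed
    feature set, under identical splits across sets.  Returns a table with
    feature-set rows and classifier columns."""
    names = list(features_by_set)
    first = features_by_set[names[0]]
    for name in names[1:]:
        other = features_by_set[name]
        if other.n_epochs != first.n_epochs or other.labels != first.labels:
            raise ValueError(f"feature set {name!r} covers different epochs")
    labels = np.array(first.labels)
    n = len(labels)
    if spec.kind != "kfold":
        raise ValueError("baseline suite uses k-fold splits")
    rs = spec.seed if spec.shuffle else None
    splitter = (
        StratifiedKFold(n_splits=spec.k, shuffle=spec.shuffle, random_state=rs)
        if spec.stratify
        else KFold(n_splits=spec.k, shuffle=spec.shuffle, random_state=rs)
    )
    folds = list(splitter.split(np.zeros(n), labels))

    table = pd.DataFrame(
        index=[BASELINE_ROWS.get(k, k) for k in names],
        columns=list(BASELINE_COLUMNS.values()),
        dtype=float,
    )
    for set_name in names:
        fm = features_by_set[set_name]
        for clf_key, col in BASELINE_COLUMNS.items():
            accs = []
            for train_idx, test_idx in folds:
                clf = make_pipeline(StandardScaler(), _make_classifier(clf_key, spec.seed))
                clf.fit(fm.values[train_idx], labels[train_idx])
                accs.append(clf.score(fm.values[test_idx], labels[test_idx]))
            table.loc[BASELINE_ROWS.get(set_name, set_name), col] = float(np.mean(accs))
    return table
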