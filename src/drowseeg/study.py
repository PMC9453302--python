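"""Canned end-to-end recovery experiments at desk scale.

These helpers wire the full pipeline into a single reproducible
experiment: simulate a two-group cohort with a 3:1 alpha/beta band-power
separation between classes, preprocess into labeled 2 s epochs, and
cross-validate both the classical SVM-on-BP+CSP pipeline and the compact
CNN, together with a label-shuffled null control.  The simulation runs at
a 125 Hz sampling rate, which preserves the full 1-30 Hz analysis band
(Nyquist 62.5 Hz) while keeping the experiment fast on one CPU.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from drowseeg.config import RunConfig, SourceConfig, sleepy_normal_specs
from drowseeg.deepnet import build_compact_net
from drowseeg.evaluate import (
    BaselinePipeline,
    CompactCNNClassifier,
    SplitSpec,
    compute_metrics,
    holdout_split,
    run_cv,
)
from drowseeg.preprocess import (
    EpochSet,
    bandpass_filter,
    reject_artifacts,
    segment_dataset,
    zero_center_epochs,
)
from drowseeg.synth import SessionProtocol, default_mixing_model, generate_dataset


def make_study_epochs(
    seed: int,
    n_epochs: int = 2000,
    n_subjects: int = 20,
    rate: float = 125.0,
    window: float = 2.0,
    power_ratio: float = 3.0,
) -> EpochSet:
    """Simulate and preprocess a balanced two-group cohort.

    Each of ``n_subjects`` contributes one session long enough that the
    cohort yields ``n_epochs`` non-overlapping windows in total.
    """
    if n_epochs % n_subjects:
        raise ValueError("n_epochs must divide evenly across subjects")
    per_subject = n_epochs // n_subjects
    half = n_subjects // 2
    groups = {
        f"s{i:02d}": ("normal" if i <= half else "deprived")
        for i in range(1, n_subjects + 1)
    }
    protocol = SessionProtocol(
        n_subjects=n_subjects,
        n_sessions_per_subject=1,
        session_duration=per_subject * window,
        sampling_rate=rate,
        n_channels=8,
        group_assignment=groups,
    )
    cfg = RunConfig(seed=seed, sources=SourceConfig(power_ratio=power_ratio))
    sleepy_spec, normal_spec = sleepy_normal_specs(cfg)
    model = default_mixing_model(n_channels=8, seed=seed)
    ds = generate_dataset(protocol, sleepy_spec, normal_spec, model, seed=seed)
    es = segment_dataset([bandpass_filter(r) for r in ds.recordings], window)
    es = zero_center_epochs(es)
    return reject_artifacts(es, amplitude_limit=100.0)


def shuffle_labels(es: EpochSet, seed: int) -> EpochSet:
    """Break the label-signal association while keeping class balance."""
    rng = np.random.default_rng(seed)
    labels = list(es.labels)
    rng.shuffle(labels)
    return replace(
        es,
        epochs=[replace(e, label=l) for e, l in zip(es.epochs, labels)],
    )


def svm_bp_csp_cv(es: EpochSet, seed: int, k: int = 10):
    """10-fold CV of the RBF-SVM on concatenated BP+CSP features."""
    return run_cv(
        es,
        SplitSpec(kind="kfold", k=k, seed=seed),
        lambda: BaselinePipeline(feature_set="bp+csp", classifier="svm", seed=seed),
    )


def compact_cnn_cv(es: EpochSet, seed: int, k: int = 10):
    """10-fold CV of the compact CNN (<= 20 training epochs per fold)."""
    shape = (es.epochs[0].data.shape[0], es.epochs[0].data.shape[1])
    config = build_compact_net(input_shape=shape, seed=seed)
    return run_cv(es, SplitSpec(kind="kfold", k=k, seed=seed),
                  lambda: CompactCNNClassifier(config))


def shuffled_control_accuracy(es: EpochSet, seed: int, n_test: int = 200) -> float:
    """Accuracy of the SVM pipeline after label shuffling, on a held-out
    test side of ``n_test`` epochs — the chance-level null experiment."""
    shuffled = shuffle_labels(es, seed)
    frac = n_test / len(shuffled)
    train, test = holdout_split(
        shuffled, SplitSpec(kind="holdout", test_fraction=frac, seed=seed)
    )
    clf = BaselinePipeline(feature_set="bp+csp", classifier="svm", seed=seed).fit(train)
    report = compute_metrics(test.labels, clf.predict_scores(test))
    return report.accuracy
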