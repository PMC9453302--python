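"""End-to-end pipeline: simulate -> filter -> segment -> reject -> split ->
augment (training side only) -> classical baselines and/or CNN -> evaluate.

Each run writes a directory containing a JSON manifest (resolved config,
seeds, stage epoch counts, data hashes), the Table-style training log CSV
when a network is trained, an evaluation report CSV, and the baseline
accuracy table CSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import pandas as pd

from drowseeg import io
from drowseeg.augment import augment_epochset
from drowseeg.config import RunConfig, sleepy_normal_specs
from drowseeg.deepnet import (
    build_compact_net,
    build_transfer_variant,
    make_finetune_plan,
    train_network,
)
from drowseeg.evaluate import (
    BaselinePipeline,
    EvalReport,
    SplitSpec,
    compute_metrics,
    holdout_split,
    run_baseline_suite,
)
from drowseeg.features import apply_csp, band_power_features, concat_features, fit_csp
from drowseeg.preprocess import (
    bandpass_filter,
    reject_artifacts,
    segment_dataset,
    zero_center_epochs,
)
from drowseeg.synth import default_mixing_model, generate_dataset

log = logging.getLogger(__name__)

CLASSICAL_MODELS = ("svm", "lda", "knn", "tree")
NETWORK_MODELS = ("compact_1d", "transfer_table1")


def _report_to_frame(report: EvalReport) -> pd.DataFrame:
    rows = []
    for cls in sorted(report.precision):
        rows.append(
            {
                "class": cls,
                "accuracy": report.accuracy,
                "precision": report.precision[cls],
                "recall": report.recall[cls],
                "f1": report.f1[cls],
                "auc": report.auc,
                "threshold": report.positive_threshold,
                "precision_undefined": cls in report.undefined_precision,
            }
        )
    return pd.DataFrame(rows)


def _build_network_config(cfg: RunConfig, input_shape):
    net = cfg.network
    if net.variant == "compact_1d":
        config = build_compact_net(
            input_shape=input_shape,
            conv_filters=net.conv_filters,
            fc_units=net.fc_units,
            seed=cfg.seed,
        )
    elif net.variant == "transfer_table1":
        config = build_transfer_variant(input_shape=input_shape, seed=cfg.seed)
    else:
        raise ValueError(f"unknown network variant {net.variant!r}")
    config = replace(
        config,
        base_learning_rate=net.base_learning_rate,
        momentum=net.momentum,
        batch_size=net.batch_size,
        max_epochs=net.max_epochs,
        patience=net.patience,
    )
    if net.finetune_first_trainable is not None:
        config = make_finetune_plan(config, net.finetune_first_trainable)
    return config


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline described by ``cfg`` into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_dict(), "stages": {}}

    def stage(name: str, **info):
        log.info("stage %s: %s", name, info)
        manifest["stages"][name] = info

    # simulate
    sleepy_spec, normal_spec = sleepy_normal_specs(cfg)
    model = default_mixing_model(
        n_channels=cfg.protocol.n_channels,
        leakage_sd=cfg.mixing.leakage_sd,
        sensor_noise_sd=cfg.mixing.sensor_noise_sd,
        seed=cfg.seed,
    )
    ds = generate_dataset(cfg.protocol, sleepy_spec, normal_spec, model, seed=cfg.seed)
    stage("simulate", recordings=len(ds.recordings))

    # filter + segment + normalize + reject
    filtered = [bandpass_filter(r, cfg.filter) for r in ds.recordings]
    es = segment_dataset(filtered, cfg.segmentation.window, cfg.segmentation.overlap_fraction)
    es = zero_center_epochs(es)
    n_before = len(es)
    es = reject_artifacts(es, cfg.segmentation.amplitude_limit)
    stage("preprocess", epochs_in=n_before, epochs_out=len(es))
    manifest["data_hash"] = io.epochset_hash(es)

    # split 80/20, then carve the 20% into validation and test halves
    ev = cfg.evaluation
    split = SplitSpec(
        kind="holdout", test_fraction=ev.test_fraction, seed=cfg.seed,
        group_by_subject=ev.group_by_subject, stratify=ev.stratify,
    )
    train_es, heldout = holdout_split(es, split)
    val_es, test_es = holdout_split(
        heldout, SplitSpec(kind="holdout", test_fraction=0.5, seed=cfg.seed + 1)
    )
    stage("split", train=len(train_es), val=len(val_es), test=len(test_es))

    # augmentation: training side only
    if cfg.augment.copies_per_epoch > 0:
        train_es = augment_epochset(train_es, replace(cfg.augment, seed=cfg.seed))
    stage("augment", train_epochs=len(train_es), copies=cfg.augment.copies_per_epoch)

    # classical baselines on the unaugmented pool
    if ev.run_baselines:
        csp = fit_csp(es, n_components=cfg.features.n_csp_components)
        bp = band_power_features(es, log_transform=cfg.features.log_band_power)
        cspf = apply_csp(csp, es)
        suite = run_baseline_suite(
            {"bp": bp, "csp": cspf, "bp+csp": concat_features(bp, cspf)},
            SplitSpec(kind="kfold", k=ev.k, seed=cfg.seed, stratify=ev.stratify),
        )
        suite.to_csv(out_dir / "baseline_table.csv")
        io.write_csp_model(csp, out_dir / "csp_model.json")
        stage("baselines", table="baseline_table.csv")

    # primary model
    if ev.model in NETWORK_MODELS:
        window_samples = train_es.epochs[0].data.shape[1]
        net_config = _build_network_config(
            cfg, (cfg.protocol.n_channels, window_samples)
        )
        trained = train_network(net_config, train_es, val_es)
        trained.log.to_dataframe().to_csv(out_dir / "training_log.csv", index=False)
        scores = trained.predict_scores(test_es)
        stage("train", variant=ev.model, log_rows=len(trained.log.rows))
    elif ev.model in CLASSICAL_MODELS:
        clf = BaselinePipeline(
            feature_set=ev.feature_set, classifier=ev.model,
            n_csp_components=cfg.features.n_csp_components, seed=cfg.seed,
        ).fit(train_es)
        scores = clf.predict_scores(test_es)
        stage("train", model=ev.model, feature_set=ev.feature_set)
    else:
        raise ValueError(f"unknown evaluation model {ev.model!r}")

    report = compute_metrics(test_es.labels, scores, ev.positive_threshold)
    _report_to_frame(report).to_csv(out_dir / "eval_report.csv", index=False)
    stage("evaluate", test_accuracy=report.accuracy, auc=report.auc)

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return out_dir
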