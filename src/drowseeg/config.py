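"""YAML run configuration.

A run config has sections ``protocol`` / ``sources`` / ``mixing`` /
``filter`` / ``segmentation`` / ``augment`` / ``features`` / ``network`` /
``evaluation`` plus a global ``seed``; every pipeline default can be
overridden, and unknown keys are rejected so typos fail fast.  The fully
resolved document is serialized into the run manifest for provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from drowseeg.augment import AugmentSpec
from drowseeg.preprocess import FilterSpec
from drowseeg.synth import SessionProtocol


@dataclass
class SourceConfig:
    """Class-separation knobs for the simulator: the sleepy class gets an
    alpha/beta band-power ratio of ``power_ratio`` and the alert class its
    reciprocal."""

    power_ratio: float = 3.0
    background_amplitude: float = 1.0
    background_exponent: float = 1.0
    per_subject_gain_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.power_ratio <= 1:
            raise ValueError("power_ratio must be > 1 (sleepy must be alpha-dominant)")


@dataclass
class MixingConfig:
    leakage_sd: float = 0.1
    sensor_noise_sd: float = 1.0


@dataclass
class SegmentationConfig:
    window: float = 2.0  # seconds
    overlap_fraction: float = 0.0
    amplitude_limit: float = 100.0  # uV, artifact rejection threshold

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.amplitude_limit <= 0:
            raise ValueError("amplitude_limit must be > 0")


@dataclass
class FeatureConfig:
    n_csp_components: int = 4
    log_band_power: bool = True


@dataclass
class NetworkSection:
    variant: str = "compact_1d"
    conv_filters: tuple[int, int, int] = (8, 16, 16)
    fc_units: int = 32
    base_learning_rate: float = 0.001
    momentum: float = 0.9
    batch_size: int = 32
    max_epochs: int = 20
    patience: int = 5
    finetune_first_trainable: int | None = None


@dataclass
class EvaluationConfig:
    model: str = "compact_1d"  # compact_1d | transfer_table1 | svm | lda | knn | tree
    feature_set: str = "bp+csp"  # for classical models
    kind: str = "holdout"  # holdout | kfold
    test_fraction: float = 0.2
    k: int = 10
    shuffle: bool = True
    group_by_subject: bool = False
    stratify: bool = True
    positive_threshold: float = 0.5
    run_baselines: bool = True

    def __post_init__(self) -> None:
        if self.kind == "kfold" and self.k < 2:
            raise ValueError("k-fold evaluation needs k >= 2")


@dataclass
class RunConfig:
    seed: int = 0
    protocol: SessionProtocol = field(default_factory=SessionProtocol)
    sources: SourceConfig = field(default_factory=SourceConfig)
    mixing: MixingConfig = field(default_factory=MixingConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    augment: AugmentSpec = field(default_factory=AugmentSpec)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    network: NetworkSection = field(default_factory=NetworkSection)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "protocol": SessionProtocol,
    "sources": SourceConfig,
    "mixing": MixingConfig,
    "filter": FilterSpec,
    "segmentation": SegmentationConfig,
    "augment": AugmentSpec,
    "features": FeatureConfig,
    "network": NetworkSection,
    "evaluation": EvaluationConfig,
}


def config_from_dict(doc: dict) -> RunConfig:
    """Build a RunConfig from a parsed YAML document, rejecting unknown keys."""
    doc = dict(doc or {})
    kwargs = {}
    seed = doc.pop("seed", 0)
    for name, cls in _SECTIONS.items():
        section = doc.pop(name, None)
        if section is None:
            kwargs[name] = cls()
            continue
        if not isinstance(section, dict):
            raise ValueError(f"section {name!r} must be a mapping")
        allowed = set(cls.__dataclass_fields__)
        unknown = set(section) - allowed
        if unknown:
            raise ValueError(f"unknown keys in section {name!r}: {sorted(unknown)}")
        if name == "network" and "conv_filters" in section:
            section = {**section, "conv_filters": tuple(section["conv_filters"])}
        kwargs[name] = cls(**section)
    if doc:
        raise ValueError(f"unknown top-level config keys: {sorted(doc)}")
    return RunConfig(seed=int(seed), **kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return config_from_dict(doc)


def sleepy_normal_specs(cfg: RunConfig):
    """Materialize the two SourceSpecs implied by the sources section."""
    from drowseeg.synth import SLEEPY, NORMAL, SourceSpec, _COMMON_BANDS

    hi = float(np.sqrt(cfg.sources.power_ratio))
    common = dict(
        background_amplitude=cfg.sources.background_amplitude,
        background_exponent=cfg.sources.background_exponent,
        per_subject_gain_sd=cfg.sources.per_subject_gain_sd,
    )
    sleepy = SourceSpec(
        class_label=SLEEPY,
        band_amplitudes={**_COMMON_BANDS, "alpha": (hi, 10.5, 5.0), "beta": (1.0, 21.5, 17.0)},
        **common,
    )
    normal = SourceSpec(
        class_label=NORMAL,
        band_amplitudes={**_COMMON_BANDS, "alpha": (1.0, 10.5, 5.0), "beta": (hi, 21.5, 17.0)},
        **common,
    )
    return sleepy, normal
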