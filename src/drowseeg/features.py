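"""Classical EEG features: band power (BP) and common spatial patterns (CSP).

Band power integrates the Welch power spectral density over canonical
frequency bands per channel.  CSP solves the two-class generalized
eigenproblem

    C_A w = lambda (C_A + C_B) w

on trace-normalized class-average covariances; eigenvalues lie in [0, 1]
and give the fraction of (normalized) variance a filtered signal carries
under class A.  The extreme eigenvectors maximize the variance ratio
between the classes and are the standard spatial features for two-class
EEG discrimination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, signal

from drowseeg.preprocess import Epoch, EpochSet


@dataclass
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"band {self.name!r}: need 0 < low < high")


def default_bands() -> list[BandDefinition]:
    """Delta/theta/alpha/beta bands tiling the 1-30 Hz passband."""
    return [
        BandDefinition("delta", 1.0, 4.0),
        BandDefinition("theta", 4.0, 8.0),
        BandDefinition("alpha", 8.0, 13.0),
        BandDefinition("beta", 13.0, 30.0),
    ]


def welch_psd(e: Epoch, rate: float, segment_length: int | None = None):
    """Per-channel Welch PSD (Hann window, 50% overlap, density scaling).

    Returns (freqs, psd) with psd shaped (n_channels, n_freqs).  Default
    segment length is one second of samples, capped at the epoch length.
    """
    n = e.data.shape[1]
    if segment_length is None:
        segment_length = min(int(round(rate)), n)
    if segment_length > n:
        raise ValueError(f"segment_length {segment_length} exceeds epoch length {n}")
    freqs, psd = signal.welch(
        e.data, fs=rate, window="hann", nperseg=segment_length,
        noverlap=segment_length // 2, axis=1, scaling="density",
    )
    return freqs, psd


def band_power(
    e: Epoch,
    bands: list[BandDefinition] | None = None,
    rate: float = 500.0,
    log_transform: bool = False,
) -> np.ndarray:
    """Integrated PSD per channel per band, shaped (n_channels, n_bands)."""
    bands = bands or default_bands()
    nyq = rate / 2.0
    for b in bands:
        if b.high > nyq:
            raise ValueError(f"band {b.name!r} exceeds Nyquist {nyq} Hz")
    freqs, psd = welch_psd(e, rate)
    out = np.empty((e.data.shape[0], len(bands)))
    for j, b in enumerate(bands):
        mask = (freqs >= b.low) & (freqs <= b.high)
        out[:, j] = np.trapezoid(psd[:, mask], freqs[mask], axis=1)
    if log_transform:
        out = np.log(out + 1e-12)
    return out


@dataclass
class FeatureMatrix:
    """Epochs-by-features table with names and labels."""

    values: np.ndarray  # (n_epochs, n_features)
    feature_names: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length != column count")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("labels length != row count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]


@dataclass
class CSPModel:
    """Fitted CSP spatial filters.

    ``filters`` columns are ordered [top n/2 eigenvectors, bottom n/2
    eigenvectors]; ``eigenvalues`` is the full descending spectrum of the
    generalized problem (class_order[0]'s variance fractions).
    """

    filters: np.ndarray  # (n_channels, n_components)
    eigenvalues: np.ndarray  # (n_channels,), descending, in [0, 1]
    n_components: int
    class_order: tuple[str, str]

    def __post_init__(self) -> None:
        self.filters = np.asarray(self.filters, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if not np.all(np.isfinite(self.filters)):
            raise ValueError("non-finite CSP filters")


def _class_covariance(epochs: list[Epoch]) -> np.ndarray:
    """Average of trace-normalized per-epoch covariances."""
    covs = []
    for e in epochs:
        x = e.data - e.data.mean(axis=1, keepdims=True)
        c = x @ x.T / x.shape[1]
        tr = np.trace(c)
        if tr <= 0:
            continue  # flat epoch carries no spatial information
        covs.append(c / tr)
    if not covs:
        raise ValueError("no epoch with nonzero variance in one class")
    return np.mean(covs, axis=0)


def fit_csp(es: EpochSet, n_components: int = 4, regularization: float = 1e-6) -> CSPModel:
    """Fit two-class CSP filters on an epoch set.

    ``regularization`` is a ridge added to the composite covariance
    (relative to its mean eigenvalue) to keep the problem well posed.
    """
    labels = sorted(set(es.labels))
    if len(labels) != 2:
        raise ValueError(f"CSP needs exactly two classes, got {labels}")
    n_channels = es.epochs[0].data.shape[0]
    if n_components % 2 or not 2 <= n_components <= n_channels:
        raise ValueError("n_components must be even and within channel count")
    label_a, label_b = labels
    cov_a = _class_covariance([e for e in es.epochs if e.label == label_a])
    cov_b = _class_covariance([e for e in es.epochs if e.label == label_b])
    composite = cov_a + cov_b
    if regularization > 0:
        composite = composite + regularization * (np.trace(composite) / n_channels) * np.eye(n_channels)
    evals, evecs = linalg.eigh(cov_a, composite)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, 1.0)
    half = n_components // 2
    picked = np.concatenate([np.arange(half), np.arange(n_channels - half, n_channels)])
    return CSPModel(
        filters=evecs[:, picked],
        eigenvalues=evals,
        n_components=n_components,
        class_order=(label_a, label_b),
    )


def apply_csp(model: CSPModel, es: EpochSet) -> FeatureMatrix:
    """Project epochs through the CSP filters and return log-variance features.

    Per epoch the feature of component j is log(var_j / sum_k var_k), the
    classic normalized log-variance readout.
    """
    n_channels = es.epochs[0].data.shape[0] if es.epochs else model.filters.shape[0]
    if n_channels != model.filters.shape[0]:
        raise ValueError(
            f"model fitted on {model.filters.shape[0]} channels, epochs have {n_channels}"
        )
    rows = []
    for i, e in enumerate(es.epochs):
        z = model.filters.T @ (e.data - e.data.mean(axis=1, keepdims=True))
        var = z.var(axis=1)
        total = var.sum()
        if total <= 0:
            raise ValueError(f"epoch {i} is flat: CSP log-variance undefined")
        rows.append(np.log(var / total))
    names = [f"csp{j + 1}" for j in range(model.n_components)]
    return FeatureMatrix(values=np.array(rows), feature_names=names, labels=es.labels)


def band_power_features(
    es: EpochSet,
    bands: list[BandDefinition] | None = None,
    log_transform: bool = True,
) -> FeatureMatrix:
    """Band power of every epoch, flattened channel-major: (n_ch * n_bands) columns."""
    bands = bands or default_bands()
    rows = [
        band_power(e, bands, rate=es.sampling_rate, log_transform=log_transform).ravel()
        for e in es.epochs
    ]
    n_channels = es.epochs[0].data.shape[0]
    names = [f"bp_ch{c + 1}_{b.name}" for c in range(n_channels) for b in bands]
    return FeatureMatrix(values=np.array(rows), feature_names=names, labels=es.labels)


def concat_features(a: FeatureMatrix, b: FeatureMatrix) -> FeatureMatrix:
    """Horizontally join two feature matrices computed on the same epochs."""
    if a.n_epochs != b.n_epochs:
        raise ValueError(f"row mismatch: {a.n_epochs} vs {b.n_epochs}")
    if a.labels != b.labels:
        raise ValueError("feature matrices disagree on epoch labels")
    return FeatureMatrix(
        values=np.hstack([a.values, b.values]),
        feature_names=list(a.feature_names) + list(b.feature_names),
        labels=list(a.labels),
    )
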