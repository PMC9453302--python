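"""Training-set enlargement by multiplicative Gaussian noise.

New epochs are obtained by elementwise multiplying a signal with Gaussian
noise centered at 1 (mean mu = 1, sd sigma).  Unlike geometric transforms
(flips, rotations, crops) or additive salt/pepper-style noise, a
multiplicative perturbation preserves the temporal and spectral structure
of the EEG in expectation: E[x * n] = mu * x, and in per-channel mode the
normalized power spectrum is exactly preserved.

Augmentation belongs strictly to the training side of a split; the
evaluation harness enforces that no augmented copy shares a source epoch
with any test epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from drowseeg.preprocess import Epoch, EpochSet

PER_SAMPLE = "per_sample"
PER_CHANNEL = "per_channel"


@dataclass
class AugmentSpec:
    """Multiplicative-noise parameters.

    mode ``per_sample`` draws one noise value per sample (a full "noise
    array"); ``per_channel`` draws a single value per channel, which scales
    each channel uniformly.
    """

    mu: float = 1.0
    sigma: float = 0.1
    copies_per_epoch: int = 2
    seed: int = 0
    mode: str = PER_SAMPLE

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.copies_per_epoch < 0:
            raise ValueError("copies_per_epoch must be >= 0")
        if self.mode not in (PER_SAMPLE, PER_CHANNEL):
            raise ValueError(f"mode must be {PER_SAMPLE} or {PER_CHANNEL}")


def gaussian_pdf(z, mu: float = 1.0, sigma: float = 0.1):
    """Density of Normal(mu, sigma) at z: (1/(sigma sqrt(2 pi))) exp(-(z-mu)^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    z = np.asarray(z, dtype=float)
    out = np.exp(-((z - mu) ** 2) / (2.0 * sigma**2)) / (sigma * np.sqrt(2.0 * np.pi))
    return out if out.ndim else float(out)


def multiplicative_noise_epoch(e: Epoch, spec: AugmentSpec, draw_seed: int) -> Epoch:
    """One augmented copy: x' = x * n with n ~ Normal(mu, sigma).

    With sigma = 0 and mu = 1 the samples are bit-identical to the input;
    only the ``augmented`` flag changes.  Label and provenance are kept so
    subject-aware splitting remains possible downstream.
    """
    if spec.sigma == 0.0 and spec.mu == 1.0:
        return replace(e, data=e.data.copy(), augmented=True)
    rng = np.random.default_rng(draw_seed)
    if spec.mode == PER_SAMPLE:
        noise = rng.normal(spec.mu, spec.sigma, size=e.data.shape)
    else:
        noise = rng.normal(spec.mu, spec.sigma, size=(e.data.shape[0], 1))
    return replace(e, data=e.data * noise, augmented=True)


def augment_epochset(es: EpochSet, spec: AugmentSpec) -> EpochSet:
    """Return the originals plus ``copies_per_epoch`` augmented variants each.

    Output size is n * (1 + copies_per_epoch); because every epoch gets the
    same number of copies, class proportions are unchanged.  Copy draws are
    derived deterministically from ``spec.seed``.
    """
    if spec.copies_per_epoch == 0:
        return es
    root = np.random.SeedSequence(spec.seed)
    seeds = root.generate_state(len(es.epochs) * spec.copies_per_epoch) % (2**31)
    out = list(es.epochs)
    k = 0
    for e in es.epochs:
        for _ in range(spec.copies_per_epoch):
            out.append(multiplicative_noise_epoch(e, spec, int(seeds[k])))
            k += 1
    return replace(es, epochs=out)
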