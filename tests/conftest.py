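import numpy as np
import pytest

from drowseeg.preprocess import Epoch, EpochSet
from drowseeg.synth import (
    SessionProtocol,
    default_mixing_model,
    generate_dataset,
)


def make_epochset(
    n_epochs: int = 20,
    n_channels: int = 4,
    n_samples: int = 100,
    rate: float = 100.0,
    seed: int = 0,
    labels=None,
) -> EpochSet:
    """Random balanced epoch set for plumbing tests."""
    rng = np.random.default_rng(seed)
    epochs = []
    for i in range(n_epochs):
        label = labels[i] if labels else ("sleepy" if i % 2 else "normal")
        epochs.append(
            Epoch(
                data=rng.standard_normal((n_channels, n_samples)),
                label=label,
                subject_id=f"s{i % 5:02d}",
                session_id="sess1",
            )
        )
    return EpochSet(epochs=epochs, sampling_rate=rate, window=n_samples / rate)


@pytest.fixture
def toy_epochs() -> EpochSet:
    return make_epochset()


@pytest.fixture(scope="session")
def small_dataset():
    """A small but spectrally realistic two-group dataset (8 ch, 125 Hz)."""
    groups = {f"s{i:02d}": ("normal" if i <= 3 else "deprived") for i in range(1, 7)}
    protocol = SessionProtocol(
        n_subjects=6,
        n_sessions_per_subject=1,
        session_duration=40.0,
        sampling_rate=125.0,
        n_channels=8,
        group_assignment=groups,
    )
    model = default_mixing_model(n_channels=8, seed=11)
    return generate_dataset(protocol, model=model, seed=11)
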