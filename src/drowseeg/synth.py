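"""Synthetic EEG generation under a linear instantaneous mixing model.

The acquisition model is ``X = A S + N``: latent band-limited cortical
sources ``S`` are projected to the electrode array through a mixing matrix
``A`` and corrupted by i.i.d. Gaussian sensor noise ``N``.  Two source
physiologies are provided: an alpha-dominant (8-13 Hz) "sleepy/calm" class
and a beta-dominant (13-30 Hz) "normal/alert" class, matching the classic
drowsiness phenomenology of scalp EEG.

The default acquisition protocol emulates a two-group driver-fatigue study:
20 subjects (half sleep-deprived), 3 sessions per subject, 7 minutes per
session at 500 Hz from an 8-electrode headset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

SLEEPY = "sleepy"
NORMAL = "normal"

#: group names in the acquisition protocol; the deprived group produces
#: sleepy-labeled recordings, the normal group alert ones.
GROUP_TO_LABEL = {"deprived": SLEEPY, "normal": NORMAL}


def _default_group_assignment(n_subjects: int) -> dict[str, str]:
    # first half normal sleep, second half sleep-deprived
    half = n_subjects // 2
    out = {}
    for i in range(n_subjects):
        sid = f"s{i + 1:02d}"
        out[sid] = "normal" if i < half else "deprived"
    return out


@dataclass
class SessionProtocol:
    """Acquisition protocol: who was recorded, for how long, and how.

    Defaults describe 20 subjects x 3 sessions x 7 min (21 min per
    volunteer, 40 trials per session) at 500 Hz on 8 channels.
    """

    n_subjects: int = 20
    n_sessions_per_subject: int = 3
    session_duration: float = 420.0  # seconds
    n_trials_per_session: int = 40
    sampling_rate: float = 500.0  # Hz
    n_channels: int = 8
    group_assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_sessions_per_subject,
               self.n_trials_per_session, self.n_channels) < 1:
            raise ValueError("all protocol counts must be >= 1")
        if self.session_duration <= 0:
            raise ValueError("session_duration must be > 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not self.group_assignment:
            self.group_assignment = _default_group_assignment(self.n_subjects)
        if len(self.group_assignment) != self.n_subjects:
            raise ValueError(
                f"group_assignment has {len(self.group_assignment)} subjects, "
                f"protocol declares {self.n_subjects}"
            )
        bad = set(self.group_assignment.values()) - set(GROUP_TO_LABEL)
        if bad:
            raise ValueError(f"unknown group names: {sorted(bad)}")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.group_assignment)

    @property
    def n_samples_per_session(self) -> int:
        return int(round(self.session_duration * self.sampling_rate))

    @property
    def minutes_per_subject(self) -> float:
        return self.n_sessions_per_subject * self.session_duration / 60.0


def make_default_protocol() -> SessionProtocol:
    """The study's default protocol: 20 subjects, 3 x 7 min sessions,
    40 trials per session, 500 Hz, 8 channels."""
    return SessionProtocol()


@dataclass
class SourceSpec:
    """Spectral recipe for one class of latent sources.

    ``band_amplitudes`` maps band name -> (RMS amplitude in uV, center Hz,
    bandwidth Hz).  Each source is the sum of narrow-band filtered white
    noise per band plus a 1/f^exponent background.  Amplitudes are RMS, so
    band power scales as amplitude squared.
    """

    class_label: str
    band_amplitudes: dict[str, tuple[float, float, float]]
    background_exponent: float = 1.0
    background_amplitude: float = 1.0  # uV RMS
    per_subject_gain_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.class_label not in (SLEEPY, NORMAL):
            raise ValueError(f"class_label must be sleepy or normal, got {self.class_label!r}")
        for name, (amp, center, bw) in self.band_amplitudes.items():
            if amp < 0:
                raise ValueError(f"band {name!r} amplitude must be >= 0")
            if center <= 0 or bw <= 0:
                raise ValueError(f"band {name!r} needs positive center and bandwidth")
        a, b = self._alpha_beta_amp()
        if a > 0 or b > 0:  # the all-zero recipe is a valid degenerate case
            if self.class_label == SLEEPY and not a > b:
                raise ValueError("sleepy spec requires alpha amplitude > beta amplitude")
            if self.class_label == NORMAL and not b > a:
                raise ValueError("normal spec requires beta amplitude > alpha amplitude")

    def _alpha_beta_amp(self) -> tuple[float, float]:
        a = self.band_amplitudes.get("alpha", (0.0, 10.5, 5.0))[0]
        b = self.band_amplitudes.get("beta", (0.0, 21.5, 17.0))[0]
        return a, b


# Default class physiology: a 3:1 alpha/beta band-power ratio for the sleepy
# class and its mirror image for the alert class (amplitude ratio sqrt(3)),
# on top of weak delta/theta activity and a 1/f background.
_SQRT3 = float(np.sqrt(3.0))

_COMMON_BANDS = {
    "delta": (0.5, 2.5, 3.0),
    "theta": (0.5, 6.0, 4.0),
}


def default_sleepy_spec() -> SourceSpec:
    """Alpha-dominant source recipe (calm / drowsy physiology)."""
    return SourceSpec(
        class_label=SLEEPY,
        band_amplitudes={
            **_COMMON_BANDS,
            "alpha": (_SQRT3, 10.5, 5.0),
            "beta": (1.0, 21.5, 17.0),
        },
    )


def default_normal_spec() -> SourceSpec:
    """Beta-dominant source recipe (alert physiology)."""
    return SourceSpec(
        class_label=NORMAL,
        band_amplitudes={
            **_COMMON_BANDS,
            "alpha": (1.0, 10.5, 5.0),
            "beta": (_SQRT3, 21.5, 17.0),
        },
    )


@dataclass
class MixingModel:
    """Instantaneous forward model: electrode signals = A @ sources + noise."""

    A: np.ndarray  # (n_channels, n_sources)
    sensor_noise_sd: float = 1.0  # uV

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2:
            raise ValueError("mixing matrix must be 2-D")
        if not np.all(np.isfinite(self.A)):
            raise ValueError("mixing matrix must be finite")
        if np.any(np.all(self.A == 0.0, axis=1)):
            raise ValueError("mixing matrix has an all-zero row: a channel sees no source")
        if self.sensor_noise_sd < 0:
            raise ValueError("sensor_noise_sd must be >= 0")


def default_mixing_model(
    n_channels: int = 8,
    n_sources: int = 8,
    leakage_sd: float = 0.1,
    sensor_noise_sd: float = 1.0,
    seed: int = 0,
) -> MixingModel:
    """Identity mixing plus small random off-diagonal leakage (sd 0.1)."""
    rng = np.random.default_rng(seed)
    A = np.eye(n_channels, n_sources)
    leak = rng.normal(0.0, leakage_sd, size=(n_channels, n_sources))
    np.fill_diagonal(leak, 0.0)
    return MixingModel(A=A + leak, sensor_noise_sd=sensor_noise_sd)


@dataclass
class Recording:
    """One continuous multichannel EEG signal with provenance metadata."""

    data: np.ndarray  # (n_channels, n_samples), uV
    sampling_rate: float
    subject_id: str
    session_id: str
    label: str
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be (n_channels, n_samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.label not in (SLEEPY, NORMAL):
            raise ValueError(f"label must be sleepy or normal, got {self.label!r}")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class LabeledDataset:
    """All recordings produced by one simulated acquisition run."""

    recordings: list[Recording]
    protocol: SessionProtocol
    seed: int


def _onef_background(n_samples: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with power spectrum proportional to 1/f^exponent."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * scale, n=n_samples)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def _narrowband(n_samples: int, low: float, high: float, rate: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS narrow-band noise: white noise band-pass filtered, so the
    oscillation has random phase by construction."""
    white = rng.standard_normal(n_samples)
    nyq = rate / 2.0
    low = max(low, 1e-3)
    high = min(high, nyq * 0.99)
    sos = signal.butter(4, [low / nyq, high / nyq], btype="bandpass", output="sos")
    band = signal.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(band**2))
    return band / rms if rms > 0 else band


def generate_sources(
    spec: SourceSpec,
    duration: float,
    rate: float,
    seed: int,
    n_sources: int = 8,
) -> np.ndarray:
    """Realize latent sources S: per source, band-limited oscillations
    (one narrow-band component per entry of ``band_amplitudes``) plus a
    1/f^exponent background.  Deterministic given ``seed``.

    Returns an (n_sources, n_samples) array in uV.
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be > 0")
    n_samples = int(round(duration * rate))
    rng = np.random.default_rng(seed)
    S = np.zeros((n_sources, n_samples))
    for i in range(n_sources):
        src = np.zeros(n_samples)
        for amp, center, bw in spec.band_amplitudes.values():
            if amp == 0:
                continue
            src += amp * _narrowband(n_samples, center - bw / 2, center + bw / 2, rate, rng)
        if spec.background_amplitude > 0:
            src += spec.background_amplitude * _onef_background(
                n_samples, spec.background_exponent, rng
            )
        S[i] = src
    return S


def mix_sources(S: np.ndarray, model: MixingModel, seed: int) -> np.ndarray:
    """Project sources to the electrodes: X = A S + N with N ~ Normal(0, sd)."""
    S = np.asarray(S, dtype=float)
    if model.A.shape[1] != S.shape[0]:
        raise ValueError(
            f"mixing matrix expects {model.A.shape[1]} sources, got {S.shape[0]}"
        )
    X = model.A @ S
    if model.sensor_noise_sd > 0:
        rng = np.random.default_rng(seed)
        X = X + rng.normal(0.0, model.sensor_noise_sd, size=X.shape)
    return X


def generate_dataset(
    protocol: SessionProtocol,
    sleepy_spec: SourceSpec | None = None,
    normal_spec: SourceSpec | None = None,
    model: MixingModel | None = None,
    seed: int = 0,
) -> LabeledDataset:
    """Simulate the full acquisition run: one Recording per subject-session.

    A multiplicative per-subject gain (1 + Normal(0, per_subject_gain_sd),
    drawn once per subject) emulates inter-individual amplitude variation.
    Reproducible given ``seed``.
    """
    sleepy_spec = sleepy_spec or default_sleepy_spec()
    normal_spec = normal_spec or default_normal_spec()
    model = model or default_mixing_model(n_channels=protocol.n_channels, seed=seed)

    root = np.random.SeedSequence(seed)
    gain_rng = np.random.default_rng(root.spawn(1)[0])
    recordings: list[Recording] = []
    for subject in protocol.subject_ids:
        group = protocol.group_assignment[subject]
        label = GROUP_TO_LABEL[group]
        spec = sleepy_spec if label == SLEEPY else normal_spec
        gain = 1.0 + gain_rng.normal(0.0, spec.per_subject_gain_sd)
        gain = max(gain, 0.1)  # keep signals from vanishing/flipping
        for sess in range(protocol.n_sessions_per_subject):
            child = root.spawn(1)[0]
            src_seed, mix_seed = child.generate_state(2) % (2**31)
            S = generate_sources(
                spec,
                protocol.session_duration,
                protocol.sampling_rate,
                seed=int(src_seed),
                n_sources=model.A.shape[1],
            )
            X = mix_sources(gain * S, model, seed=int(mix_seed))
            recordings.append(
                Recording(
                    data=X,
                    sampling_rate=protocol.sampling_rate,
                    subject_id=subject,
                    session_id=f"sess{sess + 1}",
                    label=label,
                )
            )
    return LabeledDataset(recordings=recordings, protocol=protocol, seed=seed)
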