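"""Compact 1-D convolutional classifier for EEG epochs.

The primary model is a small network of three 1-D convolution layers
(kernel extents 5, 3, 3 along time, full channel depth), each followed by
ReLU, with max-pooling after the first two convolutions and two
fully-connected layers feeding a softmax over the two classes.  A larger
"transfer" variant transcribes an AlexNet-style layer list (96@11 stride 4,
256@5, 3x conv@3, two 4096-unit hidden FC layers) adapted to the 1-D input
convention, and a fine-tuning plan can freeze any prefix of layers so that
only the classifier head is updated.

Training is mini-batch stochastic gradient descent with momentum on the
cross-entropy loss, with early stopping on validation loss and a training
log row (epoch, iteration, elapsed time, validation accuracy %, validation
loss, base learning rate) per validation pass.  The forward/backward engine
is implemented directly on numpy arrays; all randomness (initialization,
batch shuffling, dropout) derives from the config seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from drowseeg.preprocess import EpochSet

CONV = "convolution"
RELU = "relu"
NORM = "cross_channel_norm"
POOL = "max_pool"
FC = "fully_connected"
SOFTMAX = "softmax"
DROPOUT = "dropout"


@dataclass
class LayerSpec:
    """Declarative description of one layer.

    ``units`` is the output-channel count for convolutions and the neuron
    count for fully-connected layers; ``kernel`` is the time extent of a
    convolution or pooling window.
    """

    kind: str
    kernel: int = 0
    stride: int = 1
    padding: int = 0
    units: int = 0
    rate: float = 0.0  # dropout probability
    frozen: bool = False

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.kind in (CONV, POOL) and self.kernel < 1:
            raise ValueError(f"{self.kind} layer needs a kernel extent")
        if self.kind in (CONV, FC) and self.units < 1:
            raise ValueError(f"{self.kind} layer needs a units count")


@dataclass
class NetworkConfig:
    variant: str  # {compact_1d, transfer_table1}
    layers: list[LayerSpec]
    input_shape: tuple[int, int]  # (channels, window_samples)
    n_classes: int = 2
    base_learning_rate: float = 0.001
    momentum: float = 0.9
    batch_size: int = 32
    max_epochs: int = 20
    patience: int = 5  # early stopping on validation loss
    loss: str = "cross_entropy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layers and self.layers[-1].kind != SOFTMAX:
            raise ValueError("last layer must be softmax")
        if self.loss != "cross_entropy":
            raise ValueError("only cross_entropy loss is supported")


@dataclass
class TrainingLogRow:
    epoch: int
    iteration: int
    elapsed: str  # HH:MM:SS
    val_accuracy_pct: float
    val_loss: float
    base_lr: float


@dataclass
class TrainingLog:
    rows: list[TrainingLogRow] = field(default_factory=list)

    def validate(self) -> None:
        iters = [r.iteration for r in self.rows]
        if any(b <= a for a, b in zip(iters, iters[1:])):
            raise ValueError("iteration must be strictly increasing")
        for r in self.rows:
            if not 0.0 <= r.val_accuracy_pct <= 100.0:
                raise ValueError("accuracy out of [0, 100]")
            if r.val_loss < 0:
                raise ValueError("loss must be >= 0")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "Epoch": r.epoch,
                    "Iteration": r.iteration,
                    "Time elapsed HH:MM:SS": r.elapsed,
                    "Validation accuracy (%)": r.val_accuracy_pct,
                    "Validation loss": r.val_loss,
                    "Base learning rate": r.base_lr,
                }
                for r in self.rows
            ]
        )


# ---------------------------------------------------------------------------
# Builders


def build_compact_net(
    input_shape: tuple[int, int] = (8, 1000),
    n_classes: int = 2,
    conv_filters: tuple[int, int, int] = (8, 16, 16),
    fc_units: int = 32,
    seed: int = 0,
) -> NetworkConfig:
    """The compact 1-D network: three convolutions with kernel extents
    5, 3, 3, ReLU after each, max-pooling after the first two, then two
    fully-connected layers and a softmax over ``n_classes``."""
    layers = [
        LayerSpec(CONV, kernel=5, stride=1, units=conv_filters[0]),
        LayerSpec(RELU),
        LayerSpec(POOL, kernel=2, stride=2),
        LayerSpec(CONV, kernel=3, stride=1, units=conv_filters[1]),
        LayerSpec(RELU),
        LayerSpec(POOL, kernel=2, stride=2),
        LayerSpec(CONV, kernel=3, stride=1, units=conv_filters[2]),
        LayerSpec(RELU),
        LayerSpec(FC, units=fc_units),
        LayerSpec(RELU),
        LayerSpec(FC, units=n_classes),
        LayerSpec(SOFTMAX),
    ]
    config = NetworkConfig(
        variant="compact_1d", layers=layers, input_shape=tuple(input_shape),
        n_classes=n_classes, seed=seed,
    )
    _compile(config)  # raises if the window is too short for the receptive field
    return config


def build_transfer_variant(
    input_shape: tuple[int, int] = (8, 1000), n_classes: int = 2, seed: int = 0
) -> NetworkConfig:
    """AlexNet-style layer list adapted to 1-D: conv 96@11 stride 4, local
    cross-channel normalization, pool 3 stride 2, conv 256@5 pad 2, norm,
    pool, conv 384@3 / 384@3 / 256@3, pool, two hidden FC layers of 4,096
    units, then a softmax head over ``n_classes``."""
    layers = [
        LayerSpec(CONV, kernel=11, stride=4, units=96),
        LayerSpec(RELU),
        LayerSpec(NORM, kernel=5),
        LayerSpec(POOL, kernel=3, stride=2),
        LayerSpec(CONV, kernel=5, stride=1, padding=2, units=256),
        LayerSpec(RELU),
        LayerSpec(NORM, kernel=5),
        LayerSpec(POOL, kernel=3, stride=2),
        LayerSpec(CONV, kernel=3, stride=1, padding=1, units=384),
        LayerSpec(RELU),
        LayerSpec(CONV, kernel=3, stride=1, padding=1, units=384),
        LayerSpec(RELU),
        LayerSpec(CONV, kernel=3, stride=1, padding=1, units=256),
        LayerSpec(RELU),
        LayerSpec(POOL, kernel=3, stride=2),
        LayerSpec(FC, units=4096),
        LayerSpec(RELU),
        LayerSpec(DROPOUT, rate=0.5),
        LayerSpec(FC, units=4096),
        LayerSpec(RELU),
        LayerSpec(DROPOUT, rate=0.5),
        LayerSpec(FC, units=n_classes),
        LayerSpec(SOFTMAX),
    ]
    return NetworkConfig(
        variant="transfer_table1", layers=layers, input_shape=tuple(input_shape),
        n_classes=n_classes, seed=seed,
    )


def first_fully_connected_index(config: NetworkConfig) -> int:
    for i, layer in enumerate(config.layers):
        if layer.kind == FC:
            return i
    raise ValueError("network has no fully-connected layer")


def make_finetune_plan(config: NetworkConfig, first_trainable_layer: int | None = None) -> NetworkConfig:
    """Freeze every layer before ``first_trainable_layer``.

    The default freezes everything before the first fully-connected block,
    so only the classifier head is fine-tuned.  Frozen layers receive no
    parameter updates during training.
    """
    if first_trainable_layer is None:
        first_trainable_layer = first_fully_connected_index(config)
    if not 0 <= first_trainable_layer <= len(config.layers):
        raise ValueError(f"layer index {first_trainable_layer} out of range")
    layers = [
        replace(layer, frozen=(i < first_trainable_layer))
        for i, layer in enumerate(config.layers)
    ]
    return replace(config, layers=layers)


# ---------------------------------------------------------------------------
# numpy forward/backward engine


class _Conv1d:
    def __init__(self, spec: LayerSpec, in_ch: int, rng: np.random.Generator):
        k, f = spec.kernel, spec.units
        scale = np.sqrt(2.0 / (in_ch * k))  # He initialization
        self.W = rng.normal(0.0, scale, size=(f, in_ch, k))
        self.b = np.zeros(f)
        self.stride, self.pad, self.frozen = spec.stride, spec.padding, spec.frozen
        self.params = True

    def out_len(self, t: int) -> int:
        return (t + 2 * self.pad - self.W.shape[2]) // self.stride + 1

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        k = self.W.shape[2]
        cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)[:, :, :: self.stride, :]
        self._cols, self._in_padded_len = cols, x.shape[2]
        return np.einsum("bctk,fck->bft", cols, self.W, optimize=True) + self.b[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = np.einsum("bft,bctk->fck", dy, self._cols, optimize=True)
        self.db = dy.sum(axis=(0, 2))
        B = dy.shape[0]
        k = self.W.shape[2]
        t_out = dy.shape[2]
        dx = np.zeros((B, self.W.shape[1], self._in_padded_len))
        for j in range(k):
            contrib = np.einsum("bft,fc->bct", dy, self.W[:, :, j], optimize=True)
            dx[:, :, j : j + self.stride * t_out : self.stride] += contrib
        if self.pad:
            dx = dx[:, :, self.pad : dx.shape[2] - self.pad]
        return dx


class _ReLULayer:
    params = False

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _MaxPool1d:
    params = False

    def __init__(self, spec: LayerSpec):
        self.k, self.stride = spec.kernel, spec.stride

    def out_len(self, t: int) -> int:
        return (t - self.k) // self.stride + 1

    def forward(self, x, train):
        win = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=2)[:, :, :: self.stride, :]
        self._arg = win.argmax(axis=3)
        self._in_len = x.shape[2]
        return win.max(axis=3)

    def backward(self, dy):
        B, C, T_out = dy.shape
        dx = np.zeros((B, C, self._in_len))
        pos = self._arg + np.arange(T_out)[None, None, :] * self.stride
        bb, cc = np.meshgrid(np.arange(B), np.arange(C), indexing="ij")
        np.add.at(dx, (bb[:, :, None], cc[:, :, None], pos), dy)
        return dx


class _CrossChannelNorm:
    """AlexNet-style local response normalization across filter channels."""

    params = False
    k0, alpha, beta = 2.0, 1e-4, 0.75

    def __init__(self, spec: LayerSpec):
        self.n = spec.kernel

    def _denom(self, x):
        sq = x**2
        C = x.shape[1]
        half = self.n // 2
        acc = np.zeros_like(x)
        for c in range(C):
            lo, hi = max(0, c - half), min(C, c + half + 1)
            acc[:, c] = sq[:, lo:hi].sum(axis=1)
        return self.k0 + (self.alpha / self.n) * acc

    def forward(self, x, train):
        self._x = x
        self._den = self._denom(x)
        return x * self._den**-self.beta

    def backward(self, dy):
        x, den = self._x, self._den
        C = x.shape[1]
        half = self.n // 2
        core = dy * x * den ** -(self.beta + 1)
        acc = np.zeros_like(x)
        for c in range(C):
            lo, hi = max(0, c - half), min(C, c + half + 1)
            acc[:, c] = core[:, lo:hi].sum(axis=1)
        return dy * den**-self.beta - (2.0 * self.alpha * self.beta / self.n) * x * acc


class _Flatten:
    params = False

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class _Dense:
    def __init__(self, spec: LayerSpec, in_dim: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_dim)
        self.W = rng.normal(0.0, scale, size=(spec.units, in_dim))
        self.b = np.zeros(spec.units)
        self.frozen = spec.frozen
        self.params = True

    def forward(self, x, train):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.dW = dy.T @ self._x
        self.db = dy.sum(axis=0)
        return dy @ self.W


class _DropoutLayer:
    params = False

    def __init__(self, spec: LayerSpec, rng: np.random.Generator):
        self.rate, self.rng = spec.rate, rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class _Softmax:
    params = False

    def forward(self, x, train):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=1, keepdims=True)
        return self._p

    def backward(self, dy):
        # combined with cross-entropy upstream: dy is already (p - y)/B
        return dy


def _compile(config: NetworkConfig, rng: np.random.Generator | None = None):
    """Instantiate the layer stack and validate shapes end to end."""
    rng = rng or np.random.default_rng(config.seed)
    n_ch, t = config.input_shape
    layers: list = []
    flat_dim = None
    for i, spec in enumerate(config.layers):
        if spec.kind == CONV:
            if flat_dim is not None:
                raise ValueError("convolution after flatten is not supported")
            layer = _Conv1d(spec, n_ch, rng)
            t2 = layer.out_len(t)
            if t2 < 1:
                raise ValueError(
                    f"layer {i}: window too short for the receptive field "
                    f"(length {t} before kernel {spec.kernel})"
                )
            n_ch, t = spec.units, t2
            layers.append(layer)
        elif spec.kind == POOL:
            layer = _MaxPool1d(spec)
            t2 = layer.out_len(t)
            if t2 < 1:
                raise ValueError(f"layer {i}: window too short for pooling")
            t = t2
            layers.append(layer)
        elif spec.kind == RELU:
            layers.append(_ReLULayer())
        elif spec.kind == NORM:
            layers.append(_CrossChannelNorm(spec))
        elif spec.kind == FC:
            if flat_dim is None:
                layers.append(_Flatten())
                flat_dim = n_ch * t
            layers.append(_Dense(spec, flat_dim, rng))
            flat_dim = spec.units
        elif spec.kind == DROPOUT:
            layers.append(_DropoutLayer(spec, rng))
        elif spec.kind == SOFTMAX:
            layers.append(_Softmax())
        else:
            raise ValueError(f"unknown layer kind {spec.kind!r}")
    return layers


@dataclass
class TrainedNetwork:
    """A fitted network: config, weights, normalization stats, and log."""

    config: NetworkConfig
    layers: list  # engine layers holding the fitted weights
    log: TrainingLog
    classes: list[str]
    input_mean: np.ndarray  # (n_channels, 1)
    input_sd: np.ndarray  # (n_channels, 1)

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        return (X - self.input_mean[None]) / self.input_sd[None]

    def predict_proba(self, es: EpochSet | np.ndarray) -> np.ndarray:
        X = es.data_array() if isinstance(es, EpochSet) else np.asarray(es)
        if X.shape[1:] != tuple(self.config.input_shape):
            raise ValueError(
                f"input shape {X.shape[1:]} does not match configured "
                f"{tuple(self.config.input_shape)}"
            )
        return _forward(self.layers, self._prepare(X), train=False)

    def predict_scores(self, es: EpochSet | np.ndarray) -> np.ndarray:
        """Probability of the positive (last in ``classes``) class."""
        return self.predict_proba(es)[:, -1]

    def predict_labels(self, es: EpochSet | np.ndarray) -> list[str]:
        idx = self.predict_proba(es).argmax(axis=1)
        return [self.classes[i] for i in idx]


def _forward(layers, X, train):
    out = X
    for layer in layers:
        out = layer.forward(out, train)
    return out


def _snapshot(layers):
    return [(l.W.copy(), l.b.copy()) if getattr(l, "params", False) else None for l in layers]


def _restore(layers, snap):
    for layer, s in zip(layers, snap):
        if s is not None:
            layer.W, layer.b = s[0].copy(), s[1].copy()


def _evaluate(layers, X, y_idx, batch: int = 256):
    losses, correct = [], 0
    for i in range(0, len(X), batch):
        p = _forward(layers, X[i : i + batch], train=False)
        yb = y_idx[i : i + batch]
        losses.append(-np.log(np.clip(p[np.arange(len(yb)), yb], 1e-12, None)))
        correct += int((p.argmax(axis=1) == yb).sum())
    loss = float(np.concatenate(losses).mean())
    acc = correct / len(X)
    return loss, acc


def train_network(config: NetworkConfig, train: EpochSet, val: EpochSet) -> TrainedNetwork:
    """Fit the network by mini-batch SGD with momentum on cross-entropy.

    Inputs are standardized per channel using training-set statistics.  One
    training-log row is written per validation pass (end of each epoch);
    training stops early when validation loss has not improved for
    ``config.patience`` epochs, and the best-validation-loss weights are
    returned.  Frozen layers receive no updates.
    """
    if not len(train) or not len(val):
        raise ValueError("train and validation sets must be nonempty")
    classes = sorted(set(train.labels))
    if len(classes) != config.n_classes:
        raise ValueError(
            f"training labels {classes} do not cover {config.n_classes} classes"
        )
    Xtr = train.data_array()
    Xva = val.data_array()
    if Xtr.shape[1:] != tuple(config.input_shape):
        raise ValueError(
            f"epochs have shape {Xtr.shape[1:]}, config expects {tuple(config.input_shape)}"
        )
    mean = Xtr.mean(axis=(0, 2))[:, None]
    sd = Xtr.std(axis=(0, 2))[:, None]
    sd[sd == 0] = 1.0
    Xtr = (Xtr - mean[None]) / sd[None]
    Xva = (Xva - mean[None]) / sd[None]
    label_to_idx = {c: i for i, c in enumerate(classes)}
    ytr = np.array([label_to_idx[l] for l in train.labels])
    yva = np.array([label_to_idx[l] for l in val.labels])

    rng = np.random.default_rng(config.seed)
    layers = _compile(config, rng)
    velocity = [
        (np.zeros_like(l.W), np.zeros_like(l.b)) if getattr(l, "params", False) else None
        for l in layers
    ]

    log = TrainingLog()
    best_loss, best_snap, since_best = np.inf, _snapshot(layers), 0
    iteration = 0
    t0 = time.monotonic()
    lr, mom = config.base_learning_rate, config.momentum

    any_trainable = any(
        getattr(l, "params", False) and not l.frozen for l in layers
    )
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(Xtr))
        for i in range(0, len(Xtr), config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            p = _forward(layers, xb, train=True)
            grad = p.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            grad /= len(yb)
            if any_trainable:
                for layer in reversed(layers):
                    grad = layer.backward(grad)
                for layer, vel in zip(layers, velocity):
                    if vel is None or layer.frozen:
                        continue
                    vW, vb = vel
                    vW *= mom
                    vW -= lr * layer.dW
                    vb *= mom
                    vb -= lr * layer.db
                    layer.W += vW
                    layer.b += vb
            iteration += 1
        val_loss, val_acc = _evaluate(layers, Xva, yva)
        elapsed = time.strftime("%H:%M:%S", time.gmtime(time.monotonic() - t0))
        log.rows.append(
            TrainingLogRow(
                epoch=epoch, iteration=iteration, elapsed=elapsed,
                val_accuracy_pct=100.0 * val_acc, val_loss=val_loss, base_lr=lr,
            )
        )
        if val_loss < best_loss - 1e-12:
            best_loss, best_snap, since_best = val_loss, _snapshot(layers), 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    _restore(layers, best_snap)
    log.validate()
    return TrainedNetwork(
        config=config, layers=layers, log=log, classes=classes,
        input_mean=mean, input_sd=sd,
    )
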