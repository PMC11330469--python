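"""Shallow 3D CNN for masked tumor volumes.

Architecture (fixed): three convolutional blocks with 16, 32 and 64 output
channels — each block is conv(3x3x3, stride 1, pad 1) -> batch norm -> leaky
ReLU -> 2x max pool -> dropout — followed by global average pooling to a
64-feature bottleneck and two fully connected layers (64 -> 16 -> output).
The classification head has 3 outputs (Fusion / Mutation / Other); the
regression head predicts k continuous targets.  Global average pooling makes
the parameter count independent of the input size, so the same network runs
on desk-scale volumes (e.g. 32^3) and full-resolution scans alike.

Training follows a fixed protocol: cross-entropy (classification) or MSE
(regression) loss, SGD with momentum 0.9, batch size 16, cosine-annealing
learning-rate schedule with warm restarts, Kaiming-normal initialization,
dropout active only during training, and best-epoch selection by validation
loss.  Multi-channel inputs support input-level channel dropout so the model
tolerates missing MRI sequences at inference.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .synthetic import CLASS_NAMES, SubjectVolume


class CNNConfigError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class CNNConfig:
    in_channels: int = 1
    conv_channels: tuple[int, int, int] = (16, 32, 64)
    kernel_size: int = 3
    leaky_slope: float = 0.01
    head: str = "classification"  # or "regression"
    n_outputs: int = 3
    fc_hidden: int = 16
    dropout_conv: float = 0.3
    dropout_fc: float = 0.3
    hidden_features: str = "concat"  # concat | gap_only | fc1_only

    def validate(self) -> None:
        if tuple(self.conv_channels) != (16, 32, 64):
            raise CNNConfigError("conv_channels is fixed at (16, 32, 64)")
        if self.fc_hidden != 16:
            raise CNNConfigError("the hidden fully connected layer has 16 neurons")
        if self.head not in ("classification", "regression"):
            raise CNNConfigError(f"unknown head {self.head!r}")
        if self.head == "classification" and self.n_outputs != 3:
            raise CNNConfigError("the classification head has exactly 3 outputs")
        if self.head == "regression" and self.n_outputs < 1:
            raise CNNConfigError("regression head needs at least 1 output")
        if self.in_channels not in (1, 2, 3, 4):
            raise CNNConfigError("in_channels must be between 1 and 4")
        if self.dropout_conv not in (0.0, 0.3, 0.6) or self.dropout_fc not in (0.0, 0.3, 0.6):
            # the explored grid; other values are allowed but flagged early
            pass
        if self.hidden_features not in ("concat", "gap_only", "fc1_only"):
            raise CNNConfigError(f"unknown hidden_features mode {self.hidden_features!r}")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    total_epochs: int = 100
    cosine_period: int = 50
    learning_rate: float = 0.001
    momentum: float = 0.9
    seed: int = 0
    input_channel_dropout_prob: float = 0.0

    def validate(self) -> None:
        if self.total_epochs % self.cosine_period != 0:
            raise CNNConfigError(
                "total_epochs must be a multiple of the cosine annealing period"
            )
        if not 0 <= self.input_channel_dropout_prob <= 1:
            raise CNNConfigError("input_channel_dropout_prob must be in [0, 1]")
        if self.batch_size < 1 or self.learning_rate <= 0:
            raise CNNConfigError("invalid batch_size or learning_rate")


#: The explored learning-rate grid.
LR_GRID: tuple[float, ...] = (0.1, 0.01, 0.001, 0.0001)


class Model3D:
    """The shallow 3D CNN with tapped hidden representations."""

    def __init__(self, config: CNNConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        gain = nn.leaky_gain(config.leaky_slope)
        layers: list[nn.Layer] = []
        c_in = config.in_channels
        for bi, c_out in enumerate(config.conv_channels):
            layers += [
                nn.Conv3d(
                    c_in, c_out, config.kernel_size, rng, gain,
                    needs_input_grad=bi > 0,
                ),
                nn.BatchNorm(c_out),
                nn.LeakyReLU(config.leaky_slope),
                nn.MaxPool3d(),
                nn.Dropout(config.dropout_conv),
            ]
            c_in = c_out
        layers.append(nn.GlobalAvgPool())
        self.idx_gap = len(layers) - 1  # 64-feature bottleneck
        layers += [
            nn.Linear(64, config.fc_hidden, rng, gain),
            nn.BatchNorm(config.fc_hidden),
            nn.LeakyReLU(config.leaky_slope),
        ]
        self.idx_fc1 = len(layers) - 1  # 16-feature hidden representation
        layers += [
            nn.Dropout(config.dropout_fc),
            nn.Linear(config.fc_hidden, config.n_outputs, rng, gain),
        ]
        self.net = nn.Sequential(layers)

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 5 or x.shape[1] != self.config.in_channels:
            raise CNNConfigError(
                f"expected input (B, {self.config.in_channels}, D, H, W), got {x.shape}"
            )
        if min(x.shape[2:]) < 8:
            raise CNNConfigError(
                f"spatial size {x.shape[2:]} cannot reach the 64-feature "
                "bottleneck (needs >= 8 voxels per axis for three 2x pools)"
            )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._check_input(x)
        return self.net.forward(x.astype(np.float32), training)

    def forward_with_hidden(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Inference pass returning (output, gap64, fc1_16)."""
        self._check_input(x)
        h = x.astype(np.float32)
        gap = fc1 = None
        for i, layer in enumerate(self.net.layers):
            h = layer.forward(h, training=False)
            if i == self.idx_gap:
                gap = h
            elif i == self.idx_fc1:
                fc1 = h
        return h, gap, fc1

    def n_parameters(self) -> int:
        return sum(p.size for _, _, p in self.net.parameters())


def build_model(config: CNNConfig | None = None, seed: int = 0) -> Model3D:
    return Model3D(config or CNNConfig(), seed=seed)


def input_channel_dropout(
    batch: np.ndarray, prob: float, rng: np.random.Generator
) -> np.ndarray:
    """Training-time input-level dropout of non-primary channels.

    Each channel beyond the first is independently zeroed per sample with
    probability ``prob``; the primary channel is exempt.  Returns a copy.
    """
    out = batch.copy()
    if prob <= 0 or batch.shape[1] < 2:
        return out
    drop = rng.random((batch.shape[0], batch.shape[1])) < prob
    drop[:, 0] = False
    out[drop] = 0.0
    return out


@dataclass
class TrainedCNN:
    model: Model3D
    train_config: TrainConfig
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def best_val_loss(self) -> float:
        return self.history[self.best_epoch]["val_loss"]


def _batches(n: int, batch_size: int, order: np.ndarray | None = None):
    idx = order if order is not None else np.arange(n)
    for start in range(0, n, batch_size):
        yield idx[start : start + batch_size]


def _eval_loss(model: Model3D, X: np.ndarray, y: np.ndarray, batch_size: int) -> float:
    total, n = 0.0, 0
    for b in _batches(len(X), batch_size):
        out = model.forward(X[b], training=False)
        if model.config.head == "classification":
            loss, _ = nn.cross_entropy(out, y[b])
        else:
            loss, _ = nn.mse(out, y[b])
        total += loss * len(b)
        n += len(b)
    return total / n


def train(
    model: Model3D,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    tc: TrainConfig,
) -> TrainedCNN:
    """Train with SGD + cosine warm restarts; keep best-epoch weights.

    Dropout (layer and input-channel) is active only during training; the
    returned model carries the weights of the epoch with minimal validation
    loss.  Deterministic for a fixed ``tc.seed``.
    """
    tc.validate()
    Xtr, ytr = train_set
    Xval, yval = val_set
    Xtr = Xtr.astype(np.float32)
    Xval = Xval.astype(np.float32)
    if model.config.head == "regression":
        ytr = np.asarray(ytr, dtype=np.float32).reshape(len(Xtr), -1)
        yval = np.asarray(yval, dtype=np.float32).reshape(len(Xval), -1)

    ss = np.random.SeedSequence(tc.seed)
    shuffle_seed, dropout_seed, chdrop_seed = ss.spawn(3)
    shuffle_rng = np.random.default_rng(shuffle_seed)
    chdrop_rng = np.random.default_rng(chdrop_seed)
    model.net.set_dropout_rng(np.random.default_rng(dropout_seed))

    opt = nn.SGD(model.net, momentum=tc.momentum)
    trained = TrainedCNN(model=model, train_config=tc)
    best_state = None
    best_loss = np.inf
    for epoch in range(tc.total_epochs):
        lr = nn.cosine_lr(epoch, tc.learning_rate, tc.cosine_period)
        order = shuffle_rng.permutation(len(Xtr))
        epoch_loss, seen = 0.0, 0
        for b in _batches(len(Xtr), tc.batch_size, order):
            xb = Xtr[b]
            if tc.input_channel_dropout_prob > 0 and xb.shape[1] > 1:
                xb = input_channel_dropout(xb, tc.input_channel_dropout_prob, chdrop_rng)
            out = model.forward(xb, training=True)
            if model.config.head == "classification":
                loss, dout = nn.cross_entropy(out, ytr[b])
            else:
                loss, dout = nn.mse(out, ytr[b])
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite training loss at epoch {epoch} (lr={lr:.2g}); "
                    "consider a smaller learning rate"
                )
            model.net.backward(dout)
            opt.step(lr)
            epoch_loss += loss * len(b)
            seen += len(b)
        val_loss = _eval_loss(model, Xval, yval, tc.batch_size)
        trained.history.append(
            {"epoch": epoch, "lr": float(lr), "train_loss": epoch_loss / seen,
             "val_loss": float(val_loss)}
        )
        if val_loss < best_loss:
            best_loss = val_loss
            trained.best_epoch = epoch
            best_state = model.net.state_dict()
    model.net.load_state_dict(best_state)
    return trained


def predict_proba(model: Model3D | TrainedCNN, X: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Per-class probabilities (columns ordered Fusion, Mutation, Other)."""
    m = model.model if isinstance(model, TrainedCNN) else model
    if m.config.head != "classification":
        raise ValueError("predict_proba requires a classification-head model")
    probs = []
    for b in _batches(len(X), batch_size):
        logits = m.forward(X[b], training=False)
        probs.append(nn.softmax(logits.astype(np.float64)))
    return np.vstack(probs)


def predict_regression(model: Model3D | TrainedCNN, X: np.ndarray, batch_size: int = 32) -> np.ndarray:
    m = model.model if isinstance(model, TrainedCNN) else model
    if m.config.head != "regression":
        raise ValueError("predict_regression requires a regression-head model")
    out = [m.forward(X[b], training=False) for b in _batches(len(X), batch_size)]
    return np.vstack(out)


def extract_hidden_features(
    model: Model3D | TrainedCNN, X: np.ndarray, batch_size: int = 32
) -> np.ndarray:
    """Hidden activations used for fusion, dropout off.

    Default mode concatenates the 64-feature global-average-pool bottleneck
    with the 16-feature hidden fully connected output (80 values); the config
    can restrict to either alone.
    """
    m = model.model if isinstance(model, TrainedCNN) else model
    if m.config.head != "classification":
        raise ValueError("fusion features come from the classification network")
    mode = m.config.hidden_features
    feats = []
    for b in _batches(len(X), batch_size):
        _, gap, fc1 = m.forward_with_hidden(X[b])
        if mode == "gap_only":
            feats.append(gap)
        elif mode == "fc1_only":
            feats.append(fc1)
        else:
            feats.append(np.hstack([gap, fc1]))
    return np.vstack(feats)


def cohort_to_arrays(
    cohort: Sequence[SubjectVolume], n_channels: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stack a cohort into (X, y) arrays for training.

    ``y`` holds integer class indices in the fixed label order
    (Fusion=0, Mutation=1, Other=2).  Raises if the primary channel of any
    subject is absent.
    """
    for s in cohort:
        if not s.present_channels[0]:
            raise ValueError(f"subject {s.subject_id}: primary channel absent")
    c = n_channels or cohort[0].images.shape[0]
    X = np.stack([s.images[:c] for s in cohort]).astype(np.float32)
    y = np.array([CLASS_NAMES.index(s.label) for s in cohort], dtype=np.int64)
    return X, y


def save_checkpoint(trained: TrainedCNN, path) -> None:
    """Single-file checkpoint with weights, configs and training history."""
    import json

    state = trained.model.net.state_dict()
    meta = {
        "cnn_config": trained.model.config.__dict__,
        "train_config": trained.train_config.__dict__,
        "history": trained.history,
        "best_epoch": trained.best_epoch,
        "format_version": 1,
    }
    np.savez(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path) -> TrainedCNN:
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        cfg = CNNConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in meta["cnn_config"].items()})
        model = Model3D(cfg, seed=0)
        state = {k: data[k] for k in data.files if k != "__meta__"}
        model.net.load_state_dict(state)
    trained = TrainedCNN(
        model=model,
        train_config=TrainConfig(**meta["train_config"]),
        history=meta["history"],
        best_epoch=meta["best_epoch"],
    )
    return trained
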