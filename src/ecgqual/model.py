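"""The CNN-LSTM quality classifier: build, train, persist, apply.

Topology (convolution = feature extraction, LSTM = temporal
classification): a (38, 129) spectrogram — 38 time frames as the sequence
axis, 129 frequency bins as per-step features — passes through an input
normalization layer, a stack of [Conv1D -> max-pool -> dropout] blocks, a
time-distributed dense layer, an LSTM whose final state feeds dropout and
dense layers, and a softmax (2-unit) or sigmoid (1-unit) output head.
Training uses Adam at learning rate 1e-4 with sparse categorical
cross-entropy by default; a config switch selects the 1-unit sigmoid +
binary cross-entropy head instead.

Persistence is a single-file archive: a JSON header (version, config,
history, array manifest) followed by the raw little-endian float64 weight
blob. Saving the same model twice produces identical bytes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from .datasets import Corpus
from .errors import ConfigError, DataError, ModelStoreError
from .signal_io import ECGRecord, QualityLabel
from .spectrogram import Spectrogram, STFTParams, to_model_input

__all__ = [
    "ModelConfig",
    "QualityClassifier",
    "TrainedModel",
    "build_model",
    "train",
    "predict",
    "save_model",
    "load_model",
    "corpus_to_arrays",
]

MODEL_STORE_FORMAT = "ecgqual-model"
MODEL_STORE_VERSION = 1

LOSS_SPARSE_CCE = "sparse_categorical_cross_entropy"
LOSS_BCE = "binary_cross_entropy"


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the classifier and its training loop.

    Defaults follow the reference topology where stated (input shape,
    Adam at 1e-4, sparse categorical cross-entropy); layer widths are
    exposed so alternative figure readings can be substituted.
    """

    input_shape: tuple[int, int] = (38, 129)
    conv_blocks: tuple[tuple[int, int], ...] = ((64, 3), (128, 3))
    pool_size: int = 2
    dropout_rate: float = 0.3
    dense_units: int = 64
    lstm_units: int = 64
    head_units: int = 32
    output_units: int = 2
    learning_rate: float = 1e-4
    loss: str = LOSS_SPARSE_CCE
    epochs: int = 50
    batch_size: int = 32
    early_stopping_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "conv_blocks", tuple(tuple(b) for b in self.conv_blocks)
        )
        object.__setattr__(self, "input_shape", tuple(self.input_shape))
        if not self.learning_rate > 0:
            raise ConfigError(f"learning_rate must be > 0, got {self.learning_rate}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigError(f"dropout_rate must lie in [0, 1), got {self.dropout_rate}")
        if self.output_units not in (1, 2):
            raise ConfigError(f"output_units must be 1 or 2, got {self.output_units}")
        if self.loss not in (LOSS_SPARSE_CCE, LOSS_BCE):
            raise ConfigError(f"unknown loss: {self.loss!r}")
        if self.loss == LOSS_SPARSE_CCE and self.output_units != 2:
            raise ConfigError("sparse categorical cross-entropy needs output_units=2")
        if self.loss == LOSS_BCE and self.output_units != 1:
            raise ConfigError("binary cross-entropy needs output_units=1")
        if self.epochs < 0 or self.batch_size < 1:
            raise ConfigError("epochs must be >= 0 and batch_size >= 1")
        # the conv/pool stack must leave at least one time step for the LSTM
        t = self.input_shape[0]
        for _, kernel in self.conv_blocks:
            t = (t - kernel + 1) // self.pool_size
        if t < 1:
            raise ConfigError(
                f"conv/pool stack consumes the whole time axis ({self.input_shape[0]} frames)"
            )


class QualityClassifier:
    """The assembled network; untrained until :func:`train` is applied."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        t, f = config.input_shape
        layers: list[_nn.Layer] = [_nn.Normalization(f)]
        c_in = f
        for filters, kernel in config.conv_blocks:
            layers.append(_nn.Conv1D(c_in, filters, kernel, rng))
            layers.append(_nn.ReLU())
            layers.append(_nn.MaxPool1D(config.pool_size))
            layers.append(_nn.Dropout(config.dropout_rate))
            c_in = filters
        layers.append(_nn.Dense(c_in, config.dense_units, rng))
        layers.append(_nn.ReLU())
        layers.append(_nn.LSTM(config.dense_units, config.lstm_units, rng))
        layers.append(_nn.Dropout(config.dropout_rate))
        layers.append(_nn.Dense(config.lstm_units, config.head_units, rng))
        layers.append(_nn.ReLU())
        layers.append(_nn.Dense(config.head_units, config.output_units, rng))
        self.layers = layers

    @property
    def normalization(self) -> _nn.Normalization:
        return self.layers[0]  # type: ignore[return-value]

    @property
    def num_params(self) -> int:
        return sum(p.size for ly in self.layers for p in ly.params.values())

    def set_dropout_rng(self, rng: np.random.Generator | None) -> None:
        for ly in self.layers:
            if isinstance(ly, _nn.Dropout):
                ly.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for ly in self.layers:
            x = ly.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for ly in reversed(self.layers):
            dout = ly.backward(dout)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Probability of the acceptable class per segment."""
        logits = self.forward(x, train=False)
        if self.config.output_units == 2:
            return _nn.softmax(logits)[:, int(QualityLabel.ACCEPTABLE)]
        return _nn.sigmoid(logits[:, 0])

    def parameter_arrays(self) -> list[tuple[str, np.ndarray]]:
        """All arrays (trainable weights and normalization stats), in a
        stable order for persistence."""
        out = []
        for i, ly in enumerate(self.layers):
            for name in sorted(ly.params):
                out.append((f"layer{i:02d}.{name}", ly.params[name]))
        return out


@dataclass
class TrainedModel:
    """A classifier plus its config and per-epoch training history."""

    net: QualityClassifier
    config: ModelConfig
    history: dict[str, list[float]] = field(default_factory=dict)


def build_model(config: ModelConfig | None = None) -> QualityClassifier:
    """Assemble an untrained classifier from a validated config."""
    return QualityClassifier(config or ModelConfig())


def _as_array(payload, config: ModelConfig, index: int) -> np.ndarray:
    if isinstance(payload, Spectrogram):
        arr = payload.values
    elif isinstance(payload, ECGRecord):
        arr = to_model_input(payload, STFTParams()).values
    else:
        arr = np.asarray(payload, dtype=np.float64)
    if arr.shape != config.input_shape:
        raise DataError(
            f"record {index}: spectrogram shape {arr.shape} does not match "
            f"model input {config.input_shape}"
        )
    return arr


def corpus_to_arrays(corpus: Corpus, config: ModelConfig) -> tuple[np.ndarray, np.ndarray]:
    """Stack a corpus into (X, y) arrays, converting records to
    spectrograms on the fly; raises :class:`DataError` naming the first
    offending record."""
    if len(corpus) == 0:
        raise DataError("corpus is empty")
    xs = [_as_array(p, config, i) for i, p in enumerate(corpus.payloads())]
    y = corpus.labels()
    if not np.all((y == 0) | (y == 1)):
        raise DataError("labels must be encoded 0 (unacceptable) / 1 (acceptable)")
    return np.stack(xs), y


def _loss_fn(config: ModelConfig):
    if config.loss == LOSS_SPARSE_CCE:
        return _nn.softmax_cross_entropy
    return _nn.sigmoid_binary_cross_entropy


def _eval_loss_acc(net: QualityClassifier, x: np.ndarray, y: np.ndarray, config: ModelConfig):
    loss_fn = _loss_fn(config)
    losses = []
    correct = 0
    for lo in range(0, x.shape[0], 256):
        xb, yb = x[lo : lo + 256], y[lo : lo + 256]
        logits = net.forward(xb, train=False)
        loss, _ = loss_fn(logits, yb)
        losses.append(loss * xb.shape[0])
        if config.output_units == 2:
            pred = logits.argmax(axis=1)
        else:
            pred = (_nn.sigmoid(logits[:, 0]) > 0.5).astype(int)
        correct += int((pred == yb).sum())
    return sum(losses) / x.shape[0], correct / x.shape[0]


def train(
    model: QualityClassifier,
    train_corpus: Corpus,
    val_corpus: Corpus,
    config: ModelConfig | None = None,
) -> TrainedModel:
    """Train with Adam; early-stops on validation loss and restores the
    best weights. ``epochs=0`` returns the initialized network with an
    empty history."""
    config = config or model.config
    x_train, y_train = corpus_to_arrays(train_corpus, config)
    x_val, y_val = corpus_to_arrays(val_corpus, config)

    model.normalization.adapt(x_train)
    history: dict[str, list[float]] = {
        "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []
    }
    if config.epochs == 0:
        return TrainedModel(net=model, config=config, history=history)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7211]))
    model.set_dropout_rng(rng)
    optimizer = _nn.Adam(model.layers, lr=config.learning_rate)
    loss_fn = _loss_fn(config)

    best_val = np.inf
    best_weights: list[tuple[str, np.ndarray]] | None = None
    stale = 0
    n = x_train.shape[0]
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        correct = 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = model.forward(xb, train=True)
            loss, dlogits = loss_fn(logits, yb)
            if not np.isfinite(loss):
                raise DataError(f"training diverged: non-finite loss at epoch {_epoch}")
            model.backward(dlogits)
            optimizer.step()
            epoch_losses.append(loss * xb.shape[0])
            if config.output_units == 2:
                pred = logits.argmax(axis=1)
            else:
                pred = (_nn.sigmoid(logits[:, 0]) > 0.5).astype(int)
            correct += int((pred == yb).sum())
        val_loss, val_acc = _eval_loss_acc(model, x_val, y_val, config)
        history["loss"].append(sum(epoch_losses) / n)
        history["accuracy"].append(correct / n)
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = [(k, v.copy()) for k, v in model.parameter_arrays()]
            stale = 0
        else:
            stale += 1
            if stale >= config.early_stopping_patience:
                break

    if best_weights is not None:
        _restore_weights(model, dict(best_weights))
    model.set_dropout_rng(None)
    return TrainedModel(net=model, config=config, history=history)


def _restore_weights(net: QualityClassifier, named: dict[str, np.ndarray]) -> None:
    for key, current in net.parameter_arrays():
        if key not in named:
            raise ModelStoreError(f"missing parameter array {key!r}")
        if named[key].shape != current.shape:
            raise ModelStoreError(
                f"parameter {key!r} has shape {named[key].shape}, expected {current.shape}"
            )
        current[...] = named[key]


def predict(
    model: TrainedModel,
    inputs: list[Spectrogram] | list[np.ndarray],
    threshold: float = 0.5,
) -> list[tuple[QualityLabel, float]]:
    """Per-segment (label, probability-of-acceptable).

    A segment is labeled acceptable iff p > threshold; exact ties go to
    unacceptable — the conservative call for a screening tool.
    """
    if len(inputs) == 0:
        return []
    xs = np.stack([_as_array(p, model.config, i) for i, p in enumerate(inputs)])
    probs = model.net.predict_proba(xs)
    return [
        (QualityLabel.ACCEPTABLE if p > threshold else QualityLabel.UNACCEPTABLE, float(p))
        for p in probs
    ]


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write the single-file model archive (JSON header + weight blob)."""
    path = Path(path)
    arrays = model.net.parameter_arrays()
    header = {
        "format": MODEL_STORE_FORMAT,
        "version": MODEL_STORE_VERSION,
        "config": asdict(model.config),
        "history": model.history,
        "arrays": [
            {"name": k, "shape": list(v.shape), "dtype": "float64"} for k, v in arrays
        ],
    }
    blob = b"".join(np.ascontiguousarray(v, dtype="<f8").tobytes() for _, v in arrays)
    with open(path, "wb") as fh:
        fh.write(json.dumps(header, sort_keys=True).encode())
        fh.write(b"\n")
        fh.write(blob)


def load_model(path: str | Path) -> TrainedModel:
    """Read a model archive; rejects corrupt stores and unknown versions."""
    raw = Path(path).read_bytes()
    sep = raw.find(b"\n")
    if sep < 0:
        raise ModelStoreError(f"{path}: not a model archive (no header)")
    try:
        header = json.loads(raw[:sep])
    except json.JSONDecodeError as exc:
        raise ModelStoreError(f"{path}: corrupt header ({exc})") from exc
    if header.get("format") != MODEL_STORE_FORMAT:
        raise ModelStoreError(f"{path}: not an ecgqual model archive")
    if header.get("version") != MODEL_STORE_VERSION:
        raise ModelStoreError(
            f"{path}: unsupported model store version {header.get('version')!r} "
            f"(this build reads version {MODEL_STORE_VERSION})"
        )
    config = ModelConfig(**{
        k: tuple(v) if k == "input_shape" else v
        for k, v in header["config"].items()
    })
    net = QualityClassifier(config)
    blob = raw[sep + 1 :]
    named: dict[str, np.ndarray] = {}
    offset = 0
    for meta in header["arrays"]:
        count = int(np.prod(meta["shape"])) if meta["shape"] else 1
        nbytes = count * 8
        chunk = blob[offset : offset + nbytes]
        if len(chunk) != nbytes:
            raise ModelStoreError(f"{path}: truncated weight blob at {meta['name']!r}")
        named[meta["name"]] = np.frombuffer(chunk, dtype="<f8").reshape(meta["shape"]).copy()
        offset += nbytes
    if offset != len(blob):
        raise ModelStoreError(f"{path}: trailing bytes after weight blob")
    _restore_weights(net, named)
    return TrainedModel(net=net, config=config, history=header["history"])
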