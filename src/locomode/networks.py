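"""Declarative construction of the three classifier architectures.

All networks consume a stack of mel-spectrogram images of shape
``(n_channels, 10, 50)`` — the 6 or 12 sensor channels ride on the
convolution's channel axis so one or two IMUs are classified as a single
object.

* **CNN**: conv(64, 5x5) -> maxpool 2x2 -> conv(128, 5x5) -> maxpool 2x2 ->
  dropout 0.25 -> dense 512 -> dense 256 -> softmax.
* **CNN-GRU / CNN-LSTM**: the same convolution/pooling trunk, after which
  the surviving frame axis (50 -> 25 -> 12) becomes the recurrent time axis
  (per-step features: pooled mel rows x filters), followed by two recurrent
  layers of 120 and 60 units, a dense layer of 30, dropout 0.25 and the
  softmax.

Grid-searched "hidden profiles" such as ``[32, 64, 60, 30, 15]`` map onto
(conv1, conv2, rnn1, rnn2, dense) in that order.  The softmax itself lives
in the loss; ``predict`` applies it explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn

VARIANTS = ("cnn", "cnn_gru", "cnn_lstm")
ACTIVATIONS = ("relu", "elu", "tanh")


class SpecError(ValueError):
    """A network spec failed validation; the message lists the bad fields."""


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative description of one classifier network."""

    variant: str
    n_classes: int
    n_channels: int = 12
    input_shape: tuple[int, int] = (10, 50)
    conv_filters: tuple[int, int] = (64, 128)
    kernel: int = 5
    pool: int = 2
    recurrent_units: tuple[int, int] = (120, 60)
    dense_sizes: tuple[int, ...] = ()  # resolved by variant when empty
    dropout: float = 0.25
    activation: str = "relu"

    def __post_init__(self) -> None:
        problems = []
        if self.variant not in VARIANTS:
            problems.append(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.n_classes < 2:
            problems.append(f"n_classes must be >= 2, got {self.n_classes}")
        if self.n_channels < 1:
            problems.append("n_channels must be >= 1")
        if not 0 <= self.dropout < 1:
            problems.append(f"dropout must be in [0, 1), got {self.dropout}")
        if self.activation not in ACTIVATIONS:
            problems.append(
                f"activation must be one of {ACTIVATIONS}, got {self.activation!r}"
            )
        if any(v <= 0 for v in self.conv_filters + self.recurrent_units + self.dense_sizes):
            problems.append("all layer sizes must be positive")
        if self.kernel <= 0 or self.pool <= 0:
            problems.append("kernel and pool sizes must be positive")
        if problems:
            raise SpecError("; ".join(problems))

    @property
    def resolved_dense_sizes(self) -> tuple[int, ...]:
        if self.dense_sizes:
            return self.dense_sizes
        return (512, 256) if self.variant == "cnn" else (30,)

    @classmethod
    def from_profile(
        cls, variant: str, n_classes: int, profile: tuple[int, ...], **kwargs
    ) -> "NetworkSpec":
        """Build a spec from a five-element grid-search hidden profile.

        The profile maps onto (conv1, conv2, rnn1, rnn2, dense).  The CNN
        variant uses the two conv entries and keeps its own dense stack.
        """
        if len(profile) != 5:
            raise SpecError(f"hidden profile must have 5 entries, got {profile}")
        conv = (profile[0], profile[1])
        if variant == "cnn":
            return cls(variant=variant, n_classes=n_classes, conv_filters=conv, **kwargs)
        return cls(
            variant=variant,
            n_classes=n_classes,
            conv_filters=conv,
            recurrent_units=(profile[2], profile[3]),
            dense_sizes=(profile[4],),
            **kwargs,
        )


def _pooled(shape: tuple[int, int], pool: int, times: int) -> tuple[int, int]:
    h, w = shape
    for _ in range(times):
        h, w = h // pool, w // pool
    return h, w


def build_network(spec: NetworkSpec, seed: int = 0) -> nn.Sequential:
    """Instantiate an untrained network with seeded Glorot initialization."""
    rng = np.random.default_rng(seed)
    act = spec.activation
    f1, f2 = spec.conv_filters
    layers: list[nn.core.Layer] = [
        nn.Center(0.5, 2.0),  # mel images are in [0, 1]; center to [-1, 1]
        nn.Conv2D(spec.n_channels, f1, spec.kernel, rng, skip_input_grad=True),
        nn.Activation(act),
        nn.MaxPool2D(spec.pool),
        nn.Conv2D(f1, f2, spec.kernel, rng),
        nn.Activation(act),
        nn.MaxPool2D(spec.pool),
    ]
    h, w = _pooled(spec.input_shape, spec.pool, 2)
    if spec.variant == "cnn":
        layers.append(nn.Dropout(spec.dropout, rng))
        layers.append(nn.Flatten())
        dim = f2 * h * w
        for size in spec.resolved_dense_sizes:
            layers += [nn.Dense(dim, size, rng), nn.Activation(act)]
            dim = size
        layers.append(nn.Dense(dim, spec.n_classes, rng))
    else:
        cell = nn.GRU if spec.variant == "cnn_gru" else nn.LSTM
        r1, r2 = spec.recurrent_units
        layers.append(nn.FramesAsTime())
        layers.append(cell(f2 * h, r1, rng, return_sequences=True))
        layers.append(cell(r1, r2, rng, return_sequences=False))
        dim = r2
        for size in spec.resolved_dense_sizes:
            layers += [nn.Dense(dim, size, rng), nn.Activation(act)]
            dim = size
        layers.append(nn.Dropout(spec.dropout, rng))
        layers.append(nn.Dense(dim, spec.n_classes, rng))
    return nn.Sequential(layers)


def parameter_count(spec: NetworkSpec) -> int:
    """Closed-form trainable-parameter count of a spec (no instantiation)."""
    f1, f2 = spec.conv_filters
    k2 = spec.kernel ** 2
    total = (spec.n_channels * k2 + 1) * f1 + (f1 * k2 + 1) * f2
    h, w = _pooled(spec.input_shape, spec.pool, 2)
    if spec.variant == "cnn":
        dim = f2 * h * w
    else:
        gates = 3 if spec.variant == "cnn_gru" else 4
        r1, r2 = spec.recurrent_units
        d = f2 * h
        total += gates * r1 * (d + r1 + 1)
        total += gates * r2 * (r1 + r2 + 1)
        dim = r2
    for size in spec.resolved_dense_sizes:
        total += (dim + 1) * size
        dim = size
    total += (dim + 1) * spec.n_classes
    return total


@dataclass
class TrainedModel:
    """A built network plus the label strings of its softmax order."""

    spec: NetworkSpec
    model: nn.Sequential
    class_order: list[str]

    def __post_init__(self) -> None:
        if len(self.class_order) != self.spec.n_classes:
            raise SpecError(
                f"class_order has {len(self.class_order)} labels for "
                f"{self.spec.n_classes} classes"
            )


def predict(trained: TrainedModel, x: np.ndarray) -> np.ndarray:
    """Class probabilities over ``class_order`` for a tensor or a batch.

    ``x`` is (n_channels, 10, 50) or (batch, n_channels, 10, 50); returns
    the matching (n_classes,) or (batch, n_classes) simplex vectors.
    """
    single = x.ndim == 3
    if single:
        x = x[None]
    expected = (trained.spec.n_channels, *trained.spec.input_shape)
    if x.shape[1:] != expected:
        raise ValueError(f"input shape {x.shape[1:]} does not match spec {expected}")
    probs = nn.softmax(trained.model.forward(x, train=False).astype(np.float64))
    return probs[0] if single else probs


def predict_label(trained: TrainedModel, x: np.ndarray) -> str:
    """Argmax label of one tensor; ties break to the earliest class."""
    return trained.class_order[int(np.argmax(predict(trained, x)))]


def save_model(trained: TrainedModel, path: str | Path) -> None:
    """Save weights (npz) plus a JSON manifest with spec and class order."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "weights.npz", *trained.model.get_weights())
    manifest = {
        "spec": {
            "variant": trained.spec.variant,
            "n_classes": trained.spec.n_classes,
            "n_channels": trained.spec.n_channels,
            "input_shape": list(trained.spec.input_shape),
            "conv_filters": list(trained.spec.conv_filters),
            "kernel": trained.spec.kernel,
            "pool": trained.spec.pool,
            "recurrent_units": list(trained.spec.recurrent_units),
            "dense_sizes": list(trained.spec.dense_sizes),
            "dropout": trained.spec.dropout,
            "activation": trained.spec.activation,
        },
        "class_order": trained.class_order,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    """Load a model saved by :func:`save_model`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    s = manifest["spec"]
    spec = NetworkSpec(
        variant=s["variant"],
        n_classes=s["n_classes"],
        n_channels=s["n_channels"],
        input_shape=tuple(s["input_shape"]),
        conv_filters=tuple(s["conv_filters"]),
        kernel=s["kernel"],
        pool=s["pool"],
        recurrent_units=tuple(s["recurrent_units"]),
        dense_sizes=tuple(s["dense_sizes"]),
        dropout=s["dropout"],
        activation=s["activation"],
    )
    model = build_network(spec, seed=0)
    with np.load(path / "weights.npz") as data:
        model.set_weights([data[f"arr_{i}"] for i in range(len(data.files))])
    return TrainedModel(spec=spec, model=model, class_order=manifest["class_order"])
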