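"""Custom scalogram CNN: architecture arithmetic, training, transfer head.

The custom architecture is a fixed chain over a 600 x 800 single-channel
scalogram image:

    Conv(5 @ 3x3) -> ReLU -> Conv(5 @ 2x2) -> ReLU -> MaxPool(2x2 / 2)
    -> Conv(5 @ 3x3) -> ReLU -> Conv(5 @ 5x5) -> ReLU -> MaxPool(5x5 / 5)
    -> Flatten -> Dense(256) -> ReLU -> Dense(32) -> ReLU -> Dense(1) -> sigmoid

with valid padding throughout.  :func:`infer_shapes_and_params` performs
framework-independent shape inference and parameter counting with exact
integer arithmetic:

    conv params  = kh*kw*C_in*filters + filters
    dense params = in*units + units
    valid conv output = (H - kh + 1, W - kw + 1)
    pool output       = (floor((H - kh)/sh) + 1, floor((W - kw)/sw) + 1)

At the canonical input size the chain totals 5,800,248 trainable
parameters with a 22,620-wide flatten.  The same chain re-inferred at a
reduced input size drives smoke-scale training through the numpy engine
in :mod:`cardiowave.nn`.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import nn
from .classify import ConfusionCounts, EvaluationReport, compute_metrics
from .exceptions import InvalidArgumentError, ShapeMismatchError, ShapeUnderflowError

CANONICAL_INPUT_HWC = (600, 800, 1)


@dataclasses.dataclass(frozen=True)
class LayerSpec:
    kind: str                                   # CONV2D | ACTIVATION | MAXPOOL2D | FLATTEN | DENSE
    kernel_hw: tuple[int, int] | None = None
    filters_or_units: int | None = None
    stride_hw: tuple[int, int] | None = None
    padding: str = "VALID"
    activation: str | None = None               # for ACTIVATION layers: relu | sigmoid


@dataclasses.dataclass(frozen=True)
class InferredLayer:
    spec: LayerSpec
    output_shape: tuple[int, ...]               # (H, W, C) or (units,)
    n_params: int


@dataclasses.dataclass(frozen=True)
class ArchitectureSpec:
    input_hwc: tuple[int, int, int]
    layers: tuple[LayerSpec, ...]


def build_custom_architecture(
    input_hwc: tuple[int, int, int] = CANONICAL_INPUT_HWC,
    filters: int = 5,
    dense_units: tuple[int, int] = (256, 32),
    hidden_activation: str = "relu",
) -> ArchitectureSpec:
    """The fixed custom chain, optionally re-instantiated at another input size."""
    layers = (
        LayerSpec("CONV2D", kernel_hw=(3, 3), filters_or_units=filters),
        LayerSpec("ACTIVATION", activation=hidden_activation),
        LayerSpec("CONV2D", kernel_hw=(2, 2), filters_or_units=filters),
        LayerSpec("ACTIVATION", activation=hidden_activation),
        LayerSpec("MAXPOOL2D", kernel_hw=(2, 2), stride_hw=(2, 2)),
        LayerSpec("CONV2D", kernel_hw=(3, 3), filters_or_units=filters),
        LayerSpec("ACTIVATION", activation=hidden_activation),
        LayerSpec("CONV2D", kernel_hw=(5, 5), filters_or_units=filters),
        LayerSpec("ACTIVATION", activation=hidden_activation),
        LayerSpec("MAXPOOL2D", kernel_hw=(5, 5), stride_hw=(5, 5)),
        LayerSpec("FLATTEN"),
        LayerSpec("DENSE", filters_or_units=dense_units[0]),
        LayerSpec("ACTIVATION", activation=hidden_activation),
        LayerSpec("DENSE", filters_or_units=dense_units[1]),
        LayerSpec("ACTIVATION", activation=hidden_activation),
        LayerSpec("DENSE", filters_or_units=1),
        LayerSpec("ACTIVATION", activation="sigmoid"),
    )
    return ArchitectureSpec(input_hwc=tuple(input_hwc), layers=layers)


def infer_shapes_and_params(spec: ArchitectureSpec) -> tuple[list[InferredLayer], int]:
    """Per-layer output shapes and parameter counts; exact integer arithmetic."""
    shape: tuple[int, ...] = tuple(spec.input_hwc)
    rows: list[InferredLayer] = []
    for layer in spec.layers:
        if layer.kind == "CONV2D":
            h, w, c = shape
            kh, kw = layer.kernel_hw
            h2, w2 = h - kh + 1, w - kw + 1
            if h2 <= 0 or w2 <= 0:
                raise ShapeUnderflowError(f"conv {kh}x{kw} underflows {shape}")
            n_params = kh * kw * c * layer.filters_or_units + layer.filters_or_units
            shape = (h2, w2, layer.filters_or_units)
        elif layer.kind == "MAXPOOL2D":
            h, w, c = shape
            kh, kw = layer.kernel_hw
            sh, sw = layer.stride_hw
            h2, w2 = (h - kh) // sh + 1, (w - kw) // sw + 1
            if h2 <= 0 or w2 <= 0:
                raise ShapeUnderflowError(f"pool {kh}x{kw} underflows {shape}")
            n_params = 0
            shape = (h2, w2, c)
        elif layer.kind == "FLATTEN":
            n_params = 0
            shape = (int(np.prod(shape)),)
        elif layer.kind == "DENSE":
            (in_dim,) = shape
            n_params = in_dim * layer.filters_or_units + layer.filters_or_units
            shape = (layer.filters_or_units,)
        elif layer.kind == "ACTIVATION":
            n_params = 0
        else:
            raise InvalidArgumentError(f"unknown layer kind {layer.kind!r}")
        rows.append(InferredLayer(spec=layer, output_shape=shape, n_params=n_params))
    return rows, sum(r.n_params for r in rows)


def format_architecture_table(spec: ArchitectureSpec) -> str:
    """Printable summary: layer kind, output shape, parameter count."""
    rows, total = infer_shapes_and_params(spec)
    lines = [f"{'Layer':<14}{'Output shape':<22}{'Params':>12}"]
    for r in rows:
        shape = "(None, " + ", ".join(f"{d:,}" for d in r.output_shape) + ")"
        lines.append(f"{r.spec.kind:<14}{shape:<22}{r.n_params:>12,}")
    lines.append(f"Total parameters: {total:,}")
    return "\n".join(lines)


def build_transfer_head(
    backbone_output_dim: int,
    d1: int = 256,
    d2: int = 32,
) -> tuple[LayerSpec, ...]:
    """Three appended layers for a pretrained backbone: Dense(d1) ->
    Dense(d2) -> Dense(1, sigmoid).  Backbone weights are external and
    never bundled; this only specifies the head."""
    if backbone_output_dim <= 0:
        raise InvalidArgumentError("backbone output dimension must be positive")
    if d1 < 1 or d2 < 1:
        raise InvalidArgumentError("head widths must be >= 1")
    return (
        LayerSpec("DENSE", filters_or_units=d1),
        LayerSpec("DENSE", filters_or_units=d2),
        LayerSpec("DENSE", filters_or_units=1, activation="sigmoid"),
    )


def head_param_count(backbone_output_dim: int, d1: int = 256, d2: int = 32) -> int:
    return (backbone_output_dim * d1 + d1) + (d1 * d2 + d2) + (d2 + 1)


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters for the scalogram CNN."""

    learning_rate: float = 8e-4
    epochs: int = 30
    batch_size: int = 16
    folds: int = 10
    holdout_ratio: float = 0.2
    seed: int = 0
    patience: int = 5
    loss: str = "binary_crossentropy"
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise InvalidArgumentError("learning rate must be positive")
        if not 0.0 < self.holdout_ratio < 1.0:
            raise InvalidArgumentError("holdout ratio must be in (0, 1)")
        if self.folds < 2:
            raise InvalidArgumentError("need at least 2 CV folds")


def build_network(spec: ArchitectureSpec, seed: int = 0) -> nn.Network:
    """Instantiate the numpy engine's layers from an architecture spec.

    The final sigmoid is folded into the loss (trained with logits), so
    the materialized network ends at the last dense layer.
    """
    rng = np.random.default_rng(seed)
    rows, _ = infer_shapes_and_params(spec)
    layers: list[nn.Layer] = []
    shape: tuple[int, ...] = spec.input_hwc
    for layer, inferred in zip(spec.layers, rows):
        if layer.kind == "CONV2D":
            layers.append(nn.Conv2D(shape[2], layer.filters_or_units, layer.kernel_hw, rng))
        elif layer.kind == "MAXPOOL2D":
            layers.append(nn.MaxPool2D(layer.kernel_hw))
        elif layer.kind == "FLATTEN":
            layers.append(nn.Flatten())
        elif layer.kind == "DENSE":
            layers.append(nn.Dense(shape[0], layer.filters_or_units, rng))
        elif layer.kind == "ACTIVATION" and layer.activation == "relu":
            layers.append(nn.ReLU())
        # the terminal sigmoid lives inside the loss
        shape = inferred.output_shape
    return nn.Network(layers)


def _stratified_split(y: np.ndarray, ratio: float, rng: np.random.Generator):
    test_idx = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_test = max(1, int(round(ratio * idx.size)))
        test_idx.append(idx[:n_test])
    test = np.sort(np.concatenate(test_idx))
    train = np.setdiff1d(np.arange(y.size), test)
    return train, test


def train_cnn(
    images: np.ndarray,
    labels: Sequence[int],
    config: TrainConfig = TrainConfig(),
    spec: ArchitectureSpec | None = None,
) -> EvaluationReport:
    """Hold out ``holdout_ratio`` of the images, run ``folds``-fold CV on
    the remainder, then train a final model on all non-held-out images
    and report held-out metrics.

    ``images`` is (N, H, W, 1); ``labels`` binary 0/1.  If ``spec`` is
    omitted the custom chain is re-inferred at the images' own size.
    """
    x = np.asarray(images, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.ndim != 4 or x.shape[0] != y.size:
        raise InvalidArgumentError("expected (N, H, W, C) images aligned with labels")
    if len(np.unique(y)) < 2:
        raise InvalidArgumentError("need both classes present")
    if spec is None:
        spec = build_custom_architecture(input_hwc=x.shape[1:])
    if tuple(x.shape[1:]) != tuple(spec.input_hwc):
        raise ShapeMismatchError(
            f"images {x.shape[1:]} do not match spec input {spec.input_hwc}")

    rng = np.random.default_rng(config.seed)
    train_idx, hold_idx = _stratified_split(y, config.holdout_ratio, rng)
    x_tr, y_tr = x[train_idx], y[train_idx]
    x_ho, y_ho = x[hold_idx], y[hold_idx]

    # k-fold CV on the non-held-out portion
    order = rng.permutation(len(y_tr))
    folds = np.array_split(order, config.folds)
    fold_acc = []
    for f, va in enumerate(folds):
        tr = np.setdiff1d(order, va)
        net = build_network(spec, seed=config.seed + 100 + f)
        nn.train_binary(
            net, x_tr[tr], y_tr[tr],
            epochs=config.epochs, batch_size=config.batch_size,
            learning_rate=config.learning_rate, seed=config.seed + 200 + f,
            x_val=x_tr[va], y_val=y_tr[va], patience=config.patience,
        )
        fold_acc.append(float(np.mean((net.predict_proba(x_tr[va]) >= 0.5) == y_tr[va])))

    # Final model: trained on all non-held-out data; the held-out set is
    # never touched before prediction.
    final = build_network(spec, seed=config.seed)
    nn.train_binary(
        final, x_tr, y_tr,
        epochs=config.epochs, batch_size=config.batch_size,
        learning_rate=config.learning_rate, seed=config.seed + 1,
    )
    preds = (final.predict_proba(x_ho) >= 0.5).astype(int)
    truths = [str(int(v)) for v in y_ho]
    predicted = [str(int(v)) for v in preds]
    confusion = ConfusionCounts.from_predictions(truths, predicted, classes=("1", "0"))
    metrics = compute_metrics(confusion)
    return EvaluationReport(
        scheme="KFOLD", per_class=metrics["per_class"], accuracy=metrics["accuracy"],
        confusion=confusion, model_family="CNN", best_params={}, seed=config.seed,
        truths=tuple(truths), predictions=tuple(predicted),
        extras={
            "fold_accuracies": fold_acc,
            "fold_mean_accuracy": float(np.mean(fold_acc)),
            "n_holdout": int(hold_idx.size),
            "n_params": final.n_params,
        },
    )
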