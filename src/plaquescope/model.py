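"""Multi-task CNN tile classifier.

A single network predicts, for one 256 x 256 px tile, three independent
confidences: cored plaque, diffuse plaque and CAA.  The architecture is
six 3x3 convolution blocks (stride 1, padding 1, rectifier, dropout 0.2,
2x2 max pool) followed by two dense layers (512 and 100 units, rectifier,
dropout 0.5) and a 3-logit head; each task confidence is the logistic of
its logit (multi-label, no softmax coupling).  Training uses Adam with an
L2 penalty of 0.008 and a multi-label soft-margin loss on mini-batches of
64 augmented tiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import nn

TASKS = ("cored", "diffuse", "caa")

__all__ = [
    "TASKS",
    "ModelConfig",
    "TrainConfig",
    "PredictionTriple",
    "ClassifyThresholds",
    "build_model",
    "parameter_count",
    "multilabel_soft_margin_loss",
    "train",
    "predict",
    "predict_batch",
    "classify",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    input_px: int = 256
    conv_channels: tuple = (16, 16, 32, 32, 64, 64)
    kernel: int = 3
    stride: int = 1
    padding: int = 1
    fc_sizes: tuple = (512, 100)
    n_tasks: int = 3
    dropout_conv: float = 0.2
    dropout_fc: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if len(self.conv_channels) != 6:
            raise ValueError("exactly six convolutional layers are required")
        if self.input_px % 2 ** 6 != 0:
            raise ValueError("input_px must be divisible by 2^6 (six pooling stages)")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 40
    batch_size: int = 64
    weight_decay: float = 0.008
    patience: int = 5
    seed: int = 0
    micro_batch: int = 8  # gradient-accumulation chunk; cache locality only
    lr_decay: float = 1.0  # per-epoch multiplicative decay (1.0 = constant)
    lr_decay_start: int = 0  # epochs at full rate before decay kicks in


@dataclass(frozen=True)
class PredictionTriple:
    cored: float
    diffuse: float
    caa: float

    def as_array(self) -> np.ndarray:
        return np.array([self.cored, self.diffuse, self.caa])

    def __post_init__(self):
        for v in (self.cored, self.diffuse, self.caa):
            if not (0.0 <= v <= 1.0):
                raise ValueError("confidences must lie in [0, 1]")


@dataclass(frozen=True)
class ClassifyThresholds:
    cored: float = 0.91
    diffuse: float = 0.1
    caa: float = 0.85

    def as_array(self) -> np.ndarray:
        return np.array([self.cored, self.diffuse, self.caa])


class TileClassifier:
    """Bundles the network with its configuration."""

    def __init__(self, config: ModelConfig, net: nn.Net):
        self.config = config
        self.net = net

    @property
    def last_conv_index(self) -> int:
        """Layer index of the rectifier following the last convolution."""
        return self._last_conv_relu

    def scale_input(self, tiles: np.ndarray) -> np.ndarray:
        """HWC uint8 tiles -> NHWC float32 in [0, 1]."""
        x = np.asarray(tiles)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != (self.config.input_px, self.config.input_px, 3):
            raise ValueError(f"expected {self.config.input_px}^2 RGB tiles, got {x.shape}")
        return np.ascontiguousarray(x, dtype=np.float32) / np.float32(255.0)


def build_model(config: ModelConfig = ModelConfig()) -> TileClassifier:
    rng = np.random.default_rng(config.seed)
    layers: list[nn.Layer] = []
    cin = 3
    relu_idx = []
    for cout in config.conv_channels:
        layers.append(nn.Conv3x3(cin, cout, rng))
        layers.append(nn.ReLU())
        relu_idx.append(len(layers) - 1)
        layers.append(nn.Dropout(config.dropout_conv))
        layers.append(nn.MaxPool2())
        cin = cout
    side = config.input_px // 2 ** 6
    layers.append(nn.Flatten())
    nin = side * side * config.conv_channels[-1]
    for nout in config.fc_sizes:
        layers.append(nn.Dense(nin, nout, rng))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(config.dropout_fc))
        nin = nout
    layers.append(nn.Dense(nin, config.n_tasks, rng))
    model = TileClassifier(config, nn.Net(layers))
    model._last_conv_relu = relu_idx[-1]
    return model


def parameter_count(config: ModelConfig = ModelConfig()) -> int:
    return build_model(config).net.n_parameters()


def multilabel_soft_margin_loss(logits, labels) -> float:
    """Mean over tasks of -[y log s(x) + (1-y) log(1-s(x))], s the logistic."""
    return nn.multilabel_soft_margin(np.atleast_2d(logits), np.atleast_2d(labels))


def _eval_loss(model: TileClassifier, tiles, labels, batch: int = 64) -> float:
    losses, ns = [], []
    for i in range(0, len(tiles), batch):
        x = model.scale_input(np.asarray(tiles[i:i + batch]))
        logits = model.net.forward(x, train=False)
        losses.append(nn.multilabel_soft_margin(logits, labels[i:i + batch]))
        ns.append(len(x))
    return float(np.average(losses, weights=ns))


def train(model: TileClassifier,
          tiles: np.ndarray,
          labels: np.ndarray,
          config: TrainConfig = TrainConfig(),
          sample_weights: np.ndarray | None = None,
          augment_fn: Callable[[np.ndarray, int], np.ndarray] | None = None,
          val_tiles: np.ndarray | None = None,
          val_labels: np.ndarray | None = None) -> tuple[TileClassifier, pd.DataFrame]:
    """Train in place; returns the model and a per-epoch loss history.

    ``sample_weights`` selects mini-batches by weighted sampling with
    replacement (minority-class oversampling); otherwise epochs iterate a
    seeded permutation.  ``augment_fn(tile, seed)`` is applied to every
    drawn tile.  Early stopping monitors validation loss with the
    configured patience and restores the best weights.
    """
    tiles = np.asarray(tiles)
    labels = np.asarray(labels, dtype=np.float32)
    n = len(tiles)
    if n == 0:
        raise ValueError("empty training set")
    if labels.shape != (n, model.config.n_tasks):
        raise ValueError("labels must be (n_tiles, n_tasks)")
    rng = np.random.default_rng(config.seed)
    if sample_weights is not None:
        sample_weights = np.asarray(sample_weights, dtype=np.float64)
        if len(sample_weights) != n or (sample_weights <= 0).any():
            raise ValueError("sample_weights must be positive, one per tile")
        sample_weights = sample_weights / sample_weights.sum()
    opt = nn.Adam(model.net, lr=config.learning_rate, weight_decay=config.weight_decay)
    steps = max(1, int(np.ceil(n / config.batch_size)))
    history = []
    best = (np.inf, None, -1)
    bad_epochs = 0
    for epoch in range(config.epochs):
        opt.lr = config.learning_rate * config.lr_decay ** max(0, epoch - config.lr_decay_start)
        if sample_weights is not None:
            order = rng.choice(n, size=steps * config.batch_size, replace=True, p=sample_weights)
        else:
            order = rng.permutation(n)
        epoch_losses = []
        for s in range(steps):
            idx = order[s * config.batch_size:(s + 1) * config.batch_size]
            if len(idx) == 0:
                continue
            batch = tiles[idx]
            if augment_fn is not None:
                seeds = rng.integers(0, 2 ** 31, size=len(idx))
                batch = np.stack([augment_fn(t, int(sd)) for t, sd in zip(batch, seeds)])
            y = labels[idx]
            # micro-batched gradient accumulation: mathematically one
            # batch-mean gradient step, but each chunk stays cache-resident
            micro = max(1, config.micro_batch)
            accum = None
            chunk_losses = []
            for c0 in range(0, len(idx), micro):
                xb = model.scale_input(batch[c0:c0 + micro])
                yb = y[c0:c0 + micro]
                logits = model.net.forward(xb, train=True, rng=rng)
                loss = nn.multilabel_soft_margin(logits, yb)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, step {s} (loss={loss})")
                scale = len(xb) / len(idx)
                model.net.backward(nn.multilabel_soft_margin_grad(logits, yb)
                                   * np.float32(scale))
                grads = [p[2] for _, p in model.net.parameters()]
                if accum is None:
                    accum = grads
                else:
                    for a, g in zip(accum, grads):
                        a += g
                chunk_losses.append((loss, len(xb)))
            for (_, p), a in zip(model.net.parameters(), accum):
                p[2] = a
            opt.step()
            epoch_losses.append(float(np.average([l for l, _ in chunk_losses],
                                                 weights=[n for _, n in chunk_losses])))
        train_loss = float(np.mean(epoch_losses))
        val_loss = np.nan
        if val_tiles is not None:
            val_loss = _eval_loss(model, val_tiles, np.asarray(val_labels, dtype=np.float32))
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_tiles is not None:
            if val_loss < best[0] - 1e-12:
                best = (val_loss, {k: v.copy() for k, v in model.net.state_dict().items()}, epoch)
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > config.patience:
                    break
    if best[1] is not None:
        model.net.load_state_dict(best[1])
    return model, pd.DataFrame(history)


def predict_batch(model: TileClassifier, tiles: np.ndarray) -> np.ndarray:
    """Confidences for a stack of tiles, shape (n, 3); dropout inactive."""
    x = model.scale_input(tiles)
    logits = model.net.forward(x, train=False)
    return nn.sigmoid(logits)


def predict(model: TileClassifier, tile: np.ndarray) -> PredictionTriple:
    if np.asarray(tile).ndim != 3:
        raise ValueError("predict expects a single HWC tile")
    conf = predict_batch(model, tile)[0]
    return PredictionTriple(*map(float, conf))


def classify(pred: PredictionTriple, thresholds: ClassifyThresholds = ClassifyThresholds()) -> set:
    """Labels whose confidence is strictly above the task threshold."""
    conf = pred.as_array()
    thr = thresholds.as_array()
    return {task for task, c, t in zip(TASKS, conf, thr) if c > t}


def save_checkpoint(model: TileClassifier, path: str | Path):
    path = Path(path)
    meta = {"config": asdict(model.config)}
    np.savez(path.with_suffix(".npz"), **model.net.state_dict())
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> TileClassifier:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = meta["config"]
    cfg["conv_channels"] = tuple(cfg["conv_channels"])
    cfg["fc_sizes"] = tuple(cfg["fc_sizes"])
    model = build_model(ModelConfig(**cfg))
    with np.load(path.with_suffix(".npz")) as state:
        model.net.load_state_dict(dict(state))
    return model
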