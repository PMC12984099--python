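"""Lightweight Max-Feature-Map CNN classifier and its training loop.

Architecture (default): four blocks of
``conv(2f, k) -> MFM (halves channels to f) -> batch-norm -> 2x2 max-pool``
with (filters, kernel) = (16,5), (32,3), (48,3), (64,3), followed by global
average pooling, dropout 0.5, a dense layer with MFM, and a softmax output.
The default model stays well under 2 million parameters — the "lightweight"
contract — and accepts any input whose sides are divisible by 16.

Training uses Adam (lr 1e-4), categorical cross-entropy, batch size 32 and
early stopping on validation loss with the best-epoch weights restored.
All randomness (initialization, shuffling, dropout) derives from a single
seed, so split membership and training trajectories are reproducible.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from .datasets import LabeledDataset
from .errors import ConfigurationError, DataError, StageError

logger = logging.getLogger(__name__)

__all__ = [
    "LightCNNConfig",
    "TrainConfig",
    "TrainHistory",
    "LightCNN",
    "mfm_activation",
    "build_model",
    "train",
    "predict",
    "save_model",
    "load_model",
]


@dataclass
class LightCNNConfig:
    conv_blocks: list[tuple[int, int]] = field(
        default_factory=lambda: [(16, 5), (32, 3), (48, 3), (64, 3)]
    )
    dense_units: int = 64
    dropout_rate: float = 0.5
    num_classes: int = 2

    def validate(self) -> None:
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError(f"invalid dropout_rate {self.dropout_rate}")
        for f, k in self.conv_blocks:
            if f < 1 or k < 1 or k % 2 == 0:
                raise ConfigurationError(
                    f"conv block ({f}, {k}) needs positive filters and odd kernel"
                )


@dataclass
class TrainConfig:
    batch_size: int = 32
    epochs: int = 50
    learning_rate: float = 1e-4
    patience: int = 7
    min_delta: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1 or self.epochs < 1 or self.patience < 0:
            raise ConfigurationError("batch_size/epochs/patience must be positive")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_early: bool = False

    def to_rows(self):
        return [
            {
                "epoch": i + 1,
                "train_loss": self.train_loss[i],
                "val_loss": self.val_loss[i],
                "train_acc": self.train_acc[i],
                "val_acc": self.val_acc[i],
            }
            for i in range(len(self.train_loss))
        ]


def mfm_activation(features: np.ndarray) -> np.ndarray:
    """Max-Feature-Map over the channel axis: ``max(x[..c], x[..c+C])``."""
    return _nn.MFM().forward(np.asarray(features), training=False)


class LightCNN:
    """MFM convolutional classifier over (N, H, W, 1) inputs in [0, 1]."""

    def __init__(self, cfg: LightCNNConfig, seed: int = 0):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        layers: list[_nn.Layer] = []
        c_in = 1
        for f, k in cfg.conv_blocks:
            layers += [
                _nn.Conv2D(c_in, 2 * f, k, rng),
                _nn.MFM(),
                _nn.BatchNorm(f),
                _nn.MaxPool2(),
            ]
            c_in = f
        layers += [
            _nn.GlobalAvgPool(),
            _nn.Dropout(cfg.dropout_rate, rng),
            _nn.Dense(c_in, 2 * cfg.dense_units, rng),
            _nn.MFM(),
            _nn.Dense(cfg.dense_units, cfg.num_classes, rng, init_scale=0.01),
        ]
        self.net = _nn.Sequential(layers)

    # -- inference ---------------------------------------------------------
    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def _as_batch(self, imgs: np.ndarray) -> np.ndarray:
        x = np.asarray(imgs, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[..., None]
        if x.ndim != 4:
            raise DataError(f"expected (N, H, W[, 1]) images, got shape {imgs.shape}")
        depth = 2 ** sum(1 for _ in self.cfg.conv_blocks)
        if x.shape[1] % depth or x.shape[2] % depth:
            raise DataError(
                f"input sides must be divisible by {depth}, got {x.shape[1:3]}"
            )
        return x

    def predict_proba(self, imgs: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = self._as_batch(imgs)
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.net.forward(x[i:i + batch_size], training=False)
            out.append(_nn.softmax(logits.astype(np.float64)))
        return np.concatenate(out)

    def predict(self, imgs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Labels (argmax, ties to the lower index) and probabilities."""
        probs = self.predict_proba(imgs)
        return probs.argmax(axis=1), probs


def build_model(cfg: LightCNNConfig | None = None, seed: int = 0) -> LightCNN:
    cfg = cfg or LightCNNConfig()
    model = LightCNN(cfg, seed=seed)
    n = model.n_parameters()
    logger.info("LightCNN built: %d parameters, %d classes", n, cfg.num_classes)
    return model


def predict(model: LightCNN, imgs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return model.predict(imgs)


def _evaluate(model: LightCNN, x: np.ndarray, y: np.ndarray,
              batch_size: int = 64) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i:i + batch_size], y[i:i + batch_size]
        logits = model.net.forward(xb, training=False)
        loss, _ = _nn.cross_entropy_with_grad(logits, yb)
        losses.append(loss * len(xb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train(
    model: LightCNN,
    ds: LabeledDataset,
    tcfg: TrainConfig | None = None,
) -> tuple[LightCNN, TrainHistory]:
    """Fit on the train split, early-stop on the val split's loss."""
    tcfg = tcfg or TrainConfig()
    tcfg.validate()
    x_tr, y_tr = ds.subset("train")
    x_va, y_va = ds.subset("val")
    if len(x_tr) == 0:
        raise DataError("empty training split")
    has_val = len(x_va) > 0
    x_tr = model._as_batch(x_tr)
    if has_val:
        x_va = model._as_batch(x_va)

    rng = np.random.default_rng(tcfg.seed)
    opt = _nn.Adam(model.net.params, model.net.grads, lr=tcfg.learning_rate)
    hist = TrainHistory()
    best_loss, best_state, wait = np.inf, None, 0

    for epoch in range(tcfg.epochs):
        perm = rng.permutation(len(x_tr))
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, len(perm), tcfg.batch_size):
            idx = perm[i:i + tcfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            logits = model.net.forward(xb, training=True)
            loss, g = _nn.cross_entropy_with_grad(logits, yb)
            if not np.isfinite(loss):
                raise StageError("train", f"non-finite loss at epoch {epoch + 1}")
            model.net.backward(g)
            opt.step()
            ep_loss += loss * len(xb)
            ep_correct += int((logits.argmax(axis=1) == yb).sum())
        hist.train_loss.append(ep_loss / len(x_tr))
        hist.train_acc.append(ep_correct / len(x_tr))

        if has_val:
            v_loss, v_acc = _evaluate(model, x_va, y_va)
        else:
            v_loss, v_acc = hist.train_loss[-1], hist.train_acc[-1]
        hist.val_loss.append(v_loss)
        hist.val_acc.append(v_acc)
        logger.info(
            "epoch %d: train loss %.4f acc %.3f | val loss %.4f acc %.3f",
            epoch + 1, hist.train_loss[-1], hist.train_acc[-1], v_loss, v_acc,
        )

        if v_loss < best_loss - tcfg.min_delta:
            best_loss, best_state, wait = v_loss, model.net.get_state(), 0
            hist.best_epoch = epoch + 1
        else:
            wait += 1
            if wait > tcfg.patience:
                hist.stopped_early = True
                break

    if best_state is not None:
        model.net.set_state(best_state)
    return model, hist


def save_model(model: LightCNN, path: str | Path) -> None:
    """Single-file npz checkpoint plus the architecture as embedded JSON."""
    arch = {
        "conv_blocks": model.cfg.conv_blocks,
        "dense_units": model.cfg.dense_units,
        "dropout_rate": model.cfg.dropout_rate,
        "num_classes": model.cfg.num_classes,
    }
    state = model.net.get_state()
    np.savez(
        path,
        arch=np.frombuffer(json.dumps(arch).encode(), dtype=np.uint8),
        **{f"s{i}": s for i, s in enumerate(state)},
    )


def load_model(path: str | Path) -> LightCNN:
    with np.load(path) as data:
        arch = json.loads(bytes(data["arch"]).decode())
        state = [data[f"s{i}"] for i in range(len(data.files) - 1)]
    cfg = LightCNNConfig(
        conv_blocks=[tuple(b) for b in arch["conv_blocks"]],
        dense_units=arch["dense_units"],
        dropout_rate=arch["dropout_rate"],
        num_classes=arch["num_classes"],
    )
    model = LightCNN(cfg)
    model.net.set_state(state)
    return model
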