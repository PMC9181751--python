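"""Training regimen for the patch-thickness regressor.

Plain SGD with classical momentum and L2 weight decay minimising the MAE
loss, under a fixed piecewise-constant learning-rate schedule: 0.002 for
epochs 1-11, 0.0002 for epochs 12-27 and 0.00002 thereafter, with 41 epochs
and mini-batches of 15 by default.  Weight decay touches convolution and
dense weights, never biases; the last incomplete mini-batch of an epoch is
used, not dropped; shuffling is per-epoch and seed-driven, so a run is
fully reproducible on a fixed backend.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .model import CNNRegressor, as_batch, mae_loss, predict_patches

__all__ = ["TrainConfig", "TrainLog", "lr_at_epoch", "train"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (defaults follow the reference regimen)."""

    epochs: int = 41
    batch_size: int = 15
    lr_initial: float = 0.002
    lr_mid: float = 0.0002
    lr_final: float = 0.00002
    phase1_end: int = 11   # last epoch trained at lr_initial
    phase2_end: int = 27   # last epoch trained at lr_mid
    momentum: float = 0.9
    weight_decay: float = 0.0005
    seed: int = 0
    select: str = "final"  # "final" = epoch-N weights; "best" = best-val-MAE weights
    # Warm-start the head bias at the mean training label.  Under an MAE
    # loss the output drifts toward the label mean at a rate bounded by the
    # learning rate, so a zero-initialised head wastes early epochs closing
    # a ~60 px gap; starting at the mean spends them on actual structure.
    init_head_bias_to_label_mean: bool = True

    def validate(self) -> None:
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if not (self.lr_initial >= self.lr_mid >= self.lr_final > 0):
            raise ConfigurationError("learning-rate schedule must be non-increasing and positive")
        if not 1 <= self.phase1_end <= self.phase2_end:
            raise ConfigurationError("phase boundaries must satisfy 1 <= phase1_end <= phase2_end")
        if not 0 <= self.momentum < 1:
            raise ConfigurationError("momentum must lie in [0, 1)")
        if self.weight_decay < 0:
            raise ConfigurationError("weight_decay must be >= 0")
        if self.select not in ("final", "best"):
            raise ConfigurationError("select must be 'final' or 'best'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainLog:
    """Per-epoch record of the run (one entry per completed epoch)."""

    epoch: list[int] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)
    seconds: list[float] = field(default_factory=list)

    def append(self, epoch: int, lr: float, loss: float, val: float, secs: float) -> None:
        self.epoch.append(epoch)
        self.learning_rate.append(lr)
        self.train_loss.append(loss)
        self.val_mae.append(val)
        self.seconds.append(secs)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": self.epoch,
            "learning_rate": self.learning_rate,
            "train_loss": self.train_loss,
            "val_mae": self.val_mae,
            "seconds": self.seconds,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """Learning rate of a 1-based epoch under the piecewise schedule."""
    config.validate()
    if not 1 <= epoch <= config.epochs:
        raise ConfigurationError(f"epoch {epoch} outside [1, {config.epochs}]")
    if epoch <= config.phase1_end:
        return config.lr_initial
    if epoch <= config.phase2_end:
        return config.lr_mid
    return config.lr_final


def _labelled_arrays(patches, spec) -> tuple[np.ndarray, np.ndarray]:
    """Accept (rasters, labels) pairs or objects with .pixels/.label."""
    if isinstance(patches, tuple) and len(patches) == 2:
        rasters, labels = patches
    else:
        rasters = [p.pixels for p in patches]
        labels = [p.label for p in patches]
    rasters = np.asarray(rasters) if not isinstance(rasters, np.ndarray) else rasters
    if (rasters.ndim == 4 and rasters.shape[1] == spec.input_channels
            and rasters.shape[2:] == (spec.input_height, spec.input_width)):
        x = rasters.astype(float)  # already NCHW
    else:
        x = as_batch(list(rasters), spec)
    y = np.asarray(labels, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ConfigurationError("labels must be finite")
    return x, y


def train(regressor: CNNRegressor, train_patches, val_patches,
          config: TrainConfig) -> tuple[CNNRegressor, TrainLog]:
    """Fit the regressor in place and return it with the per-epoch log."""
    config.validate()
    x_train, y_train = _labelled_arrays(train_patches, regressor.spec)
    x_val, y_val = _labelled_arrays(val_patches, regressor.spec)
    if len(x_train) == 0:
        raise ConfigurationError("training set is empty")

    if config.init_head_bias_to_label_mean:
        head = regressor.net.layers[-1]
        head.params["b"][...] = float(np.mean(y_train))

    rng = np.random.default_rng(config.seed)
    params = regressor.net.parameters()
    velocity = {name: np.zeros_like(p) for name, p in params.items()}
    decayed = regressor.net.decayed_names()

    log = TrainLog()
    best_val = np.inf
    best_weights: dict[str, np.ndarray] | None = None

    n = len(x_train)
    for epoch in range(1, config.epochs + 1):
        tic = time.perf_counter()
        lr = lr_at_epoch(epoch, config)
        order = rng.permutation(n)
        epoch_losses: list[float] = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            # d(MAE)/d(prediction) = sign(residual)/batch
            pred = regressor.net.forward(xb)[:, 0]
            residual = pred - yb
            loss = float(np.mean(np.abs(residual)))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting at {start}"
                )
            epoch_losses.append(loss)
            regressor.net.backward((np.sign(residual) / len(idx))[:, None])
            grads = regressor.net.gradients()
            for name, p in params.items():
                g = grads[name]
                if name in decayed and config.weight_decay > 0:
                    g = g + config.weight_decay * p
                velocity[name] = config.momentum * velocity[name] - lr * g
                p += velocity[name]

        val_mae = mae_loss(predict_patches(regressor, [a for a in x_val.transpose(0, 2, 3, 1)]),
                           y_val) if len(x_val) else float("nan")
        log.append(epoch, lr, float(np.mean(epoch_losses)), val_mae,
                   time.perf_counter() - tic)
        if config.select == "best" and val_mae < best_val:
            best_val = val_mae
            best_weights = {k: v.copy() for k, v in params.items()}

    if config.select == "best" and best_weights is not None:
        regressor.net.set_parameters(best_weights)
    return regressor, log
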