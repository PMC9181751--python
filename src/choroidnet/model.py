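"""The patch-thickness CNN regressor.

Seven 3x3 convolutions, each followed by a ReLU; after every second
convolution a 2x2 max-pool halves the feature maps; a single fully
connected layer maps the flattened final features to one scalar — the mean
choroidal thickness of the input patch, in pixels.  Mean absolute error is
the training loss.  The same architecture accepts any patch size whose
feature maps survive the three poolings; only the fully connected fan-in
changes (optionally, a stride-2 first convolution bounds it for large
patches).

The paper-scale input is a 3-channel patch with intensities in [0, 1];
targets stay in raw pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import Conv2D, Dense, Flatten, MaxPool2, ReLU, Sequential
from .errors import ConfigurationError

__all__ = [
    "RegressorSpec",
    "PredictionRecord",
    "CNNRegressor",
    "build_regressor",
    "mae_loss",
    "predict_patches",
    "save_checkpoint",
    "load_checkpoint",
]

N_CONV_LAYERS = 7
POOL_EVERY = 2


@dataclass(frozen=True)
class RegressorSpec:
    """Architecture hyperparameters of the 7-conv thickness regressor.

    ``conv_channels`` is the output-channel ladder of the seven
    convolutions; the default keeps the model comfortably CPU-trainable.
    ``first_conv_stride`` may be set to 2 for large patches (e.g. 400x400)
    to bound the fully connected fan-in while keeping the architecture
    unchanged.
    """

    input_height: int
    input_width: int
    input_channels: int = 3
    conv_channels: tuple[int, ...] = (16, 16, 32, 32, 64, 64, 64)
    kernel_size: int = 3
    first_conv_stride: int = 1
    # "xavier_improved" is the ReLU-gain-corrected Xavier variant popularised
    # by the MatConvNet toolchain; plain "xavier" (Glorot) attenuates
    # activations through seven ReLU stages and trains far more slowly.
    init: str = "xavier_improved"

    def validate(self) -> None:
        if len(self.conv_channels) != N_CONV_LAYERS:
            raise ConfigurationError(
                f"conv_channels must list exactly {N_CONV_LAYERS} layers, "
                f"got {len(self.conv_channels)}"
            )
        if any(c < 1 for c in self.conv_channels):
            raise ConfigurationError("conv_channels must be positive")
        if self.input_channels < 1:
            raise ConfigurationError("input_channels must be >= 1")
        if self.first_conv_stride not in (1, 2):
            raise ConfigurationError("first_conv_stride must be 1 or 2")
        if self.init not in ("xavier_improved", "xavier"):
            raise ConfigurationError("init must be 'xavier_improved' or 'xavier'")
        if self.kernel_size % 2 != 1 or self.kernel_size < 1:
            raise ConfigurationError("kernel_size must be a positive odd integer")
        h, w = self.feature_hw()
        if h < 1 or w < 1:
            raise ConfigurationError(
                f"input {self.input_height}x{self.input_width} collapses to "
                f"{h}x{w} after pooling; use a larger patch"
            )

    def feature_hw(self) -> tuple[int, int]:
        """Spatial size of the final feature map after convs and pools."""
        h, w = self.input_height, self.input_width
        if self.first_conv_stride == 2:
            h, w = (h + 1) // 2, (w + 1) // 2
        for _ in range(N_CONV_LAYERS // POOL_EVERY):
            h, w = h // 2, w // 2
        return h, w

    def fc_in_features(self) -> int:
        h, w = self.feature_hw()
        return self.conv_channels[-1] * h * w

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RegressorSpec":
        d = dict(d)
        d["conv_channels"] = tuple(d["conv_channels"])
        return cls(**d)


@dataclass
class PredictionRecord:
    """One prediction/truth pair at patch or B-scan level."""

    level: str  # "patch" or "bscan"
    subject_id: str
    volume_id: str
    slice_index: int
    segment_index: int | None
    predicted: float
    truth: float


class CNNRegressor:
    """Callable network mapping a patch raster to one thickness scalar."""

    def __init__(self, spec: RegressorSpec, net: Sequential) -> None:
        self.spec = spec
        self.net = net

    def __call__(self, batch: np.ndarray) -> np.ndarray:
        """Forward pass on an NCHW batch; returns shape (batch,)."""
        return self.net.forward(batch)[:, 0]

    def forward_backward(self, batch: np.ndarray, dpred: np.ndarray) -> np.ndarray:
        """Forward pass followed by backprop of d(loss)/d(prediction)."""
        pred = self.net.forward(batch)[:, 0]
        self.net.backward(dpred[:, None])
        return pred

    def num_parameters(self) -> int:
        return sum(p.size for p in self.net.parameters().values())

    def zero_parameters(self) -> None:
        """Debug helper: a zeroed network predicts exactly 0 everywhere."""
        for p in self.net.parameters().values():
            p[...] = 0.0


def build_regressor(spec: RegressorSpec, seed: int) -> CNNRegressor:
    """Instantiate the 7-conv regressor with Xavier-initialised weights."""
    spec.validate()
    rng = np.random.default_rng(seed)
    layers = []
    cin = spec.input_channels
    for i, cout in enumerate(spec.conv_channels):
        stride = spec.first_conv_stride if i == 0 else 1
        layers.append(Conv2D(cin, cout, spec.kernel_size, stride, rng, init=spec.init))
        layers.append(ReLU())
        if (i + 1) % POOL_EVERY == 0:
            layers.append(MaxPool2())
        cin = cout
    layers.append(Flatten())
    layers.append(Dense(spec.fc_in_features(), 1, rng))
    return CNNRegressor(spec, Sequential(layers))


def mae_loss(predicted: Sequence[float], truth: Sequence[float]) -> float:
    """Mean absolute error over a batch: mean |predicted - truth|."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"batch shapes differ: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("mae_loss of an empty batch is undefined")
    return float(np.mean(np.abs(p - t)))


def as_batch(patches: Sequence[np.ndarray] | np.ndarray, spec: RegressorSpec) -> np.ndarray:
    """Stack patch rasters into an NCHW batch, checking dimensions."""
    expected = (spec.input_height, spec.input_width)
    arrays = []
    for raster in patches:
        raster = np.asarray(raster, dtype=float)
        if raster.ndim == 2:
            raster = raster[:, :, None]
        if raster.shape[:2] != expected or raster.shape[2] != spec.input_channels:
            raise ConfigurationError(
                f"patch of shape {raster.shape} does not match expected "
                f"{expected[0]}x{expected[1]}x{spec.input_channels}"
            )
        arrays.append(raster.transpose(2, 0, 1))
    if not arrays:
        raise ValueError("no patches given")
    return np.stack(arrays)


def predict_patches(regressor: CNNRegressor, patches: Sequence[np.ndarray],
                    batch_size: int = 64) -> np.ndarray:
    """One thickness scalar per patch; batched evaluation, deterministic."""
    batch = as_batch(patches, regressor.spec)
    outputs = [regressor(batch[i:i + batch_size]) for i in range(0, len(batch), batch_size)]
    return np.concatenate(outputs)


def save_checkpoint(regressor: CNNRegressor, path: str | Path) -> None:
    """Write weights (.npz) with the architecture spec as a JSON sidecar."""
    path = Path(path)
    np.savez(path, **regressor.net.parameters())
    spec_path = path.with_suffix(".spec.json")
    spec_path.write_text(json.dumps(regressor.spec.to_dict(), indent=2))


def load_checkpoint(path: str | Path) -> CNNRegressor:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    spec = RegressorSpec.from_dict(json.loads(path.with_suffix(".spec.json").read_text()))
    regressor = build_regressor(spec, seed=0)
    with np.load(path) as data:
        regressor.net.set_parameters({k: data[k] for k in data.files})
    return regressor
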