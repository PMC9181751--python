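"""Model/Results front-end for choroidal-thickness regression.

`ChoroidThicknessModel` bundles labeled training and validation patches
with an architecture spec, in the spirit of the model classes of classical
statistics packages; `fit()` runs the SGD regimen and returns a
`ChoroidThicknessResults` carrying the trained network, the training log
and evaluation helpers (per-patch prediction, B-scan aggregation, metric
reports, `summary()`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cropping import CropConfig
from .dataset import PatchSample, assemble_patches
from .evaluation import EvalReport, aggregate_to_bscan, evaluate_records
from .model import (CNNRegressor, PredictionRecord, RegressorSpec,
                    build_regressor, predict_patches)
from .training import TrainConfig, TrainLog, train

__all__ = ["ChoroidThicknessModel", "ChoroidThicknessResults"]


class ChoroidThicknessModel:
    """Patch-based CNN regression of mean choroidal thickness.

    Parameters
    ----------
    train_patches, val_patches : list of PatchSample
        Labeled patches (raster + mean-thickness label in pixels).
    spec : RegressorSpec, optional
        Architecture; inferred from the first training patch when omitted.
    """

    def __init__(self, train_patches: Sequence[PatchSample],
                 val_patches: Sequence[PatchSample],
                 spec: RegressorSpec | None = None) -> None:
        if not train_patches:
            raise ValueError("train_patches must be non-empty")
        self.train_patches = list(train_patches)
        self.val_patches = list(val_patches)
        if spec is None:
            raster = np.asarray(self.train_patches[0].pixels)
            channels = raster.shape[2] if raster.ndim == 3 else 1
            spec = RegressorSpec(input_height=raster.shape[0],
                                 input_width=raster.shape[1],
                                 input_channels=channels)
        spec.validate()
        self.spec = spec

    @classmethod
    def from_scans(cls, train_scans, val_scans, crop_config: CropConfig,
                   spec: RegressorSpec | None = None) -> "ChoroidThicknessModel":
        """Build directly from (image, annotation) pairs via the cropper."""
        return cls(assemble_patches(train_scans, crop_config),
                   assemble_patches(val_scans, crop_config), spec=spec)

    def fit(self, config: TrainConfig | None = None,
            seed: int = 0) -> "ChoroidThicknessResults":
        """Train the 7-conv regressor under the SGD regimen."""
        config = config or TrainConfig(seed=seed)
        regressor = build_regressor(self.spec, seed=seed)
        regressor, log = train(regressor, self.train_patches, self.val_patches, config)
        return ChoroidThicknessResults(model=self, regressor=regressor,
                                       log=log, config=config)


@dataclass
class ChoroidThicknessResults:
    """A fitted thickness regressor with its training history."""

    model: ChoroidThicknessModel
    regressor: CNNRegressor
    log: TrainLog
    config: TrainConfig

    def predict(self, patches: Sequence[PatchSample] | Sequence[np.ndarray]) -> np.ndarray:
        rasters = [p.pixels if isinstance(p, PatchSample) else p for p in patches]
        return predict_patches(self.regressor, rasters)

    def prediction_records(self, patches: Sequence[PatchSample]) -> list[PredictionRecord]:
        predicted = self.predict(patches)
        return [
            PredictionRecord(level="patch", subject_id=p.subject_id,
                             volume_id=p.volume_id, slice_index=p.slice_index,
                             segment_index=p.geometry.segment_index,
                             predicted=float(f), truth=float(p.label))
            for p, f in zip(patches, predicted)
        ]

    def evaluate(self, test_patches: Sequence[PatchSample],
                 patches_per_bscan: int | None = None) -> tuple[EvalReport, EvalReport]:
        """Patch-level and B-scan-level reports on held-out patches."""
        records = self.prediction_records(test_patches)
        patch_report = evaluate_records(records, level="patch")
        bscan_records = aggregate_to_bscan(records, expected_patches=patches_per_bscan)
        bscan_report = evaluate_records(bscan_records, level="bscan")
        return patch_report, bscan_report

    def summary(self) -> str:
        """Plain-text fit summary in the style of statistical model results."""
        spec = self.regressor.spec
        lines = [
            "Choroidal thickness CNN regression",
            "=" * 50,
            f"input patch:      {spec.input_height} x {spec.input_width} x {spec.input_channels}",
            f"conv channels:    {list(spec.conv_channels)}",
            f"parameters:       {self.regressor.num_parameters():,}",
            f"epochs trained:   {len(self.log.epoch)} (batch size {self.config.batch_size})",
            f"final train MAE:  {self.log.train_loss[-1]:.4f} px",
        ]
        if self.log.val_mae and np.isfinite(self.log.val_mae[-1]):
            lines.append(f"final val MAE:    {self.log.val_mae[-1]:.4f} px")
            lines.append(f"best val MAE:     {np.nanmin(self.log.val_mae):.4f} px "
                         f"(epoch {self.log.epoch[int(np.nanargmin(self.log.val_mae))]})")
        lines.append("=" * 50)
        return "\n".join(lines)
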