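"""Subject-level dataset splits and labeled patch assembly.

Splits are made at the subject level — all scans of one participant stay in
the same split — so the test set never shares an eye with training.  The
default ratios are 60/20/20 train/validation/test; sizes are rounded and
any remainder goes to training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cropping import CropConfig, crop_bscan, extract_pixels, PatchGeometry
from .errors import ConfigurationError
from .groundtruth import patch_label, thickness_profile
from .phantom import BoundaryAnnotation, BScanImage

__all__ = ["SplitSpec", "PatchSample", "split_subjects", "assemble_patches"]


@dataclass(frozen=True)
class SplitSpec:
    """Subject-level split ratios (train, val, test) and shuffle seed."""

    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def validate(self) -> None:
        if len(self.ratios) != 3 or any(r <= 0 for r in self.ratios):
            raise ConfigurationError("ratios must be three positive fractions")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ConfigurationError(f"ratios must sum to 1, got {sum(self.ratios)}")


@dataclass
class PatchSample:
    """A cropped patch raster with its geometry and thickness label."""

    pixels: np.ndarray
    geometry: PatchGeometry
    label: float
    subject_id: str
    volume_id: str
    slice_index: int


def split_subjects(subjects: Sequence[str], spec: SplitSpec) -> tuple[list[str], list[str], list[str]]:
    """Partition subject ids into train/val/test lists.

    Validation and test sizes are ``round(ratio * n)``; the remainder is the
    training set.  Deterministic for a fixed seed; input order irrelevant
    (ids are sorted before shuffling).
    """
    spec.validate()
    subjects = list(subjects)
    if len(set(subjects)) != len(subjects):
        raise ConfigurationError("subject ids must be unique")
    n = len(subjects)
    if n < 3:
        raise ConfigurationError(f"need at least 3 subjects to split, got {n}")
    n_val = round(spec.ratios[1] * n)
    n_test = round(spec.ratios[2] * n)
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ConfigurationError(
            f"split of {n} subjects at {spec.ratios} leaves an empty set"
        )
    order = np.random.default_rng(spec.seed).permutation(sorted(subjects))
    train = list(order[:n_train])
    val = list(order[n_train:n_train + n_val])
    test = list(order[n_train + n_val:])
    return train, val, test


def assemble_patches(scans: Iterable[tuple[BScanImage, BoundaryAnnotation | None]],
                     crop_config: CropConfig) -> list[PatchSample]:
    """Crop every scan into K labeled patches.

    Yields ``K x n_scans`` samples; each label is the mean per-column
    thickness over the patch's columns, recomputed from the annotation.
    """
    samples: list[PatchSample] = []
    for image, annotation in scans:
        if annotation is None:
            raise ConfigurationError(
                f"missing annotation for scan {image.subject_id}/"
                f"{image.volume_id}/{image.slice_index}"
            )
        profile = thickness_profile(annotation)
        for geometry in crop_bscan(image, crop_config):
            samples.append(PatchSample(
                pixels=extract_pixels(image, geometry),
                geometry=geometry,
                label=patch_label(profile, geometry),
                subject_id=image.subject_id,
                volume_id=image.volume_id,
                slice_index=image.slice_index,
            ))
    return samples
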