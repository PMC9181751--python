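"""Patch extraction from B-scans.

A B-scan of height N and width M is divided into K equal-width vertical
segments (patch width m = M/K).  Within each segment an n-row window slides
from the top of the image to the bottom with a fixed stride, and the
placement with the maximal summed intensity wins — on an OCT scan this
lands the window on the bright retina/choroid complex and excludes as much
dark vitreous/background as possible.  Adjacent patches never overlap, so
the K patch labels average exactly to the B-scan label.

Coordinates are 0-based half-open intervals throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import GeometryError
from .phantom import BScanImage

__all__ = [
    "CropConfig",
    "PatchGeometry",
    "candidate_offsets",
    "place_window",
    "crop_bscan",
    "extract_pixels",
]


@dataclass(frozen=True)
class CropConfig:
    """Patch-cropping parameters.

    ``k_segments`` patches of width ``image_width / k_segments`` are cut per
    B-scan; ``patch_height`` rows are kept at the vertical offset chosen by
    the summed-intensity search, which advances by ``vertical_stride`` rows
    per candidate.
    """

    k_segments: int
    patch_height: int
    vertical_stride: int = 10

    def validate(self) -> None:
        if self.k_segments < 1:
            raise GeometryError("k_segments must be >= 1")
        if self.patch_height < 1:
            raise GeometryError("patch_height must be >= 1")
        if self.vertical_stride < 1:
            raise GeometryError("vertical_stride must be >= 1")

    def patch_width(self, image_width: int) -> int:
        """Patch width m = M/K; the division must be exact."""
        if image_width % self.k_segments != 0:
            raise GeometryError(
                f"image width {image_width} is not divisible by k_segments "
                f"{self.k_segments}"
            )
        return image_width // self.k_segments


@dataclass(frozen=True)
class PatchGeometry:
    """Half-open pixel rectangle of one patch inside its B-scan."""

    col_start: int
    col_end: int
    row_start: int
    row_end: int
    segment_index: int

    @property
    def width(self) -> int:
        return self.col_end - self.col_start

    @property
    def height(self) -> int:
        return self.row_end - self.row_start

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PatchGeometry":
        return cls(**{k: int(d[k]) for k in
                      ("col_start", "col_end", "row_start", "row_end", "segment_index")})


def candidate_offsets(image_height: int, patch_height: int, stride: int) -> np.ndarray:
    """Row offsets visited by the vertical slide, top to bottom.

    Multiples of ``stride`` up to ``image_height - patch_height``; the
    terminal offset ``image_height - patch_height`` is appended when the
    stride does not land on it exactly, so the slide truly reaches the
    bottom of the image.
    """
    if patch_height >= image_height:
        raise GeometryError(
            f"patch_height {patch_height} must be smaller than image height {image_height}"
        )
    if stride < 1:
        raise GeometryError("stride must be >= 1")
    last = image_height - patch_height
    offsets = list(range(0, last + 1, stride))
    if offsets[-1] != last:
        offsets.append(last)
    return np.asarray(offsets, dtype=int)


def _intensity_plane(pixels: np.ndarray) -> np.ndarray:
    """Channel-summed 2-D intensity used by the window search."""
    return pixels.sum(axis=2) if pixels.ndim == 3 else pixels


def place_window(image: BScanImage, segment_index: int, config: CropConfig) -> PatchGeometry:
    """Choose the vertical placement of one segment's patch.

    The candidate offset maximising the summed intensity of the n x m
    window wins; ties go to the smallest offset (np.argmax returns the
    first maximum).
    """
    config.validate()
    m = config.patch_width(image.width)
    if not 0 <= segment_index < config.k_segments:
        raise GeometryError(
            f"segment_index {segment_index} outside [0, {config.k_segments})"
        )
    col_start, col_end = segment_index * m, (segment_index + 1) * m
    offsets = candidate_offsets(image.height, config.patch_height, config.vertical_stride)

    plane = _intensity_plane(image.pixels)
    segment = plane[:, col_start:col_end]
    # Direct per-window summation: a prefix-sum shortcut loses exact ties to
    # float rounding, which would break the smallest-offset tie rule.
    window_sums = np.array([segment[o:o + config.patch_height].sum() for o in offsets])
    best = offsets[int(np.argmax(window_sums))]
    return PatchGeometry(col_start=col_start, col_end=col_end,
                         row_start=int(best), row_end=int(best) + config.patch_height,
                         segment_index=segment_index)


def crop_bscan(image: BScanImage, config: CropConfig) -> list[PatchGeometry]:
    """Place all K patches of a B-scan (columns partition [0, width))."""
    config.validate()
    config.patch_width(image.width)  # fail fast on indivisible widths
    return [place_window(image, k, config) for k in range(config.k_segments)]


def extract_pixels(image: BScanImage, geometry: PatchGeometry) -> np.ndarray:
    """Copy the patch raster (no resampling)."""
    if (geometry.row_start < 0 or geometry.col_start < 0
            or geometry.row_end > image.height or geometry.col_end > image.width
            or geometry.row_start >= geometry.row_end
            or geometry.col_start >= geometry.col_end):
        raise GeometryError(
            f"geometry {geometry} does not fit inside a "
            f"{image.height}x{image.width} image"
        )
    return image.pixels[geometry.row_start:geometry.row_end,
                        geometry.col_start:geometry.col_end].copy()
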