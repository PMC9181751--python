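"""Ground-truth choroidal thickness labels from boundary annotations.

Thickness is an axial, per-column quantity: CSI row minus BM row.  A patch's
label is the mean thickness over its columns (vertical placement only
chooses the viewing window and never changes the label), and the B-scan
label is the mean of its patch labels — which, for equal-width disjoint
patches covering the image, equals the full-width column mean exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cropping import PatchGeometry
from .errors import GeometryError
from .phantom import BoundaryAnnotation

__all__ = ["ThicknessProfile", "thickness_profile", "patch_label", "bscan_label"]


@dataclass
class ThicknessProfile:
    """Per-column choroidal thickness in (fractional) pixels."""

    per_column: np.ndarray

    @property
    def width(self) -> int:
        return int(len(self.per_column))

    def mean(self) -> float:
        return float(np.mean(self.per_column))


def thickness_profile(annotation: BoundaryAnnotation) -> ThicknessProfile:
    """Per-column thickness ``csi_rows - bm_rows``; errors name the column."""
    annotation.validate()
    return ThicknessProfile(per_column=np.asarray(annotation.csi_rows, dtype=float)
                            - np.asarray(annotation.bm_rows, dtype=float))


def patch_label(profile: ThicknessProfile, geometry: PatchGeometry) -> float:
    """Mean thickness over the patch's columns."""
    if geometry.col_start < 0 or geometry.col_end > profile.width:
        raise GeometryError(
            f"columns [{geometry.col_start}, {geometry.col_end}) outside "
            f"profile of width {profile.width}"
        )
    if geometry.col_end <= geometry.col_start:
        raise GeometryError("patch has an empty column range")
    return float(np.mean(profile.per_column[geometry.col_start:geometry.col_end]))


def bscan_label(profile: ThicknessProfile, geometries: Sequence[PatchGeometry]) -> float:
    """Mean of the patch labels over a partition of the image width.

    Requires equal-width, disjoint patches covering [0, width) so the value
    is also the full-width column mean.
    """
    if not geometries:
        raise GeometryError("no patch geometries given")
    ordered = sorted(geometries, key=lambda g: g.col_start)
    widths = {g.width for g in ordered}
    if len(widths) != 1:
        raise GeometryError(f"patches have unequal widths: {sorted(widths)}")
    if ordered[0].col_start != 0 or ordered[-1].col_end != profile.width:
        raise GeometryError("patches do not span the full image width")
    for left, right in zip(ordered, ordered[1:]):
        if left.col_end != right.col_start:
            raise GeometryError(
                f"patches do not tile the width: gap/overlap at column {left.col_end}"
            )
    return float(np.mean([patch_label(profile, g) for g in ordered]))
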