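"""Disk formats: 8-bit PNG rasters, boundary CSVs, JSON sidecars, manifests.

Annotations are stored one row per image column as ``col,bm_row,csi_row``
(0-based, fractional rows allowed) with a JSON sidecar holding the subject/
volume/slice identifiers and the generating configuration.  A dataset
manifest is a CSV with one row per scan: subject_id, volume_id,
slice_index, split, image_path, annotation_path.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .phantom import BoundaryAnnotation, BScanImage

__all__ = [
    "save_image", "load_image",
    "save_annotation", "load_annotation",
    "write_manifest", "read_manifest", "load_scans",
]

MANIFEST_COLUMNS = ["subject_id", "volume_id", "slice_index", "split",
                    "image_path", "annotation_path"]


def save_image(image: BScanImage, path: str | Path) -> None:
    """Write the raster as 8-bit PNG/TIFF (intensities scaled from [0,1])."""
    raster = np.round(image.pixels * 255.0).astype(np.uint8)
    iio.imwrite(Path(path), raster)


def load_image(path: str | Path, *, subject_id: str = "unknown",
               volume_id: str = "unknown", slice_index: int = 0) -> BScanImage:
    raster = np.asarray(iio.imread(Path(path)), dtype=float) / 255.0
    image = BScanImage(pixels=raster, subject_id=subject_id,
                       volume_id=volume_id, slice_index=slice_index)
    image.validate()
    return image


def save_annotation(annotation: BoundaryAnnotation, path: str | Path,
                    sidecar: dict | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame({
        "col": np.arange(annotation.cols, dtype=int),
        "bm_row": np.asarray(annotation.bm_rows, dtype=float),
        "csi_row": np.asarray(annotation.csi_rows, dtype=float),
    })
    df.to_csv(path, index=False)
    if sidecar is not None:
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_annotation(path: str | Path) -> BoundaryAnnotation:
    df = pd.read_csv(path)
    df = df.sort_values("col")
    annotation = BoundaryAnnotation(
        bm_rows=df["bm_row"].to_numpy(dtype=float),
        csi_rows=df["csi_row"].to_numpy(dtype=float),
    )
    annotation.validate()
    return annotation


def write_manifest(rows: list[dict], path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    return df


def load_scans(manifest: pd.DataFrame, split: str | None = None,
               root: str | Path = "."):
    """Yield (BScanImage, BoundaryAnnotation) pairs for a manifest split."""
    root = Path(root)
    rows = manifest if split is None else manifest[manifest["split"] == split]
    for _, row in rows.iterrows():
        image = load_image(root / row["image_path"],
                           subject_id=str(row["subject_id"]),
                           volume_id=str(row["volume_id"]),
                           slice_index=int(row["slice_index"]))
        annotation = load_annotation(root / row["annotation_path"])
        yield image, annotation
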