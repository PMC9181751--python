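"""Synthetic OCT-like B-scan phantoms with known choroid boundaries.

Real swept-source OCT volumes of the choroid are rarely shareable, so this
module renders layered phantoms that reproduce the statistical structure the
estimation pipeline relies on: a dark vitreous above a bright Bruch's
membrane (BM) line, a speckled choroidal band of known per-column thickness
down to a smooth choroid-sclera interface (CSI), and a dimmer sclera below.
Because the boundaries are generated first and the raster is rendered from
them, every phantom comes with exact ground truth.

The rendered band is brighter than the background, so the summed-intensity
window search used for patch placement localises the tissue the same way it
does on real scans.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterator

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import AnnotationError, ConfigurationError

__all__ = [
    "PhantomConfig",
    "BScanImage",
    "BoundaryAnnotation",
    "generate_bscan",
    "generate_dataset",
    "dataset_index",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, intensity and noise settings for phantom rendering.

    All lengths are in pixels and all intensities in [0, 1].

    Parameters
    ----------
    height, width : int
        Raster size; the default 596 x 800 matches a common swept-source
        B-scan raster.
    channels : int
        1 for a plain grayscale raster, 3 replicates it into an RGB-shaped
        array (many OCT exports are stored as 3-channel images).
    vitreous_level, tissue_level : float
        Mean intensity of the vitreous/background above BM and of the
        choroidal band.  ``vitreous_level < tissue_level`` is required so
        the band out-scores the background in summed intensity.
    sclera_level : float
        Mean intensity below the CSI; intermediate between vitreous and
        choroid so the choroidal band stays the brightest region.
    bm_depth_range : (float, float)
        Interval from which the mean BM row of a scan is drawn.
    thickness_range : (float, float)
        Interval from which the per-scan mean choroidal thickness is drawn.
    boundary_wavelength_range : (float, float)
        Horizontal wavelengths (pixels) of the low-frequency boundary
        undulation; large values keep boundaries smooth.
    boundary_amplitude : float
        Maximum deviation (pixels) of each boundary from its mean course;
        also bounds how far per-column thickness strays from the scan mean.
    bm_line_gain, bm_line_sigma : float
        Brightness bump and Gaussian half-width of the BM line.
    vessel_contrast : float
        Strength of the dark, blob-like vascular texture inside the band.
    speckle_sigma : float
        Scale of the multiplicative speckle-like noise (0 disables it).
    """

    height: int = 596
    width: int = 800
    channels: int = 3
    vitreous_level: float = 0.06
    tissue_level: float = 0.55
    sclera_level: float = 0.22
    bm_depth_range: tuple[float, float] = (160.0, 260.0)
    thickness_range: tuple[float, float] = (18.0, 146.0)
    boundary_wavelength_range: tuple[float, float] = (120.0, 400.0)
    boundary_amplitude: float = 6.0
    bm_line_gain: float = 0.35
    bm_line_sigma: float = 1.5
    vessel_contrast: float = 0.15
    speckle_sigma: float = 0.12

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the violated invariant."""
        if self.height < 1 or self.width < 1:
            raise ConfigurationError("height and width must be >= 1")
        if self.channels not in (1, 3):
            raise ConfigurationError("channels must be 1 or 3")
        tmin, tmax = self.thickness_range
        if not (0 < tmin <= tmax):
            raise ConfigurationError(
                "thickness_range must satisfy 0 < min <= max, got "
                f"{self.thickness_range}"
            )
        if not (0 <= self.bm_depth_range[0] <= self.bm_depth_range[1]):
            raise ConfigurationError(
                f"bm_depth_range must be ordered and non-negative, got {self.bm_depth_range}"
            )
        deepest = self.bm_depth_range[1] + tmax + 2 * self.boundary_amplitude
        if deepest >= self.height:
            raise ConfigurationError(
                "bm_depth + max thickness + boundary amplitude must stay inside "
                f"the raster: {deepest:.1f} >= height {self.height}"
            )
        if not self.vitreous_level < self.tissue_level:
            raise ConfigurationError(
                "vitreous_level must be strictly below tissue_level "
                "(the window search needs tissue to out-score background)"
            )
        for name in ("vitreous_level", "tissue_level", "sclera_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        wmin, wmax = self.boundary_wavelength_range
        if not (0 < wmin <= wmax):
            raise ConfigurationError("boundary_wavelength_range must be positive and ordered")
        if self.boundary_amplitude < 0 or self.speckle_sigma < 0 or self.vessel_contrast < 0:
            raise ConfigurationError(
                "boundary_amplitude, speckle_sigma and vessel_contrast must be >= 0"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BScanImage:
    """One B-scan raster plus its identifiers.

    ``pixels`` is ``(rows, cols)`` or ``(rows, cols, channels)`` with finite
    intensities in [0, 1].
    """

    pixels: np.ndarray
    subject_id: str = "synthetic"
    volume_id: str = "V000"
    slice_index: int = 0

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    def validate(self) -> None:
        if self.pixels.ndim not in (2, 3):
            raise AnnotationError("pixels must be 2-D or 3-D (rows, cols[, channels])")
        if self.height < 1 or self.width < 1:
            raise AnnotationError("image must have at least one row and one column")
        if not np.all(np.isfinite(self.pixels)):
            raise AnnotationError("image contains non-finite intensities")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise AnnotationError("intensities must lie in [0, 1]")
        if self.slice_index < 0:
            raise AnnotationError("slice_index must be >= 0")


@dataclass
class BoundaryAnnotation:
    """Per-column BM and CSI row coordinates (fractional pixels allowed)."""

    bm_rows: np.ndarray
    csi_rows: np.ndarray

    @property
    def cols(self) -> int:
        return int(len(self.bm_rows))

    def validate(self, image: BScanImage | None = None) -> None:
        if len(self.bm_rows) != len(self.csi_rows):
            raise AnnotationError(
                f"bm_rows and csi_rows lengths differ: {len(self.bm_rows)} vs {len(self.csi_rows)}"
            )
        bad = np.flatnonzero(self.csi_rows < self.bm_rows)
        if bad.size:
            raise AnnotationError(f"csi_row < bm_row at column {int(bad[0])}")
        if np.any(self.bm_rows < 0):
            raise AnnotationError("bm_rows must be >= 0")
        if image is not None:
            if self.cols != image.width:
                raise AnnotationError(
                    f"annotation covers {self.cols} columns but image is {image.width} wide"
                )
            if np.any(self.csi_rows >= image.height):
                raise AnnotationError("csi_rows must lie inside the image")


def _smooth_curve(rng: np.random.Generator, width: int, wavelength_range: tuple[float, float],
                  amplitude: float, n_harmonics: int = 3) -> np.ndarray:
    """Zero-mean low-frequency undulation bounded by ``amplitude``.

    A sum of a few random-phase sinusoids, centred and rescaled so its
    extreme value equals a random fraction of the amplitude budget.
    """
    # Draw the harmonics even when amplitude == 0 so that the RNG stream,
    # and hence everything rendered after the boundaries, does not depend
    # on whether undulation is enabled.
    x = np.arange(width, dtype=float)
    curve = np.zeros(width)
    for _ in range(n_harmonics):
        wavelength = rng.uniform(*wavelength_range)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        weight = rng.uniform(0.3, 1.0)
        curve += weight * np.sin(2.0 * np.pi * x / wavelength + phase)
    scale = rng.uniform(0.5, 1.0)
    if amplitude == 0.0:
        return np.zeros(width)
    curve -= curve.mean()
    peak = np.abs(curve).max()
    if peak > 0:
        curve *= amplitude * scale / peak
    return curve


def generate_bscan(config: PhantomConfig, seed: int, *,
                   subject_id: str = "synthetic", volume_id: str = "V000",
                   slice_index: int = 0) -> tuple[BScanImage, BoundaryAnnotation]:
    """Render one phantom B-scan and its exact boundary annotation.

    Deterministic for a fixed ``(config, seed)``.  The per-scan mean
    thickness is drawn uniformly from ``config.thickness_range`` and the
    per-column thickness equals that mean plus a zero-mean undulation
    bounded by ``config.boundary_amplitude``, so the scan mean lies inside
    the configured range exactly.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    H, W = config.height, config.width

    mean_thickness = rng.uniform(*config.thickness_range)
    bm_mean = rng.uniform(*config.bm_depth_range)
    bm_rows = bm_mean + _smooth_curve(rng, W, config.boundary_wavelength_range,
                                      config.boundary_amplitude)
    thickness = mean_thickness + _smooth_curve(rng, W, config.boundary_wavelength_range,
                                               config.boundary_amplitude)
    csi_rows = bm_rows + thickness

    rows = np.arange(H, dtype=float)[:, None]  # pixel spans [r, r+1)
    bm = bm_rows[None, :]
    csi = csi_rows[None, :]
    # Per-pixel area fractions of the three layers (anti-aliased boundaries).
    above = np.clip(bm - rows, 0.0, 1.0)
    below = np.clip(rows + 1.0 - csi, 0.0, 1.0)
    band = np.clip(1.0 - above - below, 0.0, 1.0)

    img = (above * config.vitreous_level
           + band * config.tissue_level
           + below * config.sclera_level)

    # Bright BM line: Gaussian bump centred on the boundary.
    if config.bm_line_gain > 0:
        img += config.bm_line_gain * np.exp(
            -0.5 * ((rows + 0.5 - bm) / config.bm_line_sigma) ** 2
        )

    # Dark vascular blobs inside the choroidal band (low-pass thresholded noise).
    if config.vessel_contrast > 0:
        tex = gaussian_filter(rng.standard_normal((H, W)), sigma=(3.0, 6.0))
        sd = tex.std()
        if sd > 0:
            tex = np.clip(tex / sd, 0.0, None)  # only darken, never brighten
            img -= config.vessel_contrast * config.tissue_level * band * tex

    if config.speckle_sigma > 0:
        img *= 1.0 + config.speckle_sigma * rng.standard_normal((H, W))

    img = np.clip(img, 0.0, 1.0)
    if config.channels == 3:
        img = np.repeat(img[:, :, None], 3, axis=2)

    image = BScanImage(pixels=img, subject_id=subject_id,
                       volume_id=volume_id, slice_index=slice_index)
    annotation = BoundaryAnnotation(bm_rows=bm_rows, csi_rows=csi_rows)
    image.validate()
    annotation.validate(image)
    return image, annotation


def dataset_index(n_volumes: int, scans_per_volume: int) -> list[tuple[str, str, int]]:
    """Enumerate (subject_id, volume_id, slice_index) for a phantom dataset.

    One subject per volume, mirroring a one-eye-per-participant cohort.
    """
    if n_volumes < 1 or scans_per_volume < 1:
        raise ConfigurationError("n_volumes and scans_per_volume must be >= 1")
    return [
        (f"S{v:03d}", f"V{v:03d}", s)
        for v in range(n_volumes)
        for s in range(scans_per_volume)
    ]


def generate_dataset(config: PhantomConfig, n_volumes: int, scans_per_volume: int,
                     seed: int) -> Iterator[tuple[BScanImage, BoundaryAnnotation]]:
    """Lazily render ``n_volumes x scans_per_volume`` phantom scans.

    All scans of a volume share one subject id; per-scan seeds are derived
    from ``seed`` so the whole collection is reproducible.  A generator is
    returned because a full-size cohort (e.g. 150 volumes of 256 scans)
    does not fit in memory at once.
    """
    config.validate()
    index = dataset_index(n_volumes, scans_per_volume)
    master = np.random.default_rng(seed)
    scan_seeds = master.integers(0, 2**31 - 1, size=len(index))
    for (subject, volume, slice_index), scan_seed in zip(index, scan_seeds):
        yield generate_bscan(config, int(scan_seed), subject_id=subject,
                             volume_id=volume, slice_index=slice_index)
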