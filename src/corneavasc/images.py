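"""Core raster containers and image I/O.

Conventions used throughout the package: arrays are row-major with 0-based
pixel indices; pixel centers sit at integer (row, col) coordinates; affine
transforms act on homogeneous ``(x, y, 1)`` vectors where ``x`` is the column
and ``y`` the row coordinate. Intensities are floats in ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np

MODALITIES = ("OCTA", "ICGA", "SLP")

#: default pixel pitch: a 3 mm field sampled over 304 px (~9.87 um/px)
DEFAULT_PITCH_MM = 3.0 / 304

# ITU-R BT.601 luminance weights, the standard RGB -> grayscale collapse
_LUMA = np.array([0.299, 0.587, 0.114])

MIN_IMAGE_SIDE = 32


def _as_float01(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.dtype == np.uint8:
        return pixels.astype(np.float64) / 255.0
    if pixels.dtype == np.uint16:
        return pixels.astype(np.float64) / 65535.0
    out = pixels.astype(np.float64)
    if out.size and (out.min() < 0.0 or out.max() > 1.0):
        raise ValueError("float images must already be scaled to [0, 1]")
    return out


@dataclass
class RasterImage:
    """A 2-D intensity grid with physical pixel pitch and modality tag."""

    pixels: np.ndarray
    pixel_pitch_mm: float = DEFAULT_PITCH_MM
    modality: str | None = None
    week: int | None = None
    repeat_index: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("RasterImage requires a 2-D intensity grid")
        if min(self.pixels.shape) < MIN_IMAGE_SIDE:
            raise ValueError(
                f"image must be at least {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE} px, "
                f"got {self.pixels.shape}"
            )
        if not np.isfinite(self.pixels).all():
            raise ValueError("image intensities must be finite")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("image intensities must lie in [0, 1]")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be positive")
        if self.modality is not None and self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "RasterImage":
        """Copy of this image with new pixel data, metadata preserved."""
        return RasterImage(
            pixels=pixels,
            pixel_pitch_mm=self.pixel_pitch_mm,
            modality=self.modality,
            week=self.week,
            repeat_index=self.repeat_index,
        )


@dataclass
class BinaryVesselMap:
    """Boolean vessel/background grid: True = vessel (white), False = background.

    ``provenance`` records the parameters that produced the map, complete
    enough to re-run the segmentation bit-identically.
    """

    mask: np.ndarray
    modality: str | None = None
    week: int | None = None
    repeat_index: int | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("BinaryVesselMap requires a 2-D boolean grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def vessel_px(self) -> int:
        return int(self.mask.sum())

    def with_mask(self, mask: np.ndarray, **extra_provenance: Any) -> "BinaryVesselMap":
        prov = dict(self.provenance)
        prov.update(extra_provenance)
        return BinaryVesselMap(
            mask=mask,
            modality=self.modality,
            week=self.week,
            repeat_index=self.repeat_index,
            provenance=prov,
        )


@dataclass
class RegionOfInterest:
    """Pixel mask defining the measurement region A of the density integral."""

    mask: np.ndarray
    pixel_pitch_mm: float = DEFAULT_PITCH_MM

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be positive")
        if not self.mask.any():
            raise ValueError("ROI is empty: no pixels selected")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def area_mm2(self) -> float:
        return self.area_px * self.pixel_pitch_mm**2

    @classmethod
    def full_frame(
        cls, shape: tuple[int, int], pixel_pitch_mm: float = DEFAULT_PITCH_MM
    ) -> "RegionOfInterest":
        return cls(np.ones(shape, dtype=bool), pixel_pitch_mm)


def load_image(
    path: str | Path,
    pixel_pitch_mm: float = DEFAULT_PITCH_MM,
    modality: str | None = None,
    week: int | None = None,
    repeat_index: int | None = None,
) -> RasterImage:
    """Read a PNG/JPEG/TIFF image as a grayscale :class:`RasterImage`.

    RGB images are collapsed by the standard luminance weighting
    (0.299 R + 0.587 G + 0.114 B); intensities are rescaled to [0, 1].
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt / undecodable file
        raise IOError(f"cannot decode image file {path}: {exc}") from exc
    if raw.dtype not in (np.uint8, np.uint16) and not np.issubdtype(
        raw.dtype, np.floating
    ):
        raise ValueError(f"unsupported bit depth {raw.dtype} in {path}")
    pix = _as_float01(raw)
    if pix.ndim == 3:
        if pix.shape[2] == 4:  # drop alpha
            pix = pix[..., :3]
        if pix.shape[2] != 3:
            raise ValueError(f"unsupported channel count {pix.shape[2]} in {path}")
        pix = pix @ _LUMA
    pix = np.clip(pix, 0.0, 1.0)
    return RasterImage(pix, pixel_pitch_mm, modality, week, repeat_index)


def save_image(path: str | Path, img: RasterImage | np.ndarray) -> None:
    """Write an intensity image as 8-bit grayscale PNG/TIFF/JPEG."""
    pix = img.pixels if isinstance(img, RasterImage) else np.asarray(img)
    data = np.clip(np.round(pix * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), data)


def save_mask(path: str | Path, mask: BinaryVesselMap | np.ndarray) -> None:
    """Write a binary map as a 0/255 PNG."""
    arr = mask.mask if isinstance(mask, BinaryVesselMap) else np.asarray(mask, bool)
    iio.imwrite(Path(path), arr.astype(np.uint8) * 255)


def load_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 PNG written by :func:`save_mask` back as a boolean grid."""
    raw = iio.imread(Path(path))
    if raw.ndim == 3:
        raw = raw[..., 0]
    return raw > 127
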