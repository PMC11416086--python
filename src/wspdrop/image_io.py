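"""Reading scanned water-sensitive-paper (WSP) images.

Scans arrive as 8-bit grayscale or RGB rasters.  All downstream analysis
operates on a single 8-bit intensity plane (:class:`GrayImage`); RGB scans are
reduced to one channel.  The default is the *red* channel: WSP is yellow with
blue stains, so red is bright on paper and dark on droplets, which maximizes
contrast.  Physical units are carried via the scan DPI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

DEFAULT_DPI = 96.0
MM_PER_INCH = 25.4

CHANNELS = ("luma", "red", "green", "blue")


@dataclass(frozen=True)
class GrayImage:
    """A 2-D 8-bit intensity raster with scan-resolution metadata.

    Parameters
    ----------
    pixels
        2-D array of gray levels; stored as ``uint8`` (values in [0, 255]).
    dpi
        Scan resolution in dots per inch (> 0).
    """

    pixels: np.ndarray
    dpi: float = DEFAULT_DPI

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if px.size == 0:
            raise ValueError("image has zero size")
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.floating) and not np.allclose(px, np.round(px)):
                raise ValueError("pixel values must be integers in [0, 255]")
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if not self.dpi > 0:
            raise ValueError(f"dpi must be positive, got {self.dpi}")

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)


@dataclass(frozen=True)
class PhysicalScale:
    """Pixel-to-millimetre conversion for a scanned card.

    ``mm_per_px`` is derived as 25.4 / dpi.  Card dimensions default to the
    standard 76 mm x 26 mm sampling card.
    """

    mm_per_px: float
    paper_width_mm: float = 76.0
    paper_height_mm: float = 26.0

    def __post_init__(self) -> None:
        for name in ("mm_per_px", "paper_width_mm", "paper_height_mm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_dpi(cls, dpi: float, **kwargs) -> "PhysicalScale":
        if not dpi > 0:
            raise ValueError(f"dpi must be positive, got {dpi}")
        return cls(mm_per_px=MM_PER_INCH / dpi, **kwargs)

    @property
    def dpi(self) -> float:
        return MM_PER_INCH / self.mm_per_px


def load_image(
    path: str | Path,
    channel: str = "red",
    dpi_override: float | None = None,
) -> GrayImage:
    """Load a PNG/TIFF/JPEG scan as an 8-bit grayscale working image.

    RGB inputs are reduced to a single plane according to ``channel``
    (``luma`` uses Pillow's ITU-R 601-2 conversion).  DPI is taken from file
    metadata when present, else ``dpi_override``, else 96 with a warning.
    """
    path = Path(path)
    if channel not in CHANNELS:
        raise ValueError(f"channel must be one of {CHANNELS}, got {channel!r}")
    try:
        with Image.open(path) as im:
            im.load()
            file_dpi = im.info.get("dpi")
            if im.mode in ("1", "L", "I", "I;16", "F"):
                plane = im.convert("L")
            else:
                rgb = im.convert("RGB")
                if channel == "luma":
                    plane = rgb.convert("L")
                else:
                    plane = rgb.getchannel({"red": "R", "green": "G", "blue": "B"}[channel])
    except FileNotFoundError:
        raise
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc

    pixels = np.asarray(plane, dtype=np.uint8)
    if pixels.size == 0:
        raise ValueError(f"zero-sized image: {path}")

    if file_dpi and file_dpi[0] > 0:
        dpi = float(file_dpi[0])
    elif dpi_override is not None:
        dpi = float(dpi_override)
    else:
        logger.warning("no DPI metadata in %s; assuming %g DPI", path, DEFAULT_DPI)
        dpi = DEFAULT_DPI
    return GrayImage(pixels=pixels, dpi=dpi)


def physical_area_cm2(img: GrayImage, scale: PhysicalScale | None = None) -> float:
    """Physical area of the raster in cm^2 given its pixel pitch."""
    if scale is None:
        scale = PhysicalScale.from_dpi(img.dpi)
    return img.width_px * img.height_px * scale.mm_per_px**2 / 100.0


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit PNG (foreground=255, background=0)."""
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path), format="PNG")


def save_image_png(img: GrayImage, path: str | Path) -> None:
    """Write a grayscale image as PNG, preserving DPI metadata."""
    Image.fromarray(img.pixels, mode="L").save(
        Path(path), format="PNG", dpi=(img.dpi, img.dpi)
    )
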