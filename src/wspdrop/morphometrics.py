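"""Mask repair, droplet extraction, and deposition metrics.

Thresholded stain masks contain bright glare holes inside droplets; a
morphological closing (dilation then erosion) fills holes smaller than the
structuring element before anything is counted.  Connected components of the
repaired mask are the droplets; from them we compute

* coverage  C = stained pixels / total pixels x 100 %
* density   D = droplet count / card area        (droplets per cm^2)

and the sparse / medium / dense grouping by total droplet pixel area (PA):
sparse PA <= 12,000 < medium PA <= 40,000 < dense PA < 90,000.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.morphology import disk as _disk_footprint

from .genetic import GAConfig, ga_otsu_threshold
from .image_io import GrayImage, PhysicalScale, physical_area_cm2
from .thresholding import (
    FIXED_THRESHOLD,
    DropletMask,
    apply_threshold,
    compute_histogram,
    fixed_threshold_segment,
    otsu_threshold,
)

logger = logging.getLogger(__name__)

METHODS = ("fixed", "otsu", "genetic_otsu")
PA_GROUPS = ("sparse", "medium", "dense")

PA_SPARSE_MAX = 12_000
PA_MEDIUM_MAX = 40_000
PA_DENSE_MAX = 90_000  # open upper edge of the printed dense interval


@dataclass(frozen=True)
class StructuringElement:
    """Closing footprint: a disk (4-connected diamond at radius 1) or square."""

    shape: str = "disk"
    radius_px: int = 1

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "square"):
            raise ValueError(f"shape must be 'disk' or 'square', got {self.shape!r}")
        if self.radius_px < 1:
            raise ValueError("radius_px must be >= 1")

    def footprint(self) -> np.ndarray:
        if self.shape == "disk":
            return _disk_footprint(self.radius_px).astype(bool)
        side = 2 * self.radius_px + 1
        return np.ones((side, side), dtype=bool)


@dataclass(frozen=True)
class DropletRecord:
    """One labeled droplet: area, centroid and half-open bounding box."""

    label: int
    area_px: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]


@dataclass(frozen=True)
class DepositionReport:
    """Per-image deposition summary for one segmentation method."""

    method: str
    threshold_used: int
    coverage_pct: float
    droplet_count: int
    density_per_cm2: float
    total_droplet_area_px: int
    pa_group: str

    CSV_HEADER = (
        "file,method,threshold,coverage_pct,droplet_count,"
        "density_per_cm2,total_area_px,pa_group"
    )

    def to_csv_row(self, file: str) -> str:
        return (
            f"{file},{self.method},{self.threshold_used},"
            f"{self.coverage_pct:.6f},{self.droplet_count},"
            f"{self.density_per_cm2:.6f},{self.total_droplet_area_px},{self.pa_group}"
        )


def morphological_close(
    mask: DropletMask, selem: StructuringElement | None = None
) -> DropletMask:
    """Dilation-then-erosion of the droplet foreground.

    The mask is padded with background before closing so the operation is the
    standard embed-in-infinite-background closing: extensive (never removes
    input foreground) and idempotent.
    """
    if selem is None:
        selem = StructuringElement()
    fp = selem.footprint()
    r = selem.radius_px
    padded = np.pad(mask.pixels, r, mode="constant", constant_values=False)
    dilated = ndimage.binary_dilation(padded, structure=fp)
    closed = ndimage.binary_erosion(dilated, structure=fp, border_value=0)
    return DropletMask(pixels=closed[r:-r, r:-r])


def label_droplets(mask: DropletMask, connectivity: int = 8) -> list[DropletRecord]:
    """Connected components of the droplet foreground, one record each."""
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    labeled = measure.label(mask.pixels, connectivity=1 if connectivity == 4 else 2)
    records = [
        DropletRecord(
            label=int(rp.label),
            area_px=int(rp.area),
            centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            bbox=tuple(int(v) for v in rp.bbox),
        )
        for rp in measure.regionprops(labeled)
    ]
    assert sum(r.area_px for r in records) == mask.foreground_px
    return records


def coverage(mask: DropletMask) -> float:
    """Stained fraction of the card, in percent."""
    return 100.0 * mask.foreground_px / mask.pixels.size


def density(records: list[DropletRecord], area_cm2: float) -> float:
    """Droplets per cm^2 of card area."""
    if not area_cm2 > 0:
        raise ValueError(f"area_cm2 must be positive, got {area_cm2}")
    return len(records) / area_cm2


def classify_pa_group(total_droplet_area_px: int) -> str:
    """Sparse / medium / dense grouping by total droplet pixel area."""
    pa = total_droplet_area_px
    if pa < 0:
        raise ValueError(f"total droplet area must be non-negative, got {pa}")
    if pa <= PA_SPARSE_MAX:
        return "sparse"
    if pa <= PA_MEDIUM_MAX:
        return "medium"
    if pa >= PA_DENSE_MAX:
        # outside every printed interval; group as dense rather than abort
        logger.warning(
            "PA=%d is at or above %d, outside the printed dense interval; "
            "classifying as dense",
            pa,
            PA_DENSE_MAX,
        )
    return "dense"


def filter_small_droplets(
    mask: DropletMask, min_droplet_area_px: int, connectivity: int = 8
) -> DropletMask:
    """Remove connected components smaller than ``min_droplet_area_px``."""
    if min_droplet_area_px <= 1:
        return mask
    labeled = measure.label(mask.pixels, connectivity=1 if connectivity == 4 else 2)
    areas = np.bincount(labeled.ravel())
    keep = areas >= min_droplet_area_px
    keep[0] = False
    return DropletMask(pixels=keep[labeled])


def segment(
    img: GrayImage, method: str, ga_config: GAConfig | None = None
) -> tuple[DropletMask, int]:
    """Dispatch to one of the three segmentation methods; returns (mask, T)."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if method == "genetic_otsu":
        if ga_config is None:
            raise ValueError("ga_config is required for method 'genetic_otsu'")
        hist = compute_histogram(img)
        threshold, _ = ga_otsu_threshold(hist, ga_config)
        return apply_threshold(img, threshold), threshold
    if ga_config is not None:
        raise ValueError(f"ga_config must not be given for method {method!r}")
    if method == "fixed":
        return fixed_threshold_segment(img), FIXED_THRESHOLD
    threshold = otsu_threshold(compute_histogram(img))
    return apply_threshold(img, threshold), threshold


def analyze_image(
    img: GrayImage,
    method: str,
    selem: StructuringElement | None = None,
    min_droplet_area_px: int = 2,
    ga_config: GAConfig | None = None,
    scale: PhysicalScale | None = None,
    connectivity: int = 8,
) -> DepositionReport:
    """End-to-end deposition analysis of one scan.

    Segments with the chosen method, repairs glare holes by closing, drops
    components below ``min_droplet_area_px``, then computes coverage, count,
    density and the PA group from the repaired, filtered mask.
    """
    if selem is None:
        selem = StructuringElement()
    if scale is None:
        scale = PhysicalScale.from_dpi(img.dpi)

    mask, threshold = segment(img, method, ga_config)
    closed = morphological_close(mask, selem)
    filtered = filter_small_droplets(closed, min_droplet_area_px, connectivity)
    records = label_droplets(filtered, connectivity)

    area_cm2 = physical_area_cm2(img, scale)
    total_area = filtered.foreground_px
    return DepositionReport(
        method=method,
        threshold_used=threshold,
        coverage_pct=coverage(filtered),
        droplet_count=len(records),
        density_per_cm2=density(records, area_cm2),
        total_droplet_area_px=total_area,
        pa_group=classify_pa_group(total_area),
    )
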