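"""Relative-error benchmarking of segmentation methods against references.

References are "true" coverage and density values per image — manual
measurements for field scans, or exact ground truth for synthetic panels.
Errors are absolute percentage errors per image, averaged per
(method, PA group) cell; significance testing is deliberately left to
downstream statistics tools via the exported CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .genetic import GAConfig
from .image_io import GrayImage, PhysicalScale, physical_area_cm2
from .morphometrics import (
    StructuringElement,
    analyze_image,
    classify_pa_group,
    label_droplets,
)
from .synthetic import GroundTruth

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceRecord:
    """Reference ("true") values for one image."""

    image_id: str
    true_coverage_pct: float
    true_density: float
    pa_group: str

    def __post_init__(self) -> None:
        if self.true_coverage_pct < 0 or self.true_density < 0:
            raise ValueError("reference values must be non-negative")


@dataclass(frozen=True)
class ErrorSummary:
    """Mean relative errors for one (method, PA group) cell."""

    method: str
    pa_group: str
    mean_rel_err_coverage_pct: float
    mean_rel_err_density_pct: float
    n_images: int

    CSV_HEADER = (
        "method,pa_group,mean_rel_err_coverage_pct,mean_rel_err_density_pct,n_images"
    )

    def to_csv_row(self) -> str:
        return (
            f"{self.method},{self.pa_group},{self.mean_rel_err_coverage_pct:.6f},"
            f"{self.mean_rel_err_density_pct:.6f},{self.n_images}"
        )


def relative_error(measured: float, reference: float) -> float:
    """Absolute percentage error of ``measured`` against ``reference``."""
    if not reference > 0:
        raise ValueError(f"reference must be positive, got {reference}")
    return 100.0 * abs(measured - reference) / reference


def reference_from_truth(
    image_id: str,
    truth: GroundTruth,
    img: GrayImage,
    scale: PhysicalScale | None = None,
    connectivity: int = 8,
) -> ReferenceRecord:
    """Build a reference record from synthetic ground truth.

    True density counts connected components of the truth mask (droplets that
    were stamped overlapping merge into one countable stain).
    """
    if scale is None:
        scale = PhysicalScale.from_dpi(img.dpi)
    n_true = len(label_droplets(truth.mask, connectivity))
    area_cm2 = physical_area_cm2(img, scale)
    return ReferenceRecord(
        image_id=image_id,
        true_coverage_pct=truth.coverage_pct,
        true_density=n_true / area_cm2,
        pa_group=classify_pa_group(truth.total_area_px),
    )


def benchmark_methods(
    images: Sequence[tuple[GrayImage, ReferenceRecord]],
    methods: Iterable[str],
    selem: StructuringElement | None = None,
    min_droplet_area_px: int = 2,
    ga_config: GAConfig | None = None,
    scale: PhysicalScale | None = None,
) -> list[ErrorSummary]:
    """Run every method on every image and aggregate relative errors.

    Images whose reference coverage or density is zero cannot define a
    relative error and are skipped with a warning.  Summaries are sorted by
    (method, PA group), so they are invariant to image order.
    """
    if not images:
        raise ValueError("no images to benchmark")
    methods = list(methods)
    if not methods:
        raise ValueError("no methods to benchmark")

    cells: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for img, ref in images:
        if ref.true_coverage_pct <= 0 or ref.true_density <= 0:
            logger.warning(
                "image %s has a zero reference value; excluded from summaries",
                ref.image_id,
            )
            continue
        for method in methods:
            report = analyze_image(
                img,
                method,
                selem=selem,
                min_droplet_area_px=min_droplet_area_px,
                ga_config=ga_config if method == "genetic_otsu" else None,
                scale=scale,
            )
            err_cov = relative_error(report.coverage_pct, ref.true_coverage_pct)
            err_den = relative_error(report.density_per_cm2, ref.true_density)
            cells.setdefault((method, ref.pa_group), []).append((err_cov, err_den))

    summaries = [
        ErrorSummary(
            method=method,
            pa_group=group,
            mean_rel_err_coverage_pct=sum(e[0] for e in errs) / len(errs),
            mean_rel_err_density_pct=sum(e[1] for e in errs) / len(errs),
            n_images=len(errs),
        )
        for (method, group), errs in cells.items()
    ]
    summaries.sort(key=lambda s: (s.method, s.pa_group))
    return summaries
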