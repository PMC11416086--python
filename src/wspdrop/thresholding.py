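"""Histogram-based global thresholding of WSP scans.

Two baselines operate on the 256-bin gray-level histogram:

* a fixed threshold at gray level 153 (the normalized constant 0.60 mapped
  onto [0, 255]), and
* exhaustive Otsu search for the threshold maximizing the between-class
  variance ``sigma2(k) = (mG*P1 - m)^2 / (P1*P2)``.

Droplet stains are dark on light paper, so the droplet foreground is the
class *below* the threshold.  Note this is the inverse of the usual
binarization polarity that maps bright pixels to 255.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import GrayImage

#: 8-bit fixed threshold: round(0.60 * 255).
FIXED_THRESHOLD = round(0.60 * 255)

N_LEVELS = 256


class DegenerateHistogramError(ValueError):
    """Raised when a histogram has fewer than two occupied gray levels."""


@dataclass(frozen=True)
class GrayHistogram:
    """Probability distribution over the 256 gray levels of an 8-bit image."""

    p: np.ndarray
    n_pixels: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=np.float64)
        if p.shape != (N_LEVELS,):
            raise ValueError(f"p must have shape ({N_LEVELS},), got {p.shape}")
        if (p < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")
        if self.n_pixels <= 0:
            raise ValueError("n_pixels must be positive")
        object.__setattr__(self, "p", p)

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "GrayHistogram":
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (N_LEVELS,):
            raise ValueError(f"counts must have shape ({N_LEVELS},)")
        n = int(counts.sum())
        if n <= 0:
            raise ValueError("empty histogram")
        return cls(p=counts / n, n_pixels=n)

    @property
    def n_occupied_levels(self) -> int:
        return int((self.p > 0).sum())

    @property
    def global_mean(self) -> float:
        """mG, the mean gray value of the whole image."""
        return float(np.arange(N_LEVELS) @ self.p)


@dataclass(frozen=True)
class OtsuStatistics:
    """Class statistics of the two-way split at threshold ``k``.

    Class 1 ("background" side of the objective) covers levels [0, k];
    class 2 covers [k+1, 255].
    """

    k: int
    P1: float
    P2: float
    m: float
    mG: float
    sigma2: float


@dataclass(frozen=True)
class DropletMask:
    """Boolean raster aligned to a source image; True marks droplet pixels."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {px.shape}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def foreground_px(self) -> int:
        return int(self.pixels.sum())


def compute_histogram(img: GrayImage) -> GrayHistogram:
    """Gray-level probability histogram p_i of an image."""
    counts = np.bincount(img.pixels.ravel(), minlength=N_LEVELS)
    return GrayHistogram.from_counts(counts)


def otsu_statistics(hist: GrayHistogram, k: int) -> OtsuStatistics:
    """Class probabilities, cumulative mean and between-class variance at k."""
    _check_k(k)
    p = hist.p
    P1 = float(p[: k + 1].sum())
    P2 = float(p[k + 1 :].sum())
    m = float(np.arange(k + 1) @ p[: k + 1])
    mG = hist.global_mean
    if P1 <= 0.0 or P2 <= 0.0:
        sigma2 = 0.0  # degenerate split: no class separation
    else:
        sigma2 = (mG * P1 - m) ** 2 / (P1 * P2)
    return OtsuStatistics(k=int(k), P1=P1, P2=P2, m=m, mG=mG, sigma2=sigma2)


def between_class_variance(hist: GrayHistogram, k: int) -> float:
    """Between-class variance sigma2(k) = (mG*P1 - m)^2 / (P1*P2).

    Returns 0 for degenerate splits (P1 = 0 or P2 = 0), which therefore can
    never win the argmax.
    """
    return otsu_statistics(hist, k).sigma2


def variance_curve(hist: GrayHistogram) -> np.ndarray:
    """sigma2(k) for every k in [0, 255], from cumulative histogram sums."""
    p = hist.p
    P1 = np.cumsum(p)
    m = np.cumsum(np.arange(N_LEVELS) * p)
    mG = m[-1]
    P2 = 1.0 - P1
    num = (mG * P1 - m) ** 2
    den = P1 * P2
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return sigma2


def otsu_threshold(hist: GrayHistogram) -> int:
    """Exhaustive Otsu: the k maximizing between-class variance.

    Ties (the maximum is typically attained on a plateau between separated
    modes) break to the floor of the mean of all maximizing k.
    """
    if hist.n_occupied_levels < 2:
        raise DegenerateHistogramError(
            "degenerate histogram: no threshold separates classes"
        )
    sigma2 = variance_curve(hist)
    best = sigma2.max()
    maximizers = np.flatnonzero(sigma2 >= best - 1e-12 * max(best, 1.0))
    return int(np.floor(maximizers.mean()))


def apply_threshold(img: GrayImage, T: int) -> DropletMask:
    """Binarize: droplet foreground = pixels strictly below T (dark stains)."""
    _check_k(T)
    return DropletMask(pixels=img.pixels < T)


def fixed_threshold_segment(img: GrayImage) -> DropletMask:
    """Segment with the fixed 8-bit threshold 153 (normalized 0.60)."""
    return apply_threshold(img, FIXED_THRESHOLD)


def _check_k(k: int) -> None:
    if not (isinstance(k, (int, np.integer)) and 0 <= int(k) <= 255):
        raise ValueError(f"threshold must be an integer in [0, 255], got {k!r}")
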