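"""Synthetic WSP-like scans with exact ground truth.

Renders a light paper background, stamps dark near-elliptical stains with
log-normally distributed radii, optionally punches small bright "glare"
holes strictly inside stains, and adds clipped Gaussian pixel noise.  Stamps
are rasterized without anti-aliasing so the ground-truth mask, coverage and
count are exact integer quantities.  Truth is defined *before* glare and
noise: a glare hole is still droplet area, an artifact the closing step is
expected to repair.

Everything is driven by one seeded generator, so identical specs produce
bit-identical images.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .image_io import DEFAULT_DPI, GrayImage
from .morphometrics import PA_MEDIUM_MAX, PA_SPARSE_MAX, PA_DENSE_MAX
from .thresholding import DropletMask

logger = logging.getLogger(__name__)

#: 76 mm x 26 mm card at 96 DPI.
DEFAULT_WIDTH_PX = 287
DEFAULT_HEIGHT_PX = 98

MAX_PLACEMENT_ATTEMPTS = 10_000
MAX_PANEL_DRAWS = 1_000


class PlacementError(RuntimeError):
    """Raised when a spec demands more droplet area than fits on the canvas."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic scan.

    ``radius_px_lognormal`` is the (mu, sigma) of log radius; sampled radii
    are truncated to [1, min(width, height)/4].  ``min_center_distance_px``
    of 0 permits adjacency and overlap.
    """

    seed: int
    n_droplets: int
    width_px: int = DEFAULT_WIDTH_PX
    height_px: int = DEFAULT_HEIGHT_PX
    radius_px_lognormal: tuple[float, float] = (math.log(3.0), 0.4)
    ellipticity_range: tuple[float, float] = (1.0, 1.5)
    background_mean: int = 210
    droplet_mean: int = 60
    noise_sigma: float = 5.0
    glare_hole_prob: float = 0.0
    glare_hole_radius_px: int = 1
    min_center_distance_px: float = 0.0
    dpi: float = DEFAULT_DPI

    def __post_init__(self) -> None:
        if self.n_droplets < 0:
            raise ValueError("n_droplets must be non-negative")
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("canvas dimensions must be positive")
        if not 0 <= self.droplet_mean < self.background_mean <= 255:
            raise ValueError(
                "need 0 <= droplet_mean < background_mean <= 255 "
                "(dark stains on light paper)"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not 0.0 <= self.glare_hole_prob <= 1.0:
            raise ValueError("glare_hole_prob must be in [0, 1]")
        if self.glare_hole_radius_px < 1:
            raise ValueError("glare_hole_radius_px must be >= 1")
        if self.min_center_distance_px < 0:
            raise ValueError("min_center_distance_px must be non-negative")
        if self.radius_px_lognormal[1] < 0:
            raise ValueError("radius log-sigma must be non-negative")
        lo, hi = self.ellipticity_range
        if not 1.0 <= lo <= hi:
            raise ValueError("ellipticity_range must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class PlacedDroplet:
    center: tuple[float, float]
    axes: tuple[float, float]
    angle_rad: float
    area_px: int


@dataclass(frozen=True)
class GroundTruth:
    """Exact pre-glare, pre-noise stain footprint and per-droplet geometry."""

    mask: DropletMask
    n_droplets_placed: int
    coverage_pct: float
    per_droplet: tuple[PlacedDroplet, ...] = field(default_factory=tuple)

    @property
    def total_area_px(self) -> int:
        """Total droplet pixel area (PA) of the truth mask."""
        return self.mask.foreground_px


def generate_wsp(spec: SyntheticSpec) -> tuple[GrayImage, GroundTruth]:
    """Render one synthetic scan and its exact ground truth.

    Droplet centers are rejection-sampled to honor ``min_center_distance_px``
    (10,000 attempts per droplet; on exhaustion fewer droplets are placed,
    with a warning, and ``n_droplets_placed`` records the shortfall — unless
    nothing at all could be placed, which raises :class:`PlacementError`).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    mask = np.zeros((h, w), dtype=bool)
    canvas = np.full((h, w), spec.background_mean, dtype=np.float64)

    mu, sigma = spec.radius_px_lognormal
    max_radius = min(w, h) / 4.0
    centers: list[tuple[float, float]] = []
    placed: list[PlacedDroplet] = []
    footprints: list[tuple[np.ndarray, np.ndarray]] = []

    for _ in range(spec.n_droplets):
        r_minor = float(np.clip(rng.lognormal(mu, sigma), 1.0, max_radius))
        ratio = float(rng.uniform(*spec.ellipticity_range))
        r_major = min(r_minor * ratio, max_radius)
        angle = float(rng.uniform(0.0, math.pi))
        margin = r_major + 1.0
        if 2 * margin >= min(w, h):
            margin = 1.0  # canvas too small for a safe margin; clip at edges

        ok = False
        for _attempt in range(MAX_PLACEMENT_ATTEMPTS):
            cy = float(rng.uniform(margin, h - margin)) if h > 2 * margin else h / 2.0
            cx = float(rng.uniform(margin, w - margin)) if w > 2 * margin else w / 2.0
            if spec.min_center_distance_px > 0 and any(
                math.hypot(cy - y0, cx - x0) < spec.min_center_distance_px
                for y0, x0 in centers
            ):
                continue
            ok = True
            break
        if not ok:
            break

        rr, cc = draw_ellipse(cy, cx, r_minor, r_major, rotation=angle, shape=(h, w))
        if rr.size == 0:  # sub-pixel stamp: keep at least the center pixel
            rr = np.array([int(round(cy))])
            cc = np.array([int(round(cx))])
        mask[rr, cc] = True
        centers.append((cy, cx))
        footprints.append((rr, cc))
        placed.append(
            PlacedDroplet(
                center=(cy, cx),
                axes=(r_minor, r_major),
                angle_rad=angle,
                area_px=int(rr.size),
            )
        )

    if spec.n_droplets > 0 and not placed:
        raise PlacementError(
            f"could not place any of {spec.n_droplets} droplets after "
            f"{MAX_PLACEMENT_ATTEMPTS} attempts each (placed 0)"
        )
    if len(placed) < spec.n_droplets:
        logger.warning(
            "placed only %d of %d requested droplets (min_center_distance=%g)",
            len(placed),
            spec.n_droplets,
            spec.min_center_distance_px,
        )

    canvas[mask] = spec.droplet_mean

    truth = GroundTruth(
        mask=DropletMask(pixels=mask.copy()),
        n_droplets_placed=len(placed),
        coverage_pct=100.0 * mask.sum() / mask.size,
        per_droplet=tuple(placed),
    )

    _punch_glare_holes(canvas, mask, footprints, spec, rng)

    if spec.noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sigma, size=canvas.shape)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return GrayImage(pixels=pixels, dpi=spec.dpi), truth


def _punch_glare_holes(
    canvas: np.ndarray,
    mask: np.ndarray,
    footprints: list[tuple[np.ndarray, np.ndarray]],
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> None:
    """Restore small discs to background strictly inside individual stains.

    A hole center is only eligible where the hole disc plus a 1-pixel margin
    lies inside the union stain mask, so holes never touch true background
    and a closing element covering the hole repairs the mask exactly.
    """
    if spec.glare_hole_prob <= 0:
        return
    hr = spec.glare_hole_radius_px
    # hole disc footprint dilated by the 8-neighborhood = required interior zone
    side = 2 * (hr + 1) + 1
    zone = np.zeros((side, side), dtype=bool)
    rr, cc = draw_disk((hr + 1, hr + 1), hr)
    zone[rr, cc] = True
    zone = ndimage.binary_dilation(zone, structure=np.ones((3, 3), dtype=bool))
    eligible = ndimage.binary_erosion(mask, structure=zone, border_value=0)

    for rr, cc in footprints:
        if rng.random() >= spec.glare_hole_prob:
            continue
        inside = eligible[rr, cc]
        if not inside.any():
            continue  # stain too small to host a strictly interior hole
        idx = rng.integers(0, int(inside.sum()))
        hy, hx = rr[inside][idx], cc[inside][idx]
        hrr, hcc = draw_disk((int(hy), int(hx)), hr, shape=canvas.shape)
        canvas[hrr, hcc] = spec.background_mean


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent child seeds from one master seed."""
    return [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(seed).spawn(n)]


#: Per-group rendering presets.  Canvas grows with the group so the printed
#: PA intervals stay reachable at moderate coverage; droplet count ranges are
#: tuned so realized PA lands in-interval on most draws.
_GROUP_PRESETS: dict[str, dict] = {
    "sparse": dict(
        width_px=DEFAULT_WIDTH_PX,
        height_px=DEFAULT_HEIGHT_PX,
        n_range=(8, 16),
        radius_ln=(math.log(4.0), 0.25),
        min_center_distance=30.0,
        pa_interval=(1, PA_SPARSE_MAX),  # inclusive both ends
    ),
    "medium": dict(
        width_px=500,
        height_px=250,
        n_range=(180, 320),
        radius_ln=(math.log(5.0), 0.25),
        min_center_distance=14.0,
        pa_interval=(PA_SPARSE_MAX + 1, PA_MEDIUM_MAX),
    ),
    "dense": dict(
        width_px=700,
        height_px=300,
        n_range=(220, 360),
        radius_ln=(math.log(8.0), 0.25),
        min_center_distance=22.0,
        pa_interval=(PA_MEDIUM_MAX + 1, PA_DENSE_MAX - 1),
    ),
}


def generate_group_panel(
    group: str,
    n_images: int,
    seed: int,
    noise_sigma: float = 5.0,
    glare_hole_prob: float = 0.6,
    glare_hole_radius_px: int = 1,
) -> list[tuple[GrayImage, GroundTruth]]:
    """Generate scans whose realized truth PA lies inside a group's interval.

    Specs are drawn and re-drawn (up to 1,000 tries per image) until the
    realized ground-truth total pixel area falls inside the printed interval
    for ``group``; every returned truth verifiably lies in-interval.
    """
    if group not in _GROUP_PRESETS:
        raise ValueError(f"group must be one of {tuple(_GROUP_PRESETS)}, got {group!r}")
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    preset = _GROUP_PRESETS[group]
    lo, hi = preset["pa_interval"]
    master = np.random.default_rng(seed)
    panel: list[tuple[GrayImage, GroundTruth]] = []

    for _img_idx in range(n_images):
        for _draw in range(MAX_PANEL_DRAWS):
            spec = SyntheticSpec(
                seed=int(master.integers(0, 2**63 - 1)),
                n_droplets=int(master.integers(*preset["n_range"], endpoint=True)),
                width_px=preset["width_px"],
                height_px=preset["height_px"],
                radius_px_lognormal=preset["radius_ln"],
                noise_sigma=noise_sigma,
                glare_hole_prob=glare_hole_prob,
                glare_hole_radius_px=glare_hole_radius_px,
                min_center_distance_px=preset["min_center_distance"],
            )
            img, truth = generate_wsp(spec)
            if lo <= truth.total_area_px <= hi:
                panel.append((img, truth))
                break
        else:
            raise RuntimeError(
                f"could not realize a {group}-group PA in [{lo}, {hi}] "
                f"within {MAX_PANEL_DRAWS} draws"
            )
    return panel
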