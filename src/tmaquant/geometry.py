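"""Core-disk detection and the normalised coordinate frame.

A dearrayed TMA image shows one roughly circular ~1 mm tissue disk on a
light background.  The disk is located with a Hough circle transform on
an edge map; the detected centre and radius define the reference frame
that every downstream stage (cell filtering, stack registration) uses.
Images where no acceptable circle exists (blank positions, destroyed
tissue) are flagged rather than quantified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color, feature, transform

from .stains import rgb_to_od

__all__ = [
    "CoreImage",
    "CircleROI",
    "UndetectedCircleError",
    "detect_core_circle",
    "to_core_frame",
    "from_core_frame",
    "in_core",
]

NO_CIRCLE = "no_circle"
LOW_TISSUE = "low_tissue"
SUSPECTED_FOLD = "suspected_fold"


class UndetectedCircleError(ValueError):
    """Raised when an operation requires a detected core circle."""


@dataclass
class CoreImage:
    """One RGB core image plus identifying metadata.

    Pixel convention used throughout: 0-based indices, x rightward,
    y downward, a point is the centre of its pixel.
    """

    pixels: np.ndarray
    sample_id: str = ""
    core_id: str = ""
    marker: str = ""

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] == 0 or p.shape[1] == 0:
            raise ValueError("CoreImage requires a non-empty H x W x 3 RGB array")
        if p.dtype != np.uint8:
            raise ValueError("CoreImage requires 8-bit pixels")
        self.pixels = p

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class CircleROI:
    """Detected core geometry in image pixel coordinates."""

    cx: float = 0.0
    cy: float = 0.0
    radius: float = 0.0
    detected: bool = False
    quality_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        flags = frozenset(self.quality_flags)
        object.__setattr__(self, "quality_flags", flags)
        if self.detected and self.radius <= 0:
            raise ValueError("a detected circle must have positive radius")
        if not self.detected and NO_CIRCLE not in flags:
            object.__setattr__(self, "quality_flags", flags | {NO_CIRCLE})

    @property
    def centre(self) -> tuple[float, float]:
        return (self.cx, self.cy)


def _edge_map(grey: np.ndarray, sigma: float) -> np.ndarray:
    return feature.canny(grey, sigma=sigma)


def detect_core_circle(
    image: CoreImage,
    radius_fraction_range: tuple[float, float] = (0.55, 0.98),
    accept_score: float = 0.3,
    downscale: int = 4,
    min_tissue_fraction: float = 0.85,
    fold_od_ceiling: float = 2.5,
    fold_fraction: float = 0.10,
    tissue_grey_offset: float = 0.08,
) -> CircleROI:
    """Locate the tissue disk with a two-stage Hough circle transform.

    A coarse pass runs on a ``downscale``-reduced edge map over the full
    radius range (expressed as fractions of min(width, height)/2); the
    winning circle is then refined at full resolution in a narrow radius
    window.  The accumulator is normalised by the circle perimeter, so the
    peak is the fraction of the circle supported by edge pixels; peaks
    below ``accept_score`` count as "no circle".

    Quality flags on a detected circle:

    * ``low_tissue`` - tissue pixels cover less than
      ``min_tissue_fraction`` of the disk, as with large gaps or
      mostly-empty cores.  A pixel counts as tissue when its grey level
      sits at least ``tissue_grey_offset`` below the background level
      (median grey outside the disk); this stays stable where a global
      two-class cut can lock onto the nuclei/tissue split instead of the
      tissue/background split.
    * ``suspected_fold`` - more than ``fold_fraction`` of disk pixels have
      a summed RGB optical density above ``fold_od_ceiling``, the
      signature of folded, doubly-absorbing tissue.
    """
    grey = color.rgb2gray(image.pixels)
    half_min = min(image.width, image.height) / 2.0
    lo = max(3.0, radius_fraction_range[0] * half_min)
    hi = radius_fraction_range[1] * half_min

    small = transform.rescale(grey, 1.0 / downscale, anti_aliasing=True)
    edges_small = _edge_map(small, sigma=1.5)
    radii_small = np.arange(
        max(2, int(np.floor(lo / downscale))), int(np.ceil(hi / downscale)) + 1
    )
    if not edges_small.any():
        return CircleROI(detected=False, quality_flags=frozenset({NO_CIRCLE}))
    accum = transform.hough_circle(edges_small, radii_small)
    best = np.unravel_index(np.argmax(accum), accum.shape)
    score = float(accum[best])
    if score < accept_score:
        return CircleROI(detected=False, quality_flags=frozenset({NO_CIRCLE}))
    r0 = radii_small[best[0]] * downscale
    cy0, cx0 = best[1] * downscale, best[2] * downscale

    # full-resolution refinement in a narrow radius window; only edges in an
    # annulus around the coarse circle can vote, which keeps the refinement
    # cost proportional to the rim length rather than the tissue content
    edges = _edge_map(grey, sigma=2.0)
    yy, xx = np.ogrid[: image.height, : image.width]
    rim_dist = np.hypot(xx - cx0, yy - cy0)
    edges &= np.abs(rim_dist - r0) <= (2 * downscale + 4)
    radii = np.arange(max(3, r0 - downscale - 2), r0 + downscale + 3)
    accum = transform.hough_circle(edges, radii)
    # restrict the centre search to the coarse neighbourhood
    win = 2 * downscale
    ys = slice(max(0, cy0 - win), min(image.height, cy0 + win + 1))
    xs = slice(max(0, cx0 - win), min(image.width, cx0 + win + 1))
    sub = accum[:, ys, xs]
    b = np.unravel_index(np.argmax(sub), sub.shape)
    score = float(sub[b])
    if score < accept_score:
        return CircleROI(detected=False, quality_flags=frozenset({NO_CIRCLE}))
    radius = float(radii[b[0]])
    cy = float(b[1] + ys.start)
    cx = float(b[2] + xs.start)

    flags = set()
    yy, xx = np.ogrid[: image.height, : image.width]
    disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    if disk.any():
        outside = ~disk
        background = float(np.median(grey[outside])) if outside.any() else float(grey.max())
        tissue_fraction = float(np.mean(grey[disk] < background - tissue_grey_offset))
        if tissue_fraction < min_tissue_fraction:
            flags.add(LOW_TISSUE)
        total_od = rgb_to_od(image.pixels).sum(axis=2)
        if float(np.mean(total_od[disk] > fold_od_ceiling)) > fold_fraction:
            flags.add(SUSPECTED_FOLD)
    return CircleROI(cx=cx, cy=cy, radius=radius, detected=True, quality_flags=frozenset(flags))


def _require_detected(circle: CircleROI):
    if not circle.detected:
        raise UndetectedCircleError(
            "core circle was not detected; skip this core (no_circle flag set)"
        )


def to_core_frame(points, circle: CircleROI, reference_radius: float) -> np.ndarray:
    """Map image-frame points into the shared core frame.

    Translates so the circle centre becomes the origin, then scales by
    ``reference_radius / circle.radius``; exactly inverted by
    :func:`from_core_frame`.
    """
    _require_detected(circle)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    scale = reference_radius / circle.radius
    return (pts - np.array([circle.cx, circle.cy])) * scale


def from_core_frame(points, circle: CircleROI, reference_radius: float) -> np.ndarray:
    """Inverse of :func:`to_core_frame`."""
    _require_detected(circle)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    scale = circle.radius / reference_radius
    return pts * scale + np.array([circle.cx, circle.cy])


def in_core(point, circle: CircleROI, margin_fraction: float = 0.05) -> bool:
    """True iff the point lies within (1 + margin) x radius of the centre.

    The margin absorbs circle-detection error so cells on the detected rim
    are not dropped spuriously.
    """
    _require_detected(circle)
    x, y = float(point[0]), float(point[1])
    return bool(np.hypot(x - circle.cx, y - circle.cy) <= circle.radius * (1.0 + margin_fraction))
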