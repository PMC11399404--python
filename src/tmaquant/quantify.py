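"""Nuclei detection and the positive-cell calling rule.

Cells are detected in the hematoxylin concentration channel by a
pluggable segmentation backend and then classified against the
thresholded DAB layer: every cell is placed at the centre of a
``grid_size`` x ``grid_size`` pixel window and called marker-positive
when strictly more than ``fraction_cutoff`` (default 10%) of the window
pixels are DAB-positive.  Counting a core is fully deterministic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
from skimage import feature

from .geometry import CircleROI, CoreImage, detect_core_circle, in_core
from .stains import (
    BinaryMask,
    OpticalDensityChannels,
    StainMatrix,
    deconvolve,
    rgb_to_od,
    triangle_threshold,
)
from .synthetic import GroundTruth, load_ground_truth

__all__ = [
    "CellObject",
    "CoreResult",
    "QuantifyConfig",
    "SegmentationBackend",
    "LogBlobBackend",
    "GroundTruthBackend",
    "register_backend",
    "get_backend",
    "segment_nuclei",
    "call_positive",
    "quantify_core",
    "cutoff_sensitivity",
]


@dataclass
class CellObject:
    """One segmented nucleus and (once called) its positivity."""

    x: float
    y: float
    radius: float
    marker: str = ""
    positive: bool | None = None
    positive_pixel_fraction: float | None = None

    @property
    def area(self) -> float:
        return float(np.pi * self.radius**2)


class SegmentationBackend(Protocol):
    """Contract every nuclei-segmentation backend must satisfy.

    ``segment`` must be deterministic: the same image, channels and
    parameters always return the same ordered cell list.
    """

    name: str

    def segment(
        self,
        image: CoreImage,
        channels: OpticalDensityChannels,
        circle: CircleROI | None = None,
    ) -> list[CellObject]: ...


@dataclass
class LogBlobBackend:
    """Classical detector: multi-scale Laplacian-of-Gaussian blob detection.

    Runs on the hematoxylin concentration channel.  Scales span the
    configured nucleus radius range, candidate blobs below ``min_od``
    (scale-normalised LoG response) are dropped, and overlapping maxima
    are suppressed via the blob overlap criterion.  Blobs closer than
    ``edge_margin`` pixels to the detected rim are discarded: the disk
    boundary is a step edge whose LoG ridge would otherwise masquerade as
    a line of nuclei.
    """

    name: str = "log"
    min_radius: float = 5.0
    max_radius: float = 10.0
    min_od: float = 0.15
    num_sigma: int = 8
    overlap: float = 0.5
    edge_margin: float = 12.0

    def segment(self, image, channels, circle=None):
        hema = np.ascontiguousarray(channels.hematoxylin)
        baseline = float(np.median(hema))
        blobs = feature.blob_log(
            hema - baseline,
            min_sigma=self.min_radius / np.sqrt(2),
            max_sigma=self.max_radius / np.sqrt(2),
            num_sigma=self.num_sigma,
            threshold=self.min_od,
            overlap=self.overlap,
        )
        cells = []
        for y, x, sigma in blobs:
            if circle is not None and circle.detected:
                rim = circle.radius - np.hypot(x - circle.cx, y - circle.cy)
                if rim < self.edge_margin:
                    continue
            cells.append(CellObject(x=float(x), y=float(y), radius=float(sigma * np.sqrt(2)), marker=image.marker))
        cells.sort(key=lambda c: (c.y, c.x))
        return cells


@dataclass
class GroundTruthBackend:
    """Test-oracle backend: returns the synthetic ground-truth cells verbatim."""

    ground_truth: GroundTruth | None = None
    sidecar: str | None = None
    name: str = "ground_truth"

    def segment(self, image, channels, circle=None):
        gt = self.ground_truth
        if gt is None:
            if self.sidecar is None:
                raise FileNotFoundError(
                    "ground-truth injection backend needs a GroundTruth object or a sidecar path"
                )
            gt = load_ground_truth(self.sidecar)
        return [
            CellObject(x=c.x, y=c.y, radius=c.radius, marker=image.marker) for c in gt.cells
        ]


_BACKENDS: dict[str, type] = {"log": LogBlobBackend, "ground_truth": GroundTruthBackend}


def register_backend(name: str, factory) -> None:
    """Register a segmentation backend factory under ``name``.

    The adapter point for external pretrained models (e.g. star-convex
    polygon segmenters): any callable returning an object with a
    deterministic ``segment(image, channels, circle)`` method qualifies.
    """
    _BACKENDS[name] = factory


def get_backend(name: str, **params):
    try:
        factory = _BACKENDS[name]
    except KeyError:
        raise ValueError(
            f"unknown segmentation backend {name!r}; registered: {sorted(_BACKENDS)}"
        ) from None
    return factory(**params)


def segment_nuclei(
    image: CoreImage,
    channels: OpticalDensityChannels,
    backend: SegmentationBackend,
    circle: CircleROI | None = None,
) -> list[CellObject]:
    """Run a segmentation backend on the hematoxylin layer."""
    return backend.segment(image, channels, circle)


def call_positive(
    cell: CellObject,
    dab_mask: BinaryMask,
    grid_size: int = 16,
    fraction_cutoff: float = 0.10,
) -> CellObject:
    """Classify one cell against the thresholded DAB layer.

    A ``grid_size`` x ``grid_size`` window is centred on the cell's
    centroid rounded half-up to integer pixels; the window spans
    [c - g/2, c + g/2) on each axis and is clipped to the image, with the
    clipped pixel count as denominator.  The cell is positive iff the
    DAB-positive fraction strictly exceeds ``fraction_cutoff``.
    """
    mask = dab_mask.mask
    h, w = mask.shape
    half = grid_size // 2
    cx = int(np.floor(cell.x + 0.5))
    cy = int(np.floor(cell.y + 0.5))
    x0, x1 = max(0, cx - half), min(w, cx - half + grid_size)
    y0, y1 = max(0, cy - half), min(h, cy - half + grid_size)
    n_window = (x1 - x0) * (y1 - y0)
    if n_window <= 0:
        fraction = 0.0
    else:
        fraction = float(np.count_nonzero(mask[y0:y1, x0:x1])) / n_window
    return dataclasses.replace(
        cell, positive=fraction > fraction_cutoff, positive_pixel_fraction=fraction
    )


@dataclass
class QuantifyConfig:
    """Everything :func:`quantify_core` needs besides the image."""

    backend: SegmentationBackend = field(default_factory=LogBlobBackend)
    stain_matrix: StainMatrix = field(default_factory=StainMatrix)
    radius_fraction_range: tuple[float, float] = (0.55, 0.98)
    grid_size: int = 16
    fraction_cutoff: float = 0.10
    margin_fraction: float = 0.05
    n_bins: int = 256
    restrict_histogram_to_circle: bool = True
    exclude_outside_circle: bool = True
    # below this 99.99th-percentile DAB OD the layer is treated as signal-free:
    # thresholding a pure-noise channel would otherwise hallucinate positives
    min_dab_signal: float = 0.15


@dataclass
class CoreResult:
    """Per-core quantification record."""

    sample_id: str = ""
    core_id: str = ""
    marker: str = ""
    n_total_cells: int | None = None
    n_positive_cells: int | None = None
    dab_threshold: float | None = None
    circle: CircleROI = field(default_factory=CircleROI)
    flags: frozenset[str] = field(default_factory=frozenset)
    cells: list[CellObject] = field(default_factory=list)

    def __post_init__(self):
        self.flags = frozenset(self.flags)
        if "no_circle" in self.flags:
            if self.n_total_cells is not None or self.n_positive_cells is not None:
                raise ValueError("a no_circle core must not carry counts")
        elif self.n_total_cells is not None and self.n_positive_cells is not None:
            if not 0 <= self.n_positive_cells <= self.n_total_cells:
                raise ValueError("0 <= n_positive <= n_total violated")


def quantify_core(image: CoreImage, config: QuantifyConfig | None = None) -> CoreResult:
    """Full per-core pipeline: circle -> deconvolution -> threshold -> cells -> calls."""
    config = config or QuantifyConfig()
    circle = detect_core_circle(image, radius_fraction_range=config.radius_fraction_range)
    if not circle.detected:
        return CoreResult(
            sample_id=image.sample_id, core_id=image.core_id, marker=image.marker,
            circle=circle, flags=circle.quality_flags,
        )
    od = rgb_to_od(image.pixels)
    channels = deconvolve(od, config.stain_matrix)

    hist_mask = None
    if config.restrict_histogram_to_circle:
        yy, xx = np.ogrid[: image.height, : image.width]
        hist_mask = (xx - circle.cx) ** 2 + (yy - circle.cy) ** 2 <= circle.radius**2
    dab_values = channels.dab[hist_mask] if hist_mask is not None else channels.dab.ravel()
    signal_level = float(np.quantile(dab_values, 0.9999)) if dab_values.size else 0.0
    if signal_level < config.min_dab_signal:
        dab_mask = BinaryMask(
            mask=np.zeros(channels.dab.shape, dtype=bool),
            threshold_value=signal_level,
            method="triangle-no-signal",
        )
    else:
        dab_mask = triangle_threshold(channels.dab, n_bins=config.n_bins, histogram_mask=hist_mask)

    cells = segment_nuclei(image, channels, config.backend, circle)
    if config.exclude_outside_circle:
        cells = [c for c in cells if in_core((c.x, c.y), circle, config.margin_fraction)]
    cells = [
        call_positive(c, dab_mask, grid_size=config.grid_size, fraction_cutoff=config.fraction_cutoff)
        for c in cells
    ]
    return CoreResult(
        sample_id=image.sample_id, core_id=image.core_id, marker=image.marker,
        n_total_cells=len(cells), n_positive_cells=sum(bool(c.positive) for c in cells),
        dab_threshold=dab_mask.threshold_value, circle=circle,
        flags=circle.quality_flags, cells=cells,
    )


def cutoff_sensitivity(result: CoreResult, cutoffs=(0.05, 0.10, 0.15, 0.20, 0.25)):
    """Positive-cell counts over a grid of calling cutoffs.

    Re-uses the stored per-cell positive-pixel fractions, so no
    re-segmentation or re-thresholding is involved; by construction the
    count is non-increasing in the cutoff.
    """
    import pandas as pd

    if result.n_total_cells is None:
        raise ValueError("cannot vary the cutoff on a flagged core without counts")
    fractions = np.array([c.positive_pixel_fraction for c in result.cells], dtype=float)
    rows = [
        {"fraction_cutoff": float(c), "n_positive": int(np.sum(fractions > c))} for c in cutoffs
    ]
    return pd.DataFrame(rows)
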