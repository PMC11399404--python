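"""Stain separation for hematoxylin/DAB chromogenic images.

Chromogenic IHC obeys the Beer-Lambert law: each stain attenuates light
multiplicatively, so stain contributions add linearly in optical density
(OD = -log10 of transmitted/incident light per RGB channel).  Given the
per-stain OD direction vectors, per-pixel stain concentrations are
recovered by inverting the 3x3 stain matrix ("colour deconvolution").
The DAB concentration map is then binarised with triangle thresholding,
computed image-by-image so that staining intensity differences between
cores and between TMA blocks do not share a single global cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StainMatrix",
    "OpticalDensityChannels",
    "BinaryMask",
    "rgb_to_od",
    "od_to_rgb",
    "deconvolve",
    "triangle_threshold",
    "triangle_bin_bruteforce",
]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("stain vector must be non-zero")
    return v / n


@dataclass(frozen=True)
class StainMatrix:
    """OD direction vectors of the two stains plus the residual axis.

    Columns of :attr:`matrix` are the unit OD vectors, so a pixel's OD
    3-vector is ``matrix @ concentrations``.  The default is the standard
    H-DAB matrix of Ruifrok & Johnston with the residual taken as the
    normalised cross product of the two stain vectors.
    """

    hematoxylin: tuple[float, float, float] = (0.650, 0.704, 0.286)
    dab: tuple[float, float, float] = (0.269, 0.568, 0.778)
    residual: tuple[float, float, float] | None = None

    def __post_init__(self):
        h = _unit(self.hematoxylin)
        d = _unit(self.dab)
        if self.residual is None:
            r = np.cross(h, d)
            if np.linalg.norm(r) < 1e-12:
                raise ValueError("hematoxylin and DAB vectors are collinear")
            r = _unit(r)
        else:
            r = _unit(self.residual)
        object.__setattr__(self, "hematoxylin", tuple(h))
        object.__setattr__(self, "dab", tuple(d))
        object.__setattr__(self, "residual", tuple(r))
        m = np.column_stack([h, d, r])
        if abs(np.linalg.det(m)) < 1e-8:
            raise ValueError("stain matrix is singular")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 matrix with stain OD vectors as columns (H, DAB, residual)."""
        return np.column_stack([self.hematoxylin, self.dab, self.residual])

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


@dataclass
class OpticalDensityChannels:
    """Per-stain concentration maps from colour deconvolution (OD units)."""

    hematoxylin: np.ndarray
    dab: np.ndarray
    residual: np.ndarray

    def __post_init__(self):
        if not (self.hematoxylin.shape == self.dab.shape == self.residual.shape):
            raise ValueError("channel shapes differ")


@dataclass
class BinaryMask:
    """Boolean DAB-positivity map with the threshold that produced it."""

    mask: np.ndarray
    threshold_value: float
    method: str = "triangle"

    @property
    def shape(self):
        return self.mask.shape


def rgb_to_od(pixels: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB array to per-channel optical density.

    OD_c = -log10((I_c + 1) / 256); the +1 guard keeps black pixels finite
    (OD ~ 2.408) and maps pure white to exactly 0.
    """
    pixels = np.asarray(pixels)
    if pixels.dtype != np.uint8:
        if np.any(pixels < 0) or np.any(pixels > 255):
            raise ValueError("expected 8-bit intensities in [0, 255]")
    return -np.log10((pixels.astype(np.float64) + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Invert :func:`rgb_to_od`: I_c = round(256 * 10**(-OD_c)) - 1.

    Exact inverse of the OD transform up to 8-bit quantisation; OD 0 maps
    to 255 so an unstained background renders as pure white.
    """
    intensity = np.rint(256.0 * np.power(10.0, -np.asarray(od, dtype=float))) - 1.0
    return np.clip(intensity, 0, 255).astype(np.uint8)


def deconvolve(od_image: np.ndarray, matrix: StainMatrix | None = None) -> OpticalDensityChannels:
    """Unmix a per-pixel OD image (H x W x 3) into stain concentration maps.

    Solves ``od = M @ conc`` per pixel with the matrix inverse; negative
    concentrations (noise outside the stain simplex) are clipped to zero.
    """
    matrix = matrix or StainMatrix()
    od_image = np.asarray(od_image, dtype=float)
    if od_image.ndim != 3 or od_image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 OD image")
    conc = od_image @ matrix.inverse.T
    conc = np.clip(conc, 0.0, None)
    return OpticalDensityChannels(
        hematoxylin=conc[..., 0], dab=conc[..., 1], residual=conc[..., 2]
    )


def _triangle_bin(hist: np.ndarray) -> int | None:
    """Index of the triangle-threshold bin, or None if degenerate.

    Geometry: draw a line from the histogram peak to the furthest
    non-empty bin on the longer-tailed side (ties to the high side) in
    coordinates normalised so that the peak-to-tail span is 1 on both
    axes, and pick the bin whose (index, count) point is furthest from
    that line.  Ties break to the bin nearest the peak.
    """
    nonempty = np.flatnonzero(hist)
    if nonempty.size <= 1:
        return None
    peak = int(np.argmax(hist))
    left, right = int(nonempty[0]), int(nonempty[-1])
    tail = right if (right - peak) >= (peak - left) else left
    if tail == peak:
        return None
    idx = np.arange(peak, tail + (1 if tail > peak else -1), 1 if tail > peak else -1)
    x = (idx - peak) / (tail - peak)
    y = hist[idx] / hist[peak]
    # line through (0, 1) and (1, y_tail): y = 1 + (y_tail - 1) * x
    y_tail = hist[tail] / hist[peak]
    dist = np.abs((y_tail - 1.0) * x - y + 1.0) / np.hypot(y_tail - 1.0, 1.0)
    return int(idx[int(np.argmax(dist))])


def triangle_bin_bruteforce(hist: np.ndarray) -> int | None:
    """Reference construction of the triangle bin by explicit per-bin geometry.

    Loops over every candidate bin and computes the point-to-line distance
    from first principles; used as the oracle against :func:`_triangle_bin`.
    """
    hist = np.asarray(hist, dtype=float)
    nonempty = [i for i, h in enumerate(hist) if h > 0]
    if len(nonempty) <= 1:
        return None
    peak = max(range(len(hist)), key=lambda i: (hist[i], -i))
    left, right = nonempty[0], nonempty[-1]
    tail = right if (right - peak) >= (peak - left) else left
    if tail == peak:
        return None
    # normalised coordinates: peak -> (0, 1), tail -> (1, hist[tail]/hist[peak])
    x1, y1 = 0.0, 1.0
    x2, y2 = 1.0, hist[tail] / hist[peak]
    best, best_d = None, -1.0
    step = 1 if tail > peak else -1
    for i in range(peak, tail + step, step):
        px = (i - peak) / (tail - peak)
        py = hist[i] / hist[peak]
        d = abs((y2 - y1) * px - (x2 - x1) * py + x2 * y1 - y2 * x1) / (
            ((y2 - y1) ** 2 + (x2 - x1) ** 2) ** 0.5
        )
        if d > best_d + 1e-12:
            best, best_d = i, d
    return best


def triangle_threshold(
    channel: np.ndarray,
    n_bins: int = 256,
    histogram_mask: np.ndarray | None = None,
) -> BinaryMask:
    """Binarise an OD channel at the triangle threshold of its histogram.

    The histogram spans [0, max] of the (optionally masked) channel with
    ``n_bins`` equal bins.  The threshold is the upper edge of the selected
    bin and the mask is ``channel > threshold`` over the full array, so
    scaling the channel by k > 0 scales the threshold by k and leaves the
    mask unchanged.

    Parameters
    ----------
    channel : 2-D float array of non-negative OD values.
    n_bins : number of histogram bins.
    histogram_mask : optional boolean array restricting which pixels feed
        the histogram (e.g. the detected core disk); the output mask still
        covers the whole channel.
    """
    channel = np.asarray(channel, dtype=float)
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite values")
    values = channel[histogram_mask] if histogram_mask is not None else channel.ravel()
    if values.size == 0:
        raise ValueError("no pixels available for the histogram")
    vmax = float(values.max())
    if vmax <= 0 or np.all(values == values.flat[0]):
        warnings.warn("constant channel: triangle threshold undefined, empty mask")
        return BinaryMask(
            mask=np.zeros(channel.shape, dtype=bool),
            threshold_value=float(values.flat[0]),
            method="triangle-degenerate",
        )
    hist, edges = np.histogram(values, bins=n_bins, range=(0.0, vmax))
    bin_idx = _triangle_bin(hist)
    if bin_idx is None:
        warnings.warn("single-bin histogram: triangle threshold undefined, empty mask")
        return BinaryMask(
            mask=np.zeros(channel.shape, dtype=bool),
            threshold_value=vmax,
            method="triangle-degenerate",
        )
    threshold = float(edges[bin_idx + 1])
    return BinaryMask(mask=channel > threshold, threshold_value=threshold)
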