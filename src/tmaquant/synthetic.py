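"""Seeded generator of TMA-core-like images with exact ground truth.

Emulates a dearrayed ~1 mm core imaged at 20X: a circular tissue disk on
a light background, nuclei as darker hematoxylin-toned elliptical blobs,
a controlled subset carrying brown DAB chromogen, plus blank / folded /
gapped artifact variants.  Images are composed in optical-density space
(per-pixel OD = hematoxylin concentration x H vector + DAB concentration
x DAB vector) and converted to RGB by the Beer-Lambert relation, so the
stain-processing deconvolution is an exact inverse up to 8-bit
quantisation and the recorded cell layout is an exact counting oracle.

The generator does not attempt photorealistic histology: nuclei are
smooth ellipses without chromatin texture, the disk is perfectly
circular, and there is no staining-batch variation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import draw

from .geometry import CircleROI, CoreImage
from .stains import StainMatrix, od_to_rgb

__all__ = [
    "SyntheticCoreSpec",
    "GroundTruthCell",
    "GroundTruth",
    "render_core",
    "render_artifact_core",
    "render_marker_stack",
    "compose_core_od",
    "save_ground_truth",
    "load_ground_truth",
    "WELL_SEPARATED_SPACING",
    "OVERLAPPING_SPACING",
]

WELL_SEPARATED_SPACING = 2.2  # x max nucleus radius; isolates counting from segmentation
OVERLAPPING_SPACING = 1.1  # deliberately fused nuclei for segmentation stress tests

ARTIFACTS = ("none", "blank", "fold", "gap")


@dataclass(frozen=True)
class SyntheticCoreSpec:
    """Parameters of one synthetic core; same spec + seed => identical output.

    OD amplitudes are per-nucleus stain concentrations in optical-density
    units; defaults keep the maximum per-channel OD low enough that 8-bit
    quantisation perturbs deconvolved concentrations by well under
    0.02 OD.
    """

    image_size: int = 1024
    core_centre: tuple[int, int] | None = None
    core_radius: int = 400
    n_cells: int = 200
    positive_fraction: float = 0.3
    nucleus_radius_range: tuple[float, float] = (6.0, 9.0)
    hematoxylin_od_range: tuple[float, float] = (0.35, 0.75)
    dab_od_range: tuple[float, float] = (0.25, 0.65)
    tissue_wash_od: float = 0.15
    background_intensity: int = 245
    noise_sigma: float = 2.0
    min_spacing_factor: float = WELL_SEPARATED_SPACING
    artifact: str = "none"
    gap_fraction: float = 0.25
    fold_fraction: float = 0.35
    fold_od: float = 1.9
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.core_radius >= self.image_size / 2:
            raise ValueError("core_radius must be < image_size / 2")
        if self.artifact not in ARTIFACTS:
            raise ValueError(f"artifact must be one of {ARTIFACTS}")
        if self.core_centre is None:
            c = self.image_size // 2
            object.__setattr__(self, "core_centre", (c, c))

    @property
    def background_od(self) -> float:
        return -float(np.log10((self.background_intensity + 1) / 256.0))


@dataclass(frozen=True)
class GroundTruthCell:
    x: float
    y: float
    radius: float
    is_positive: bool


@dataclass
class GroundTruth:
    """Exact layout and labels of a rendered core; the counting oracle."""

    circle: CircleROI
    cells: list[GroundTruthCell]
    seed: int = 0

    def __post_init__(self):
        r = self.circle.radius
        for c in self.cells:
            if np.hypot(c.x - self.circle.cx, c.y - self.circle.cy) > r:
                raise ValueError("ground-truth cell centroid outside the core circle")

    @property
    def n_total(self) -> int:
        return len(self.cells)

    @property
    def n_positive(self) -> int:
        return sum(c.is_positive for c in self.cells)


class PackingError(ValueError):
    """Requested cell count cannot be placed at the minimum spacing."""


def _sample_layout(spec: SyntheticCoreSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping cell positions inside the disk."""
    cx, cy = spec.core_centre
    r_min, r_max = spec.nucleus_radius_range
    spacing = spec.min_spacing_factor * r_max
    placement_radius = spec.core_radius - (r_max + 4.0)
    if placement_radius <= 0 and spec.n_cells > 0:
        raise PackingError("core_radius too small to contain any nucleus")
    positions: list[tuple[float, float]] = []
    attempts, max_attempts = 0, max(2000, 400 * max(spec.n_cells, 1))
    while len(positions) < spec.n_cells:
        if attempts >= max_attempts:
            raise PackingError(
                f"could not place {spec.n_cells} cells with minimum spacing "
                f"{spacing:.1f} px inside radius {placement_radius:.0f} px "
                f"(placed {len(positions)}); reduce n_cells or min_spacing_factor"
            )
        attempts += 1
        t = 2 * np.pi * rng.random()
        u = placement_radius * np.sqrt(rng.random())
        x, y = cx + u * np.cos(t), cy + u * np.sin(t)
        if all((x - px) ** 2 + (y - py) ** 2 >= spacing**2 for px, py in positions):
            positions.append((x, y))
    radii = rng.uniform(r_min, r_max, size=spec.n_cells)
    aspects = rng.uniform(0.85, 1.0, size=spec.n_cells)
    angles = rng.uniform(0, np.pi, size=spec.n_cells)
    hema = rng.uniform(*spec.hematoxylin_od_range, size=spec.n_cells)
    return positions, radii, aspects, angles, hema


def _positive_labels(n: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    n_pos = int(round(fraction * n))
    labels = np.zeros(n, dtype=bool)
    labels[rng.permutation(n)[:n_pos]] = True
    return labels


def _gap_mask(spec: SyntheticCoreSpec, shape, rng: np.random.Generator):
    """Boolean mask of the missing wedge (angular sector of the disk)."""
    cx, cy = spec.core_centre
    theta0 = rng.uniform(0, 2 * np.pi)
    width = 2 * np.pi * spec.gap_fraction
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    ang = np.mod(np.arctan2(yy - cy, xx - cx) - theta0, 2 * np.pi)
    return ang < width


def _fold_mask(spec: SyntheticCoreSpec, shape, rng: np.random.Generator):
    """Boolean mask of a dark band through the disk centre."""
    cx, cy = spec.core_centre
    theta = rng.uniform(0, np.pi)
    # solve for the band half-width whose chord band covers fold_fraction of the disk
    def band_area_fraction(b):
        return (2.0 / np.pi) * (b * np.sqrt(1.0 - b**2) + np.arcsin(b))

    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if band_area_fraction(mid) < spec.fold_fraction:
            lo = mid
        else:
            hi = mid
    half_width = hi * spec.core_radius
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dist = np.abs((xx - cx) * np.sin(theta) - (yy - cy) * np.cos(theta))
    return dist <= half_width


def compose_core_od(spec: SyntheticCoreSpec):
    """Build the exact per-pixel concentration fields and ground truth.

    Returns ``(h_field, d_field, ground_truth)`` where the fields are the
    hematoxylin and DAB concentration maps (OD units) before any
    quantisation.  The background is an extremely light hematoxylin tint
    whose mean grey level equals ``background_intensity``.
    """
    rng_layout = np.random.default_rng([spec.seed, 0])
    rng_labels = np.random.default_rng([spec.seed, 1])
    rng_artifact = np.random.default_rng([spec.seed, 2])
    n = spec.image_size
    shape = (n, n)
    cx, cy = spec.core_centre

    matrix = StainMatrix()
    h_baseline = spec.background_od / float(np.mean(matrix.hematoxylin))
    h_field = np.full(shape, h_baseline, dtype=float)
    d_field = np.zeros(shape, dtype=float)

    if spec.artifact == "blank":
        circle = CircleROI(detected=False, quality_flags=frozenset({"no_circle"}))
        return h_field, d_field, GroundTruth(circle=circle, cells=[], seed=spec.seed)

    yy, xx = np.mgrid[:n, :n]
    disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.core_radius**2
    wash = np.zeros(shape)
    wash[disk] = spec.tissue_wash_od

    gap = None
    if spec.artifact == "gap":
        gap = _gap_mask(spec, shape, rng_artifact)
        wash[gap] = 0.0

    positions, radii, aspects, angles, hema = _sample_layout(spec, rng_layout)
    labels = _positive_labels(spec.n_cells, spec.positive_fraction, rng_labels)

    cells: list[GroundTruthCell] = []
    nuc_h = np.zeros(shape)
    nuc_d = np.zeros(shape)
    keep = np.ones(spec.n_cells, dtype=bool)
    if gap is not None:
        for i, (x, y) in enumerate(positions):
            if gap[int(round(y)), int(round(x))]:
                keep[i] = False
    for i, (x, y) in enumerate(positions):
        if not keep[i]:
            continue
        rr, cc = draw.ellipse(
            y, x, radii[i], radii[i] * aspects[i], shape=shape, rotation=angles[i]
        )
        nuc_h[rr, cc] = np.maximum(nuc_h[rr, cc], hema[i])
        if labels[i]:
            amp = rng_labels.uniform(*spec.dab_od_range)
            nuc_d[rr, cc] = np.maximum(nuc_d[rr, cc], amp)
        cells.append(
            GroundTruthCell(x=float(x), y=float(y), radius=float(radii[i]), is_positive=bool(labels[i]))
        )

    if spec.artifact == "fold":
        fold = _fold_mask(spec, shape, rng_artifact) & disk
        nuc_h[fold] = spec.fold_od

    # soften nucleus and wash edges (sigma = 1 px)
    h_field += gaussian_filter(wash, 1.0) + gaussian_filter(nuc_h, 1.0)
    d_field += gaussian_filter(nuc_d, 1.0)

    circle = CircleROI(cx=float(cx), cy=float(cy), radius=float(spec.core_radius), detected=True)
    return h_field, d_field, GroundTruth(circle=circle, cells=cells, seed=spec.seed)


def _fields_to_image(h_field, d_field, spec: SyntheticCoreSpec, rng: np.random.Generator) -> np.ndarray:
    matrix = StainMatrix()
    od = (
        h_field[..., None] * np.asarray(matrix.hematoxylin)
        + d_field[..., None] * np.asarray(matrix.dab)
    )
    rgb = od_to_rgb(od).astype(float)
    if spec.noise_sigma > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sigma, size=rgb.shape)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def render_core(
    spec: SyntheticCoreSpec,
    sample_id: str = "",
    core_id: str = "",
    marker: str = "",
) -> tuple[CoreImage, GroundTruth]:
    """Render one synthetic core image plus its exact ground truth."""
    h_field, d_field, gt = compose_core_od(spec)
    rng_noise = np.random.default_rng([spec.seed, 3])
    pixels = _fields_to_image(h_field, d_field, spec, rng_noise)
    image = CoreImage(pixels=pixels, sample_id=sample_id, core_id=core_id, marker=marker)
    return image, gt


def render_artifact_core(spec: SyntheticCoreSpec) -> CoreImage:
    """Render a blank / fold / gap artifact core (image only)."""
    if spec.artifact == "none":
        raise ValueError("render_artifact_core requires artifact in {blank, fold, gap}")
    image, _ = render_core(spec)
    return image


def render_marker_stack(
    base_spec: SyntheticCoreSpec,
    marker_positive_fractions: Sequence[float],
    jitters: Sequence[tuple[float, float, float]],
    markers: Sequence[str] | None = None,
) -> list[tuple[CoreImage, GroundTruth]]:
    """Render serial single-plex sections of the same core.

    All markers share one cell layout; each marker gets its own positivity
    labels, and its circle (and with it every cell position and radius) is
    translated by ``(dx, dy)`` and scaled by ``scale`` - emulating the
    positional shifts between stacked sections that circle-based
    registration must undo.
    """
    if len(marker_positive_fractions) != len(jitters):
        raise ValueError("need one jitter per marker")
    for dx, dy, s in jitters:
        if abs(dx) > 0.15 * base_spec.core_radius or abs(dy) > 0.15 * base_spec.core_radius:
            raise ValueError("jitter translation too large relative to core radius")
        if not 0.85 <= s <= 1.15:
            raise ValueError("jitter scale must be within 15% of unity")
    rng_layout = np.random.default_rng([base_spec.seed, 0])
    positions, radii, aspects, angles, hema = _sample_layout(base_spec, rng_layout)
    cx0, cy0 = base_spec.core_centre

    out = []
    for m, (frac, (dx, dy, s)) in enumerate(zip(marker_positive_fractions, jitters)):
        rng_labels = np.random.default_rng([base_spec.seed, 1 if m == 0 else 10 + m])
        labels = _positive_labels(base_spec.n_cells, frac, rng_labels)
        cxm, cym = cx0 + dx, cy0 + dy
        rm = base_spec.core_radius * s
        n = base_spec.image_size
        shape = (n, n)
        matrix = StainMatrix()
        h_baseline = base_spec.background_od / float(np.mean(matrix.hematoxylin))
        h_field = np.full(shape, h_baseline)
        d_field = np.zeros(shape)
        yy, xx = np.mgrid[:n, :n]
        wash = np.zeros(shape)
        wash[(xx - cxm) ** 2 + (yy - cym) ** 2 <= rm**2] = base_spec.tissue_wash_od
        nuc_h = np.zeros(shape)
        nuc_d = np.zeros(shape)
        cells = []
        for i, (x, y) in enumerate(positions):
            xm, ym = cxm + s * (x - cx0), cym + s * (y - cy0)
            rr, cc = draw.ellipse(
                ym, xm, radii[i] * s, radii[i] * s * aspects[i], shape=shape, rotation=angles[i]
            )
            nuc_h[rr, cc] = np.maximum(nuc_h[rr, cc], hema[i])
            if labels[i]:
                amp = rng_labels.uniform(*base_spec.dab_od_range)
                nuc_d[rr, cc] = np.maximum(nuc_d[rr, cc], amp)
            cells.append(
                GroundTruthCell(x=float(xm), y=float(ym), radius=float(radii[i] * s), is_positive=bool(labels[i]))
            )
        h_field = h_field + gaussian_filter(wash, 1.0) + gaussian_filter(nuc_h, 1.0)
        d_field = d_field + gaussian_filter(nuc_d, 1.0)
        rng_noise = np.random.default_rng([base_spec.seed, 3 if m == 0 else 100 + m])
        pixels = _fields_to_image(h_field, d_field, base_spec, rng_noise)
        circle = CircleROI(cx=float(cxm), cy=float(cym), radius=float(rm), detected=True)
        marker_name = markers[m] if markers is not None else f"marker{m}"
        image = CoreImage(pixels=pixels, marker=marker_name)
        out.append((image, GroundTruth(circle=circle, cells=cells, seed=base_spec.seed)))
    return out


# ---------------------------------------------------------------------------
# sidecar I/O: TSV of cells plus a JSON header (circle, counts, seed)

def save_ground_truth(gt: GroundTruth, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.gt.tsv`` (one row per cell) and ``<prefix>.gt.json``."""
    prefix = Path(path_prefix)
    tsv = prefix.with_suffix(prefix.suffix + ".gt.tsv") if prefix.suffix else Path(str(prefix) + ".gt.tsv")
    jsn = Path(str(tsv)[: -len(".tsv")] + ".json")
    with open(tsv, "w") as fh:
        fh.write("x\ty\tradius\tis_positive\n")
        for c in gt.cells:
            fh.write(f"{c.x:.10g}\t{c.y:.10g}\t{c.radius:.10g}\t{int(c.is_positive)}\n")
    header = {
        "circle": {
            "cx": gt.circle.cx,
            "cy": gt.circle.cy,
            "radius": gt.circle.radius,
            "detected": gt.circle.detected,
        },
        "n_total": gt.n_total,
        "n_positive": gt.n_positive,
        "seed": gt.seed,
    }
    with open(jsn, "w") as fh:
        json.dump(header, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return tsv, jsn


def load_ground_truth(path_prefix: str | Path) -> GroundTruth:
    """Read a ground-truth sidecar written by :func:`save_ground_truth`."""
    prefix = Path(path_prefix)
    tsv = Path(str(prefix) + ".gt.tsv") if not str(prefix).endswith(".gt.tsv") else prefix
    jsn = Path(str(tsv)[: -len(".tsv")] + ".json")
    if not tsv.exists() or not jsn.exists():
        raise FileNotFoundError(f"ground-truth sidecar not found: {tsv} / {jsn}")
    with open(jsn) as fh:
        header = json.load(fh)
    c = header["circle"]
    circle = CircleROI(
        cx=c["cx"], cy=c["cy"], radius=c["radius"], detected=c["detected"],
        quality_flags=frozenset() if c["detected"] else frozenset({"no_circle"}),
    )
    cells = []
    with open(tsv) as fh:
        next(fh)
        for line in fh:
            x, y, r, pos = line.rstrip("\n").split("\t")
            cells.append(GroundTruthCell(float(x), float(y), float(r), bool(int(pos))))
    gt = GroundTruth(circle=circle, cells=cells, seed=int(header.get("seed", 0)))
    if gt.n_total != header["n_total"] or gt.n_positive != header["n_positive"]:
        raise ValueError("ground-truth sidecar counts disagree with cell rows")
    return gt
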