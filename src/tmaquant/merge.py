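"""In-silico merging of stacked single-plex stains.

Serial sections of the same TMA core are stained for different markers;
because every section's cells are quantified relative to its own
detected circle, mapping all cell maps through the circle geometry
(translation + isotropic scale, no rotation or warp) places them on one
common coordinate grid.  Residual shifts between sections are reported
by downstream matching, not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import draw

from .geometry import CircleROI, to_core_frame
from .quantify import CellObject, CoreResult

__all__ = ["CompositeOverlay", "align_stack", "render_composite", "match_cells"]


@dataclass
class CompositeOverlay:
    """Registered cell maps from one stack of single-plex stains.

    Layer coordinates are in the core frame: origin at the core centre,
    one unit = one pixel at ``reference_radius``.
    """

    reference_radius: float
    layers: list[tuple[str, list[CellObject]]]
    provenance: dict[str, CircleROI] = field(default_factory=dict)

    def __post_init__(self):
        markers = [m for m, _ in self.layers]
        if len(set(markers)) != len(markers):
            raise ValueError("each marker may appear in exactly one layer")


def align_stack(
    results: list[CoreResult], reference_radius: float | None = None
) -> CompositeOverlay:
    """Map each marker's cells into the shared core frame.

    All results must come from the same (sample, core) and have detected
    circles; the reference radius defaults to the first layer's radius.
    """
    if not results:
        raise ValueError("align_stack needs at least one CoreResult")
    key = (results[0].sample_id, results[0].core_id)
    for r in results:
        if (r.sample_id, r.core_id) != key:
            raise ValueError(
                f"mixed stack: {(r.sample_id, r.core_id)} does not match {key}"
            )
        if not r.circle.detected:
            raise ValueError(
                f"marker {r.marker!r}: core circle not detected, cannot register"
            )
    ref = reference_radius if reference_radius is not None else results[0].circle.radius
    layers, provenance = [], {}
    for r in results:
        scale = ref / r.circle.radius
        cells = []
        for c in r.cells:
            (nx, ny), = to_core_frame([(c.x, c.y)], r.circle, ref)
            cells.append(
                CellObject(
                    x=float(nx), y=float(ny), radius=c.radius * scale, marker=r.marker,
                    positive=c.positive, positive_pixel_fraction=c.positive_pixel_fraction,
                )
            )
        layers.append((r.marker, cells))
        provenance[r.marker] = r.circle
    return CompositeOverlay(reference_radius=ref, layers=layers, provenance=provenance)


def render_composite(
    overlay: CompositeOverlay,
    palette: dict[str, tuple[int, int, int]],
    output_size: int = 1024,
    background: tuple[int, int, int] = (250, 250, 250),
) -> np.ndarray:
    """Draw the overlay as an RGB image: coloured cell dots on a neutral
    background with the reference circle outlined.

    Layers are drawn in their stored order, so later layers paint over
    earlier ones at coincident positions.
    """
    for marker, _ in overlay.layers:
        if marker not in palette:
            raise ValueError(f"palette has no colour for marker {marker!r}")
    canvas = np.full((output_size, output_size, 3), background, dtype=np.uint8)
    centre = output_size / 2.0
    scale = (output_size / 2.0 - 2.0) / overlay.reference_radius
    rr, cc = draw.circle_perimeter(
        int(round(centre)), int(round(centre)),
        int(round(overlay.reference_radius * scale)), shape=canvas.shape[:2],
    )
    canvas[rr, cc] = (120, 120, 120)
    for marker, cells in overlay.layers:
        colour = palette[marker]
        for c in cells:
            px = centre + c.x * scale
            py = centre + c.y * scale
            radius = max(1.5, c.radius * scale)
            rr, cc = draw.disk((py, px), radius, shape=canvas.shape[:2])
            canvas[rr, cc] = colour
    return canvas


def match_cells(
    layer_a: list[CellObject], layer_b: list[CellObject], gate: float = 10.0
) -> list[tuple[int, int, float]]:
    """Greedy nearest-neighbour matching between two core-frame cell lists.

    Pairs are accepted closest-first while both cells are unused and the
    distance is within ``gate``; returns (index_a, index_b, distance)
    triples.  Used to quantify registration residuals against ground
    truth.
    """
    if not layer_a or not layer_b:
        return []
    pa = np.array([[c.x, c.y] for c in layer_a])
    pb = np.array([[c.x, c.y] for c in layer_b])
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    used_a, used_b, out = set(), set(), []
    for i, j in order:
        if d[i, j] > gate:
            break
        if i in used_a or j in used_b:
            continue
        used_a.add(int(i))
        used_b.add(int(j))
        out.append((int(i), int(j), float(d[i, j])))
    return out
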