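"""Batch orchestration, run configuration, and output file formats.

A run is described by a YAML configuration file::

    output_dir: results
    seed: 0
    defaults:            # optional, applied to every image
      backend: log
      fraction_cutoff: 0.10
      grid_size: 16
    markers:             # optional per-marker overrides of the defaults
      CD3:
        fraction_cutoff: 0.10
    images:
      - {path: cores/S1_c1_CD3.png, sample: S1, core: "1", marker: CD3}

Outputs are TSV with a fixed column order and a schema-version comment
line, formatted deterministically (counts as integers, real values at 6
significant digits) so that re-running an identical batch produces
byte-identical tables.  Per-core quality flags are reported, never
raised: a flagged core appears in the flagged-core report and is skipped
by downstream analytics, but does not abort the batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .geometry import CoreImage
from .quantify import CoreResult, QuantifyConfig, get_backend, quantify_core
from .stains import StainMatrix

__all__ = [
    "SCHEMA_VERSION",
    "ImageEntry",
    "RunConfig",
    "ConfigError",
    "validate_config",
    "run_batch",
    "write_results_tsv",
    "write_cells_tsv",
    "write_circles_tsv",
    "write_flagged_tsv",
    "read_tsv",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "tmaquant/1"

_PARAM_KEYS = {
    "backend", "backend_params", "grid_size", "fraction_cutoff", "margin_fraction",
    "n_bins", "radius_fraction_range", "min_dab_signal", "stain_vectors",
}


class ConfigError(ValueError):
    """Raised with every offending entry listed, before any processing."""


@dataclass(frozen=True)
class ImageEntry:
    path: Path
    sample_id: str
    core_id: str
    marker: str

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.sample_id, self.core_id, self.marker)


@dataclass
class RunConfig:
    entries: list[ImageEntry]
    output_dir: Path
    seed: int = 0
    defaults: dict = field(default_factory=dict)
    marker_overrides: dict[str, dict] = field(default_factory=dict)

    def quantify_config(self, marker: str) -> QuantifyConfig:
        """Materialise the per-marker parameters into a QuantifyConfig."""
        params = dict(self.defaults)
        params.update(self.marker_overrides.get(marker, {}))
        backend_name = params.pop("backend", "log")
        backend_params = params.pop("backend_params", {})
        backend = get_backend(backend_name, **backend_params)
        vectors = params.pop("stain_vectors", None)
        matrix = StainMatrix(**vectors) if vectors else StainMatrix()
        rng = params.pop("radius_fraction_range", (0.55, 0.98))
        return QuantifyConfig(
            backend=backend, stain_matrix=matrix,
            radius_fraction_range=tuple(rng), **params,
        )


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a run configuration, reporting all problems at once."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    problems: list[str] = []
    entries: list[ImageEntry] = []
    seen: dict[tuple, int] = {}
    base = path.parent
    for i, item in enumerate(raw.get("images") or []):
        missing = [k for k in ("path", "sample", "core", "marker") if k not in item]
        if missing:
            problems.append(f"images[{i}]: missing fields {missing}")
            continue
        img_path = Path(item["path"])
        if not img_path.is_absolute():
            img_path = base / img_path
        entry = ImageEntry(
            path=img_path, sample_id=str(item["sample"]),
            core_id=str(item["core"]), marker=str(item["marker"]),
        )
        if entry.key in seen:
            problems.append(
                f"images[{i}]: duplicate (sample, core, marker) key {entry.key} "
                f"(first seen at images[{seen[entry.key]}])"
            )
        else:
            seen[entry.key] = i
        if not entry.path.exists():
            problems.append(f"images[{i}]: file not found: {entry.path}")
        entries.append(entry)
    if not entries:
        problems.append("no images listed")
    defaults = raw.get("defaults") or {}
    markers = raw.get("markers") or {}
    for scope, params in [("defaults", defaults)] + [
        (f"markers.{m}", p) for m, p in markers.items()
    ]:
        for key in params:
            if key not in _PARAM_KEYS:
                problems.append(f"{scope}: unknown parameter {key!r}")
    if problems:
        raise ConfigError(f"{path}: invalid configuration:\n  " + "\n  ".join(problems))
    out_dir = Path(raw.get("output_dir", "tmaquant_out"))
    if not out_dir.is_absolute():
        out_dir = base / out_dir
    return RunConfig(
        entries=entries, output_dir=out_dir, seed=int(raw.get("seed", 0)),
        defaults=defaults, marker_overrides=markers,
    )


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and not np.isfinite(value)):
        return "NA"
    if isinstance(value, (bool, np.bool_)):
        return str(int(value))
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def _write_table(path: Path, columns: list[str], rows: list[list]) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a table written by this module (schema comment line skipped)."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    return df


RESULT_COLUMNS = [
    "sample", "core", "marker", "n_total", "n_positive", "dab_threshold",
    "circle_x", "circle_y", "circle_radius", "detected", "flags",
]
CELL_COLUMNS = [
    "sample", "core", "marker", "x", "y", "core_frame_x", "core_frame_y",
    "radius", "area", "positive_pixel_fraction", "positive",
]
CIRCLE_COLUMNS = ["image", "centre_x", "centre_y", "diameter", "detected", "flags"]


def _flags_str(flags) -> str:
    return ",".join(sorted(flags)) if flags else "-"


def write_results_tsv(path: Path, results: list[CoreResult]) -> None:
    rows = []
    for r in results:
        rows.append([
            r.sample_id, r.core_id, r.marker, r.n_total_cells, r.n_positive_cells,
            r.dab_threshold, r.circle.cx if r.circle.detected else None,
            r.circle.cy if r.circle.detected else None,
            r.circle.radius if r.circle.detected else None,
            r.circle.detected, _flags_str(r.flags),
        ])
    _write_table(path, RESULT_COLUMNS, rows)


def write_cells_tsv(path: Path, results: list[CoreResult]) -> None:
    from .geometry import to_core_frame

    rows = []
    for r in results:
        for c in r.cells:
            (fx, fy), = to_core_frame([(c.x, c.y)], r.circle, r.circle.radius)
            rows.append([
                r.sample_id, r.core_id, r.marker, c.x, c.y, float(fx), float(fy),
                c.radius, c.area, c.positive_pixel_fraction, c.positive,
            ])
    _write_table(path, CELL_COLUMNS, rows)


def write_circles_tsv(path: Path, results: list[CoreResult], names: list[str]) -> None:
    rows = []
    for name, r in zip(names, results):
        rows.append([
            name, r.circle.cx if r.circle.detected else None,
            r.circle.cy if r.circle.detected else None,
            2 * r.circle.radius if r.circle.detected else None,
            r.circle.detected, _flags_str(r.flags),
        ])
    _write_table(path, CIRCLE_COLUMNS, rows)


def write_flagged_tsv(path: Path, results: list[CoreResult]) -> None:
    rows = [
        [r.sample_id, r.core_id, r.marker, _flags_str(r.flags)]
        for r in results
        if r.flags
    ]
    _write_table(path, ["sample", "core", "marker", "flags"], rows)


def run_batch(config: RunConfig) -> list[CoreResult]:
    """Quantify every configured image and write the output tables.

    Each core is processed independently (no cross-core state); an
    unreadable image is logged and recorded as a ``read_error`` flag
    without aborting the batch.  Writes ``results.tsv``, ``cells.tsv``,
    ``circles.tsv`` and ``flagged.tsv`` into the output directory.
    """
    config.output_dir.mkdir(parents=True, exist_ok=True)
    results: list[CoreResult] = []
    names: list[str] = []
    for entry in config.entries:
        names.append(entry.path.name)
        try:
            pixels = np.asarray(iio.imread(entry.path))
            if pixels.ndim == 3 and pixels.shape[2] == 4:
                pixels = pixels[..., :3]
            image = CoreImage(
                pixels=pixels.astype(np.uint8), sample_id=entry.sample_id,
                core_id=entry.core_id, marker=entry.marker,
            )
        except Exception as exc:  # noqa: BLE001 - recorded, not raised
            logger.error("cannot read %s: %s", entry.path, exc)
            results.append(CoreResult(
                sample_id=entry.sample_id, core_id=entry.core_id, marker=entry.marker,
                flags=frozenset({"read_error", "no_circle"}),
            ))
            continue
        result = quantify_core(image, config.quantify_config(entry.marker))
        logger.info(
            "%s: n_total=%s n_positive=%s flags=%s",
            entry.path.name, result.n_total_cells, result.n_positive_cells,
            _flags_str(result.flags),
        )
        results.append(result)
    write_results_tsv(config.output_dir / "results.tsv", results)
    write_cells_tsv(config.output_dir / "cells.tsv", results)
    write_circles_tsv(config.output_dir / "circles.tsv", results, names)
    write_flagged_tsv(config.output_dir / "flagged.tsv", results)
    return results
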