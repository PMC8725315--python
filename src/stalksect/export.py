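"""Calibrated geometry export: FE-preprocessor sketch scripts and neutral formats.

Extracted boundaries are converted to world millimeters with the origin at
the section centroid and y pointing up (the convention of FE sketch
planes), optionally simplified with Douglas–Peucker, and written either as
an Abaqus/CAE-dialect Python sketch script (model → sheet size → one
closed spline per boundary → rename) or as CSV / GeoJSON / SVG for
solver-agnostic exchange.  The emitted script is validated by the
companion parser (:func:`parse_fe_script`), not by executing it in the
commercial package.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely

from .bundles import BundleSet
from .io import Calibration, px_to_mm
from .morphometry import RindBoundaries, signed_area

__all__ = [
    "WorldGeometry",
    "to_world",
    "decimate_boundary",
    "sheet_size_for",
    "emit_fe_script",
    "parse_fe_script",
    "export_neutral",
    "import_neutral_csv",
]

DEFAULT_DECIMATION_TOL_MM = 0.01
MODEL_NAME = "StalkSection"


@dataclass
class WorldGeometry:
    """Closed splines in world mm, named deterministically."""

    splines: list[np.ndarray]
    names: list[str]
    sheet_size_mm: float

    def __post_init__(self) -> None:
        if len(self.splines) != len(self.names):
            raise ValueError("one name per spline required")
        if not self.splines:
            raise ValueError("empty geometry")
        closed = []
        for name, sp in zip(self.names, self.splines):
            sp = np.asarray(sp, dtype=np.float64)
            if not np.isfinite(sp).all():
                raise ValueError(f"non-finite coordinate in spline {name!r}")
            if not np.allclose(sp[0], sp[-1]):
                sp = np.vstack([sp, sp[0]])
            closed.append(sp)
        self.splines = closed
        if self.sheet_size_mm < 2.0 * _bbox_diagonal(self.splines) * (1 - 1e-9):
            raise ValueError("sheet_size_mm must be at least twice the bounding-box diagonal")


def _bbox_diagonal(splines: list[np.ndarray]) -> float:
    allpts = np.vstack(splines)
    span = allpts.max(axis=0) - allpts.min(axis=0)
    return float(np.hypot(*span))


def sheet_size_for(splines: list[np.ndarray]) -> float:
    """Smallest power of 10 (mm) exceeding twice the bounding-box diagonal."""
    need = 2.0 * _bbox_diagonal(splines)
    size = 1.0
    while size <= need:
        size *= 10.0
    return size


def to_world(b: RindBoundaries, bundles: BundleSet | None, cal: Calibration) -> WorldGeometry:
    """Convert boundaries (and auto-bundle outlines) to world mm.

    The world origin sits at the section centroid and y increases upward.
    """
    if cal is None:
        raise ValueError("calibration required for world-coordinate export")
    world_cal = Calibration(px_per_mm=cal.px_per_mm, origin_px=b.centroid_px, y_up=True)
    splines = [px_to_mm(b.outer, world_cal), px_to_mm(b.inner, world_cal)]
    names = ["outer_rind", "inner_rind"]
    if bundles is not None:
        for i, bun in enumerate(b for b in bundles.bundles if b.boundary is not None):
            splines.append(px_to_mm(bun.boundary, world_cal))
            names.append(f"bundle_{i + 1:03d}")
    return WorldGeometry(splines=splines, names=names, sheet_size_mm=sheet_size_for(splines))


def decimate_boundary(spline: np.ndarray, tolerance_mm: float) -> np.ndarray:
    """Douglas–Peucker simplification of a closed polyline; tolerance 0 = identity."""
    if tolerance_mm < 0:
        raise ValueError("tolerance_mm must be ≥ 0")
    spline = np.asarray(spline, dtype=np.float64)
    if tolerance_mm == 0:
        return spline.copy()
    ring = shapely.LinearRing(spline)
    simplified = shapely.simplify(ring, tolerance_mm, preserve_topology=True)
    out = np.asarray(simplified.coords, dtype=np.float64)
    if not np.allclose(out[0], out[-1]):
        out = np.vstack([out, out[0]])
    return out


# ---------------------------------------------------------------------------
# FE sketch script


def emit_fe_script(geom: WorldGeometry, out_path: str | Path | None = None) -> str:
    """Emit an Abaqus/CAE-dialect sketch script for the geometry.

    Statement order: model creation, sheet-size declaration, one closed
    spline per boundary with its full coordinate list at fixed 6-decimal
    precision, and a rename per sketch.  Byte-identical for identical input.
    """
    lines = [
        "# Specimen-specific cross-section sketch (generated by stalksect)",
        "from abaqus import mdb",
        f"mdb.Model(name='{MODEL_NAME}')",
        f"sheetSize = {geom.sheet_size_mm:.6f}",
    ]
    for name, sp in zip(geom.names, geom.splines):
        coords = ", ".join(f"({x:.6f}, {y:.6f})" for x, y in sp)
        lines.append(
            f"s = mdb.models['{MODEL_NAME}'].ConstrainedSketch(name='__profile__', sheetSize=sheetSize)"
        )
        lines.append(f"s.Spline(points=({coords}))")
        lines.append(f"mdb.models['{MODEL_NAME}'].sketches.changeKey(fromName='__profile__', toName='{name}')")
    text = "\n".join(lines) + "\n"
    if out_path is not None:
        Path(out_path).write_text(text)
    return text


_SHEET_RE = re.compile(r"^sheetSize = ([0-9.+-eE]+)$")
_SPLINE_RE = re.compile(r"^s\.Spline\(points=\((.*)\)\)$")
_RENAME_RE = re.compile(r"toName='([^']+)'\)$")
_POINT_RE = re.compile(r"\(([^()]+)\)")


def parse_fe_script(text: str) -> WorldGeometry:
    """Companion parser: recover the geometry from an emitted script."""
    sheet = None
    splines: list[np.ndarray] = []
    names: list[str] = []
    pending: np.ndarray | None = None
    for line in text.splitlines():
        m = _SHEET_RE.match(line)
        if m:
            sheet = float(m.group(1))
            continue
        m = _SPLINE_RE.match(line)
        if m:
            pts = [tuple(float(v) for v in grp.split(",")) for grp in _POINT_RE.findall(m.group(1))]
            pending = np.asarray(pts, dtype=np.float64)
            continue
        m = _RENAME_RE.search(line)
        if m and pending is not None:
            splines.append(pending)
            names.append(m.group(1))
            pending = None
    if sheet is None or not splines:
        raise ValueError("not a recognizable sketch script")
    return WorldGeometry(splines=splines, names=names, sheet_size_mm=sheet)


# ---------------------------------------------------------------------------
# neutral formats


def export_neutral(geom: WorldGeometry, format: str, out_path: str | Path) -> None:
    """Write the geometry as ``csv``, ``geojson``, or ``svg`` (mm units)."""
    out_path = Path(out_path)
    if format == "csv":
        lines = ["spline,vertex,x_mm,y_mm"]
        for name, sp in zip(geom.names, geom.splines):
            for i, (x, y) in enumerate(sp):
                lines.append(f"{name},{i},{float(x)!r},{float(y)!r}")
        out_path.write_text("\n".join(lines) + "\n")
    elif format == "geojson":
        features = [
            {
                "type": "Feature",
                "properties": {"name": name},
                "geometry": {"type": "Polygon", "coordinates": [np.asarray(sp).tolist()]},
            }
            for name, sp in zip(geom.names, geom.splines)
        ]
        payload = {"type": "FeatureCollection", "features": features, "properties": {"units": "mm"}}
        out_path.write_text(json.dumps(payload))
    elif format == "svg":
        allpts = np.vstack(geom.splines)
        lo = allpts.min(axis=0)
        hi = allpts.max(axis=0)
        pad = 0.05 * max(hi - lo)
        x0, y0 = lo - pad
        w, h = (hi - lo) + 2 * pad
        paths = []
        for name, sp in zip(geom.names, geom.splines):
            # SVG y grows downward; flip world y for display
            d = "M " + " L ".join(f"{x:.4f},{(-y):.4f}" for x, y in sp[:-1]) + " Z"
            paths.append(f'  <path id="{name}" d="{d}" fill="none" stroke="black" stroke-width="{w / 400:.4f}"/>')
        svg = (
            f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="{x0:.4f} {-(y0 + h):.4f} {w:.4f} {h:.4f}">\n'
            + "\n".join(paths)
            + "\n</svg>\n"
        )
        out_path.write_text(svg)
    else:
        raise ValueError(f"unknown export format {format!r}; expected csv, geojson, or svg")


def import_neutral_csv(path: str | Path) -> WorldGeometry:
    """Re-import a CSV written by :func:`export_neutral` (exact round trip)."""
    names: list[str] = []
    by_name: dict[str, list[tuple[float, float]]] = {}
    with Path(path).open() as fh:
        header = fh.readline()
        if not header.startswith("spline,"):
            raise ValueError(f"not a stalksect geometry CSV: {path}")
        for line in fh:
            name, _idx, x, y = line.rstrip("\n").split(",")
            if name not in by_name:
                by_name[name] = []
                names.append(name)
            by_name[name].append((float(x), float(y)))
    splines = [np.asarray(by_name[n], dtype=np.float64) for n in names]
    return WorldGeometry(splines=splines, names=names, sheet_size_mm=sheet_size_for(splines))
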