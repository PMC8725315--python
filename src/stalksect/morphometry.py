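"""Boundary extraction and cross-sectional morphometry.

The four headline phenotypes are computed from the traced rind boundaries:

* **Diameters** — two conventions are available.  The *axis-endpoint*
  convention intersects rays from the section centroid along the image
  axes (0°/90°/180°/270°) with the outer boundary and pairs opposite
  crossings into a horizontal and a vertical chord; the larger is the
  major diameter.  The *Feret* convention measures the caliper distances:
  the maximum pairwise support distance (major) and the minimum width over
  all support directions (minor), both rotation-invariant.
* **Rind thickness** — the mean over every outer-boundary vertex of the
  shortest Euclidean distance to the inner boundary polyline (distance to
  segments, not just vertices), i.e. a directed outer→inner mean.
* **Areas** — foreground pixel counts scaled by the calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import ConvexHull
from skimage import measure

from .io import Calibration
from .segment import SegmentedSection

__all__ = [
    "RindBoundaries",
    "DiameterResult",
    "RindThicknessResult",
    "trace_boundaries",
    "axis_diameters",
    "feret_diameters",
    "rind_thickness",
    "region_areas",
]


def signed_area(poly: np.ndarray) -> float:
    """Shoelace signed area of a closed polyline (first point = last)."""
    x, y = poly[:-1, 0], poly[:-1, 1]
    xn, yn = poly[1:, 0], poly[1:, 1]
    return 0.5 * float(np.sum(x * yn - xn * y))


def _canonicalize(poly: np.ndarray) -> np.ndarray:
    """Close the polyline and orient it counterclockwise (positive shoelace
    area in image coordinates)."""
    poly = np.asarray(poly, dtype=np.float64)
    if not np.allclose(poly[0], poly[-1]):
        poly = np.vstack([poly, poly[0]])
    if signed_area(poly) < 0:
        poly = poly[::-1].copy()
    return poly


@dataclass
class RindBoundaries:
    """Ordered closed outer and inner rind boundary polylines, image px."""

    outer: np.ndarray
    inner: np.ndarray
    centroid_px: tuple[float, float]

    def __post_init__(self) -> None:
        self.outer = _canonicalize(self.outer)
        self.inner = _canonicalize(self.inner)
        for name, poly in (("outer", self.outer), ("inner", self.inner)):
            if len(poly) - 1 < 8:
                raise ValueError(f"{name} boundary has fewer than 8 vertices")


@dataclass(frozen=True)
class DiameterResult:
    major_mm: float
    minor_mm: float
    major_endpoints_px: np.ndarray
    minor_endpoints_px: np.ndarray
    convention: str

    def __post_init__(self) -> None:
        if not self.major_mm >= self.minor_mm > 0:
            raise ValueError(f"need major ≥ minor > 0, got {self.major_mm}, {self.minor_mm}")


@dataclass(frozen=True)
class RindThicknessResult:
    mean_mm: float
    per_point_mm: np.ndarray
    segments_px: np.ndarray  # (n, 2, 2): outer vertex, nearest inner point


# ---------------------------------------------------------------------------
# boundary tracing


def _largest_contour(mask: np.ndarray) -> np.ndarray:
    padded = np.pad(mask, 1).astype(np.float64)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("no contour found in mask")
    best = max(contours, key=len)
    # (row, col) → (x, y), undo padding
    return best[:, ::-1] - 1.0


def trace_boundaries(seg: SegmentedSection) -> RindBoundaries:
    """Trace closed sub-pixel contours of the whole and inner masks."""
    if seg.whole_mask.pixels.sum() < 8 or seg.inner_mask.pixels.sum() < 8:
        raise ValueError("mask too small to trace (fewer than 8 boundary pixels)")
    outer = _largest_contour(seg.whole_mask.pixels)
    inner = _largest_contour(seg.inner_mask.pixels)
    ys, xs = np.nonzero(seg.whole_mask.pixels)
    centroid = (float(xs.mean()), float(ys.mean()))
    return RindBoundaries(outer=outer, inner=inner, centroid_px=centroid)


# ---------------------------------------------------------------------------
# diameters


def _ray_crossing(poly: np.ndarray, origin: np.ndarray, direction: np.ndarray) -> float:
    """Outermost intersection parameter t ≥ 0 of origin + t·direction with
    the closed polyline; raises if the ray misses."""
    p = poly[:-1]
    q = poly[1:]
    d = direction
    e = q - p
    w = origin - p
    denom = d[0] * (-e[:, 1]) + d[1] * e[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (w[:, 0] * (-e[:, 1]) + w[:, 1] * e[:, 0]) / denom
        u = (d[0] * w[:, 1] - d[1] * w[:, 0]) / denom
    ok = np.isfinite(t) & np.isfinite(u) & (t >= 0) & (u >= -1e-12) & (u <= 1 + 1e-12)
    if not ok.any():
        raise ValueError("diameter ray does not intersect the outer boundary (non-star-shaped section?)")
    return float(t[ok].max())


def axis_diameters(b: RindBoundaries, cal: Calibration) -> DiameterResult:
    """Axis-endpoint diameters: centroid-anchored chords along the image axes."""
    origin = np.asarray(b.centroid_px, dtype=np.float64)
    t_px = _ray_crossing(b.outer, origin, np.array([1.0, 0.0]))
    t_nx = _ray_crossing(b.outer, origin, np.array([-1.0, 0.0]))
    t_py = _ray_crossing(b.outer, origin, np.array([0.0, 1.0]))
    t_ny = _ray_crossing(b.outer, origin, np.array([0.0, -1.0]))
    horiz = t_px + t_nx
    vert = t_py + t_ny
    h_seg = np.array([origin + [-t_nx, 0.0], origin + [t_px, 0.0]])
    v_seg = np.array([origin + [0.0, -t_ny], origin + [0.0, t_py]])
    if horiz >= vert:
        major, minor = horiz, vert
        major_seg, minor_seg = h_seg, v_seg
    else:
        major, minor = vert, horiz
        major_seg, minor_seg = v_seg, h_seg
    return DiameterResult(
        major_mm=major / cal.px_per_mm,
        minor_mm=minor / cal.px_per_mm,
        major_endpoints_px=major_seg,
        minor_endpoints_px=minor_seg,
        convention="axis-endpoint",
    )


def feret_diameters(b: RindBoundaries, cal: Calibration) -> DiameterResult:
    """Caliper (Feret) diameters: max pairwise support distance and min width."""
    pts = b.outer[:-1]
    try:
        hull = ConvexHull(pts)
    except Exception as exc:  # qhull raises on degenerate input
        raise ValueError(f"degenerate (collinear) boundary, no convex hull: {exc}") from exc
    hv = pts[hull.vertices]
    # max Feret: max pairwise distance between hull vertices
    diff = hv[:, None, :] - hv[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    major_px = float(np.sqrt(d2[i, j]))
    major_seg = np.array([hv[i], hv[j]])
    # min Feret: min over hull edges of the farthest vertex from the edge line
    edges = np.roll(hv, -1, axis=0) - hv
    lengths = np.linalg.norm(edges, axis=1)
    valid = lengths > 0
    normals = np.column_stack([-edges[valid, 1], edges[valid, 0]]) / lengths[valid, None]
    # distance of every vertex to every edge line
    rel = hv[None, :, :] - hv[valid][:, None, :]  # (edges, vertices, 2)
    dists = np.abs(np.einsum("evk,ek->ev", rel, normals))
    widths = dists.max(axis=1)
    k = int(np.argmin(widths))
    minor_px = float(widths[k])
    far_idx = int(np.argmax(dists[k]))
    n = normals[k]
    far = hv[far_idx]
    minor_seg = np.array([far - n * minor_px, far])
    if minor_px > major_px:  # cannot happen geometrically; guard for ties
        minor_px, major_px = major_px, minor_px
    return DiameterResult(
        major_mm=major_px / cal.px_per_mm,
        minor_mm=minor_px / cal.px_per_mm,
        major_endpoints_px=major_seg,
        minor_endpoints_px=minor_seg,
        convention="feret",
    )


# ---------------------------------------------------------------------------
# rind thickness


def rind_thickness(b: RindBoundaries, cal: Calibration) -> RindThicknessResult:
    """Mean shortest outer→inner boundary distance (per outer vertex)."""
    outer_pts = b.outer[:-1]
    inner_ring = shapely.LinearRing(b.inner)
    if not shapely.Polygon(b.outer).contains(inner_ring):
        raise ValueError(
            "inner boundary intersects or lies outside the outer boundary; segmentation is inconsistent"
        )
    points = shapely.points(outer_pts)
    dists_px = shapely.distance(points, inner_ring)
    nearest = shapely.shortest_line(points, inner_ring)
    seg_coords = np.array([np.asarray(line.coords) for line in nearest])
    per_point_mm = dists_px / cal.px_per_mm
    if not np.all(per_point_mm > 0):
        raise ValueError("zero rind thickness at some boundary point; boundaries touch")
    return RindThicknessResult(
        mean_mm=float(np.mean(per_point_mm)),
        per_point_mm=per_point_mm,
        segments_px=seg_coords,
    )


# ---------------------------------------------------------------------------
# areas


def region_areas(seg: SegmentedSection, cal: Calibration) -> tuple[float, float]:
    """(whole, inner) areas in mm²: pixel counts / px_per_mm²."""
    whole_px, inner_px = seg.areas_px
    return whole_px / cal.px_per_mm**2, inner_px / cal.px_per_mm**2
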