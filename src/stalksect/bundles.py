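"""Vascular bundle detection and file-based manual corrections.

Bundles appear as compact dark blobs inside the pith of stained
pith-filled sections.  Automatic detection labels the thresholded
foreground restricted to the pith and keeps components that look like
single bundles (area window + circularity gate); components that are too
large or too ragged — typically several bundles touching — are reported as
merged-cluster candidates for the user to resolve.

The interactive click-to-edit step of the original workflow is replaced by
a plain-text edit list (CSV lines ``remove,<id>`` / ``add,<x>,<y>``), which
keeps corrections scriptable, reviewable, and testable.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure

from .preprocess import BinaryMask

__all__ = [
    "Bundle",
    "BundleSet",
    "EditList",
    "detect_bundles",
    "apply_manual_edits",
    "read_edit_list",
    "bundle_set_to_json",
]

DEFAULT_MIN_AREA_PX = 25.0
DEFAULT_MAX_AREA_FRAC = 0.02  # of pith area
DEFAULT_MIN_CIRCULARITY = 0.3

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class Bundle:
    id: int
    centroid_px: tuple[float, float]
    area_px: float
    provenance: str  # "auto" | "manual"
    boundary: np.ndarray | None = None  # closed polyline, absent for manual points


@dataclass
class BundleSet:
    bundles: list[Bundle] = field(default_factory=list)
    merged_candidates: list[Bundle] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.bundles)

    def ids(self) -> set[int]:
        return {b.id for b in self.bundles}


@dataclass(frozen=True)
class EditList:
    """Manual corrections: bundle ids to delete, points to add."""

    removals: tuple[int, ...] = ()
    additions: tuple[tuple[float, float], ...] = ()


def _circularity(area: float, perimeter: float) -> float:
    if perimeter <= 0:
        return 0.0
    return 4 * math.pi * area / perimeter**2


def detect_bundles(
    mask: BinaryMask,
    pith_mask: BinaryMask,
    min_area_px: float = DEFAULT_MIN_AREA_PX,
    max_area_px: float | None = None,
    min_circularity: float = DEFAULT_MIN_CIRCULARITY,
) -> BundleSet:
    """Detect bundle blobs in the thresholded image restricted to the pith.

    ``max_area_px`` defaults to 2 % of the pith area.  Components passing
    the area window and the circularity gate (4πA/P² ≥ ``min_circularity``)
    become bundles with traced boundaries; components above the area cap or
    below the circularity gate (but above the minimum area) are returned as
    merged-cluster candidates.
    """
    pith_area = float(pith_mask.pixels.sum())
    if pith_area == 0:
        raise ValueError("empty pith mask; cannot detect bundles")
    if max_area_px is None:
        max_area_px = DEFAULT_MAX_AREA_FRAC * pith_area
    if not 0 < min_area_px < max_area_px:
        raise ValueError(f"need 0 < min_area_px < max_area_px, got {min_area_px}, {max_area_px}")
    if not 0 <= min_circularity <= 1:
        raise ValueError(f"min_circularity must lie in [0, 1], got {min_circularity}")

    restricted = mask.pixels & pith_mask.pixels
    labels, n = ndimage.label(restricted, structure=_STRUCT8)
    bundles: list[Bundle] = []
    merged: list[Bundle] = []
    next_id = 1
    for props in measure.regionprops(labels):
        area = float(props.area)
        if area < min_area_px:
            continue
        cy, cx = props.centroid
        circ = _circularity(area, float(props.perimeter))
        # boundary traced on the component's own padded crop
        crop = np.pad(labels[props.slice] == props.label, 1).astype(np.float64)
        contours = measure.find_contours(crop, 0.5)
        boundary = None
        if contours:
            c = max(contours, key=len)[:, ::-1] - 1.0
            r0, c0 = props.slice[0].start, props.slice[1].start
            boundary = c + np.array([c0, r0], dtype=np.float64)
        b = Bundle(id=next_id, centroid_px=(float(cx), float(cy)), area_px=area, provenance="auto", boundary=boundary)
        next_id += 1
        if area <= max_area_px and circ >= min_circularity:
            bundles.append(b)
        else:
            merged.append(b)
    return BundleSet(bundles=bundles, merged_candidates=merged)


def apply_manual_edits(bs: BundleSet, edits: EditList, pith_mask: BinaryMask | None = None) -> BundleSet:
    """Apply removals then additions, returning a new BundleSet.

    Removal ids must exist (in the accepted bundles or the merged-cluster
    candidates); addition points must fall inside the pith mask when one is
    supplied.  The operation is intentionally not idempotent: replaying an
    edit list against its own output raises on the already-removed ids.
    """
    known = {b.id: b for b in bs.bundles}
    candidates = {b.id: b for b in bs.merged_candidates}
    for rid in edits.removals:
        if rid not in known and rid not in candidates:
            raise ValueError(f"manual edit removes unknown bundle id {rid}")
    removal_set = set(edits.removals)
    kept = [b for b in bs.bundles if b.id not in removal_set]
    kept_candidates = [b for b in bs.merged_candidates if b.id not in removal_set]
    next_id = max([b.id for b in bs.bundles + bs.merged_candidates], default=0) + 1
    added = []
    for x, y in edits.additions:
        if pith_mask is not None:
            xi, yi = int(round(x)), int(round(y))
            h, w = pith_mask.shape
            if not (0 <= yi < h and 0 <= xi < w) or not pith_mask.pixels[yi, xi]:
                raise ValueError(f"manual addition ({x}, {y}) lies outside the pith")
        added.append(Bundle(id=next_id, centroid_px=(float(x), float(y)), area_px=0.0, provenance="manual"))
        next_id += 1
    return BundleSet(bundles=kept + added, merged_candidates=kept_candidates)


def read_edit_list(path: str | Path) -> EditList:
    """Parse a manual-edit file: lines ``remove,<id>`` / ``add,<x>,<y>``."""
    removals: list[int] = []
    additions: list[tuple[float, float]] = []
    with Path(path).open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0].strip().startswith("#"):
                continue
            kind = row[0].strip().lower()
            try:
                if kind == "remove" and len(row) == 2:
                    removals.append(int(row[1]))
                elif kind == "add" and len(row) == 3:
                    additions.append((float(row[1]), float(row[2])))
                else:
                    raise ValueError
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad edit line {row!r}; expected 'remove,<id>' or 'add,<x>,<y>'")
    return EditList(removals=tuple(removals), additions=tuple(additions))


def bundle_set_to_json(bs: BundleSet, path: str | Path) -> None:
    """Serialize a BundleSet (with boundaries) to JSON."""

    def encode(b: Bundle) -> dict:
        return {
            "id": b.id,
            "centroid_px": list(b.centroid_px),
            "area_px": b.area_px,
            "provenance": b.provenance,
            "boundary": None if b.boundary is None else np.asarray(b.boundary).tolist(),
        }

    payload = {
        "count": bs.count,
        "bundles": [encode(b) for b in bs.bundles],
        "merged_candidates": [encode(b) for b in bs.merged_candidates],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
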