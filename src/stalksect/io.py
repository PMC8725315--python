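"""Image/result I/O and pixel-to-millimeter spatial calibration.

All geometry in this package lives in image pixel coordinates (x rightward,
y downward, origin at the top-left pixel center, 0-based) until it is
converted to world millimeters through a :class:`Calibration`.  The
calibration is a single isotropic scalar — the number of pixels spanning one
millimeter, as obtained by imaging a scale rule at a fixed magnification.
Anisotropic pixels are out of scope.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from PIL import Image, ImageDraw

__all__ = [
    "Calibration",
    "SectionImage",
    "PhenotypeRecord",
    "read_image",
    "px_to_mm",
    "mm_to_px",
    "write_results",
    "read_results",
    "write_overlay",
]

PLANT_TYPES = ("pith-filled", "hollow")

#: fixed column order of the phenotype CSV
RESULT_COLUMNS = [
    "image_id",
    "major_d_mm",
    "minor_d_mm",
    "rind_thickness_mm",
    "bundle_count",
    "whole_area_mm2",
    "inner_area_mm2",
    "diameter_convention",
    "threshold_method",
]

_MM_COLUMNS = {
    "major_d_mm",
    "minor_d_mm",
    "rind_thickness_mm",
    "whole_area_mm2",
    "inner_area_mm2",
}


@dataclass(frozen=True)
class Calibration:
    """Isotropic pixel↔mm mapping.

    Parameters
    ----------
    px_per_mm
        Number of pixels per millimeter (> 0).
    origin_px
        Pixel coordinate mapped to the world origin.
    y_up
        If True, world y increases upward (image y is flipped on conversion),
        the convention of FE sketch planes.
    """

    px_per_mm: float
    origin_px: tuple[float, float] = (0.0, 0.0)
    y_up: bool = False

    def __post_init__(self) -> None:
        if not self.px_per_mm > 0:
            raise ValueError(f"px_per_mm must be > 0, got {self.px_per_mm}")


@dataclass
class SectionImage:
    """A calibrated 8-bit RGB raster of a stained stalk cross-section."""

    pixels: np.ndarray
    path_or_id: str
    plant_type: str
    calibration: Calibration | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be H×W×3, got shape {px.shape}")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise ValueError(f"image too small ({px.shape[0]}×{px.shape[1]}), need ≥ 32×32")
        if px.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {px.dtype}")
        if self.plant_type not in PLANT_TYPES:
            raise ValueError(f"plant_type must be one of {PLANT_TYPES}, got {self.plant_type!r}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class PhenotypeRecord:
    """The headline cross-sectional phenotypes of one section, in mm units."""

    image_id: str
    major_d_mm: float
    minor_d_mm: float
    rind_thickness_mm: float
    bundle_count: int
    whole_area_mm2: float
    inner_area_mm2: float
    diameter_convention: str = "axis-endpoint"
    threshold_method: str = "otsu"

    def __post_init__(self) -> None:
        for name in ("major_d_mm", "minor_d_mm", "rind_thickness_mm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.bundle_count < 0:
            raise ValueError("bundle_count must be ≥ 0")
        if not self.inner_area_mm2 < self.whole_area_mm2:
            raise ValueError("inner_area_mm2 must be smaller than whole_area_mm2")


# ---------------------------------------------------------------------------
# image reading


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        # linear rescale of the full 16-bit range
        return np.round(arr.astype(np.float64) * (255.0 / 65535.0)).astype(np.uint8)
    if arr.dtype == bool:
        return arr.astype(np.uint8) * 255
    raise ValueError(f"unsupported image bit depth / dtype: {arr.dtype}")


def read_image(path: str | Path, plant_type: str, calibration: Calibration | None = None) -> SectionImage:
    """Read a TIFF or PNG cross-section image into a :class:`SectionImage`.

    Grayscale sources are replicated to three channels; 16-bit sources are
    linearly rescaled to 8-bit; an alpha channel, if present, is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(str(path))
        else:
            with Image.open(path) as im:
                arr = np.asarray(im)
    except Exception as exc:  # noqa: BLE001 - surface decoder errors uniformly
        raise ValueError(f"could not decode image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    arr = _to_uint8(arr)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]
    else:
        raise ValueError(f"unsupported image layout with shape {arr.shape}: {path}")
    return SectionImage(pixels=arr, path_or_id=str(path), plant_type=plant_type, calibration=calibration)


# ---------------------------------------------------------------------------
# pixel ↔ millimeter conversion


def px_to_mm(points: Sequence[tuple[float, float]] | np.ndarray, cal: Calibration) -> np.ndarray:
    """Convert pixel coordinates to world millimeters.

    Subtracts the calibration origin, divides by ``px_per_mm``, and negates
    the y component when ``y_up`` is set (image y-down → world y-up).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    out = (pts - np.asarray(cal.origin_px, dtype=np.float64)) / cal.px_per_mm
    if cal.y_up:
        out[:, 1] = -out[:, 1]
    return out


def mm_to_px(points: Sequence[tuple[float, float]] | np.ndarray, cal: Calibration) -> np.ndarray:
    """Inverse of :func:`px_to_mm`."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64)).copy()
    if cal.y_up:
        pts[:, 1] = -pts[:, 1]
    return pts * cal.px_per_mm + np.asarray(cal.origin_px, dtype=np.float64)


# ---------------------------------------------------------------------------
# results CSV


def write_results(records: Iterable[PhenotypeRecord], path: str | Path) -> None:
    """Write phenotype records as CSV: one header row, one row per record,
    fixed column order, mm values at 4 decimal places."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULT_COLUMNS)
        for rec in records:
            row = []
            for col in RESULT_COLUMNS:
                val = getattr(rec, col)
                row.append(f"{val:.4f}" if col in _MM_COLUMNS else val)
            writer.writerow(row)


def read_results(path: str | Path) -> list[PhenotypeRecord]:
    """Parse a CSV written by :func:`write_results`."""
    records = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            records.append(
                PhenotypeRecord(
                    image_id=row["image_id"],
                    major_d_mm=float(row["major_d_mm"]),
                    minor_d_mm=float(row["minor_d_mm"]),
                    rind_thickness_mm=float(row["rind_thickness_mm"]),
                    bundle_count=int(row["bundle_count"]),
                    whole_area_mm2=float(row["whole_area_mm2"]),
                    inner_area_mm2=float(row["inner_area_mm2"]),
                    diameter_convention=row["diameter_convention"],
                    threshold_method=row["threshold_method"],
                )
            )
    return records


# ---------------------------------------------------------------------------
# QC overlay


def _draw_polyline(draw: ImageDraw.ImageDraw, poly: np.ndarray, color: tuple[int, int, int], width: int = 2) -> None:
    pts = [(float(x), float(y)) for x, y in np.asarray(poly)]
    draw.line(pts, fill=color, width=width)


def write_overlay(
    image: SectionImage,
    path: str | Path,
    boundaries=None,
    bundles=None,
    diam_segments: Sequence[np.ndarray] | None = None,
) -> None:
    """Write a PNG of the grayscale image with extracted features drawn on it.

    Outer/inner rind boundaries in red/blue, diameter segments in yellow,
    automatically detected bundle outlines in red, and manually added bundle
    points as green circles — the standard visual QC panel.
    """
    from .preprocess import to_grayscale  # local import avoids a cycle

    gray = to_grayscale(image).pixels
    canvas = Image.fromarray(gray).convert("RGB")
    draw = ImageDraw.Draw(canvas)
    if boundaries is not None:
        _draw_polyline(draw, boundaries.outer, (220, 30, 30))
        _draw_polyline(draw, boundaries.inner, (40, 80, 230))
    if diam_segments is not None:
        for seg in diam_segments:
            _draw_polyline(draw, seg, (240, 210, 40))
    if bundles is not None:
        for b in bundles.bundles:
            if b.provenance == "auto" and b.boundary is not None:
                _draw_polyline(draw, b.boundary, (220, 30, 30), width=1)
            else:
                x, y = b.centroid_px
                r = 8.0
                draw.ellipse([x - r, y - r, x + r, y + r], outline=(40, 200, 60), width=2)
    canvas.save(Path(path), format="PNG")
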