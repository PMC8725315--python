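"""End-to-end pipeline: image → binarize → segment → smooth → phenotypes.

Single-image and batch entry points with a serializable configuration.
The measurement path is entirely deterministic (no randomness anywhere in
the pipeline), so a rerun on identical inputs reproduces outputs
byte-for-byte; in a batch, per-image failures are recorded in the manifest
and never abort the run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .bundles import BundleSet, EditList, apply_manual_edits, bundle_set_to_json, detect_bundles
from .io import Calibration, PhenotypeRecord, SectionImage, read_image, write_overlay, write_results
from .morphometry import axis_diameters, feret_diameters, region_areas, rind_thickness, trace_boundaries
from .preprocess import (
    DEFAULT_SENSITIVITY,
    DEFAULT_WINDOW_FRACTION,
    binarize_adaptive,
    binarize_otsu,
    to_grayscale,
)
from .segment import SmoothingParams, segment_regions, smooth_mask

__all__ = ["PipelineConfig", "run_single", "run_batch", "analyze_section", "load_config"]

IMAGE_SUFFIXES = (".tif", ".tiff", ".png")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs, serializable into the run manifest."""

    plant_type: str = "pith-filled"
    px_per_mm: float = 100.0
    threshold: str = "auto"  # auto | otsu | adaptive
    adaptive_window: float = DEFAULT_WINDOW_FRACTION
    adaptive_sensitivity: float = DEFAULT_SENSITIVITY
    speck_frac: float = 0.001
    hole_frac: float = 0.001
    opening_radius: int = 0
    bundle_min_area: float = 25.0
    bundle_max_area_frac: float = 0.02
    bundle_min_circ: float = 0.3
    diameter_convention: str = "axis-endpoint"  # or "feret"
    detect_bundles: bool | None = None  # None = only for pith-filled sections
    write_overlays: bool = False
    write_bundle_json: bool = False
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.plant_type not in ("pith-filled", "hollow"):
            raise ValueError(f"unknown plant_type {self.plant_type!r}")
        if self.threshold not in ("auto", "otsu", "adaptive"):
            raise ValueError(f"unknown threshold method {self.threshold!r}")
        if self.diameter_convention not in ("axis-endpoint", "feret"):
            raise ValueError(f"unknown diameter convention {self.diameter_convention!r}")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be > 0")

    @property
    def smoothing(self) -> SmoothingParams:
        return SmoothingParams(
            speck_area_frac=self.speck_frac,
            hole_area_frac=self.hole_frac,
            opening_radius=self.opening_radius,
        )

    def resolve_threshold(self, plant_type: str) -> str:
        if self.threshold != "auto":
            return self.threshold
        return "adaptive" if plant_type == "pith-filled" else "otsu"


_CONFIG_FLOAT = {
    "px_per_mm",
    "adaptive_window",
    "adaptive_sensitivity",
    "speck_frac",
    "hole_frac",
    "bundle_min_area",
    "bundle_max_area_frac",
    "bundle_min_circ",
}
_CONFIG_INT = {"opening_radius"}
_CONFIG_BOOL = {"write_overlays", "write_bundle_json"}


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Read a ``key = value`` config file; keyword overrides win."""
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key in _CONFIG_FLOAT:
            values[key] = float(val)
        elif key in _CONFIG_INT:
            values[key] = int(val)
        elif key in _CONFIG_BOOL:
            values[key] = val.lower() in ("1", "true", "yes", "on")
        elif key == "detect_bundles":
            values[key] = None if val.lower() == "auto" else val.lower() in ("1", "true", "yes", "on")
        else:
            values[key] = val
    values.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**values)


def analyze_section(
    image: SectionImage, config: PipelineConfig, edits: EditList | None = None
) -> tuple[PhenotypeRecord, dict]:
    """Run the measurement pipeline on an in-memory image.

    Returns the phenotype record plus the intermediate artifacts
    (boundaries, segmentation, bundle set) for overlays and export.
    """
    cal = image.calibration or Calibration(px_per_mm=config.px_per_mm)
    plant_type = image.plant_type
    method = config.resolve_threshold(plant_type)

    gray = to_grayscale(image)
    if method == "otsu":
        binary = binarize_otsu(gray)
    else:
        binary = binarize_adaptive(gray, config.adaptive_window, config.adaptive_sensitivity)
    cleaned = smooth_mask(binary, config.smoothing)
    seg = segment_regions(cleaned, plant_type)

    boundaries = trace_boundaries(seg)
    if config.diameter_convention == "feret":
        diam = feret_diameters(boundaries, cal)
    else:
        diam = axis_diameters(boundaries, cal)
    thick = rind_thickness(boundaries, cal)
    whole_mm2, inner_mm2 = region_areas(seg, cal)

    want_bundles = config.detect_bundles
    if want_bundles is None:
        want_bundles = plant_type == "pith-filled"
    if want_bundles:
        pith_area = seg.inner_mask.pixels.sum()
        bundle_set = detect_bundles(
            cleaned,
            seg.inner_mask,
            min_area_px=config.bundle_min_area,
            max_area_px=config.bundle_max_area_frac * float(pith_area),
            min_circularity=config.bundle_min_circ,
        )
    else:
        bundle_set = BundleSet()
    if edits is not None:
        bundle_set = apply_manual_edits(bundle_set, edits, seg.inner_mask)

    record = PhenotypeRecord(
        image_id=Path(image.path_or_id).name,
        major_d_mm=diam.major_mm,
        minor_d_mm=diam.minor_mm,
        rind_thickness_mm=thick.mean_mm,
        bundle_count=bundle_set.count,
        whole_area_mm2=whole_mm2,
        inner_area_mm2=inner_mm2,
        diameter_convention=diam.convention,
        threshold_method=method,
    )
    artifacts = {
        "gray": gray,
        "binary": binary,
        "cleaned": cleaned,
        "segmentation": seg,
        "boundaries": boundaries,
        "diameters": diam,
        "thickness": thick,
        "bundles": bundle_set,
    }
    return record, artifacts


def run_single(
    image_path: str | Path, config: PipelineConfig, edits: EditList | None = None
) -> PhenotypeRecord:
    """Process one image file; optionally write overlay / bundle artifacts."""
    image = read_image(image_path, config.plant_type, Calibration(px_per_mm=config.px_per_mm))
    record, artifacts = analyze_section(image, config, edits)
    out_dir = Path(config.out_dir)
    stem = Path(image_path).stem
    if config.write_overlays:
        out_dir.mkdir(parents=True, exist_ok=True)
        diam = artifacts["diameters"]
        write_overlay(
            image,
            out_dir / f"{stem}_overlay.png",
            boundaries=artifacts["boundaries"],
            bundles=artifacts["bundles"],
            diam_segments=[diam.major_endpoints_px, diam.minor_endpoints_px],
        )
    if config.write_bundle_json:
        out_dir.mkdir(parents=True, exist_ok=True)
        bundle_set_to_json(artifacts["bundles"], out_dir / f"{stem}_bundles.json")
    return record


def run_batch(input_dir: str | Path, config: PipelineConfig) -> tuple[list[PhenotypeRecord], dict]:
    """Process every TIFF/PNG in a directory in sorted order.

    Writes ``phenotypes.csv`` and ``manifest.json`` into the configured
    output directory and returns (records, manifest).
    """
    input_dir = Path(input_dir)
    paths = sorted(p for p in input_dir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
    if not paths:
        raise ValueError(f"no TIFF/PNG images found in {input_dir}")
    records: list[PhenotypeRecord] = []
    statuses: dict[str, dict] = {}
    for path in paths:
        try:
            rec = run_single(path, config)
        except Exception as exc:  # noqa: BLE001 - per-image failures are data
            statuses[path.name] = {"status": "failed", "reason": str(exc)}
            continue
        records.append(rec)
        statuses[path.name] = {"status": "ok"}
    manifest = {
        "software": f"stalksect {__version__}",
        "config": dataclasses.asdict(config),
        "images": statuses,
    }
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_results(records, out_dir / "phenotypes.csv")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return records, manifest
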