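"""Region segmentation and mask smoothing.

After binarization the stained rind is the dominant dark component; the
pith (or the lumen of a hollow stem) is the large background hole it
encloses.  Segmentation keeps the largest foreground component as the
cross-section, fills it to obtain the whole-section support, and takes its
largest enclosed hole as the inner (pith/lumen) region.  Smoothing clears
the small spurious clusters that segmentation reveals — small bright
specks inside the rind (holes) and small dark specks inside the pith
(islands) — by area gating, without the boundary erosion a structuring
element sweep would cause.

Connectivity convention: 8-connected foreground, 4-connected holes (the
standard complementary pairing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, opening

from .preprocess import BinaryMask

__all__ = [
    "SegmentedSection",
    "SmoothingParams",
    "segment_regions",
    "fill_holes",
    "remove_specks",
    "open_mask",
    "smooth_mask",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class SegmentedSection:
    """Paired masks for the whole cross-section and its inner region."""

    whole_mask: BinaryMask
    inner_mask: BinaryMask
    plant_type: str

    def __post_init__(self) -> None:
        if self.whole_mask.shape != self.inner_mask.shape:
            raise ValueError("whole and inner masks must share a shape")
        if not np.all(self.whole_mask.pixels[self.inner_mask.pixels]):
            raise ValueError("inner_mask must be a subset of whole_mask")

    @property
    def areas_px(self) -> tuple[int, int]:
        return int(self.whole_mask.pixels.sum()), int(self.inner_mask.pixels.sum())


@dataclass(frozen=True)
class SmoothingParams:
    """Area-fraction gates for speck/hole removal, plus optional opening.

    Fractions are relative to the whole-section area; defaults clear
    segmentation debris at the scale seen in stained sections without
    touching real anatomy.  ``opening_radius`` defaults to 0 (off): a
    structuring-element sweep shrinks boundaries and would bias the
    diameter and rind-thickness measurements.
    """

    speck_area_frac: float = 0.001
    hole_area_frac: float = 0.001
    opening_radius: int = 0

    def __post_init__(self) -> None:
        for name in ("speck_area_frac", "hole_area_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 0.05:
                raise ValueError(f"{name} must lie in [0, 0.05], got {v}")
        if self.opening_radius < 0:
            raise ValueError("opening_radius must be ≥ 0")


def _largest_component(mask: np.ndarray, structure: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        raise ValueError("mask contains no foreground component")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def segment_regions(mask: BinaryMask, plant_type: str) -> SegmentedSection:
    """Split a binary image into whole-section and inner-region masks.

    The whole mask is the largest 8-connected foreground component with all
    enclosed holes filled; the inner mask is the largest hole that component
    encloses — the pith support of a pith-filled stem (bundle spots and all)
    or the lumen of a hollow one.
    """
    main = _largest_component(mask.pixels, _STRUCT8)
    whole = ndimage.binary_fill_holes(main, structure=_STRUCT4)
    holes = whole & ~main
    if not holes.any():
        raise ValueError(
            "the main component encloses no hole — no pith/lumen detected; review the threshold settings"
        )
    inner = _largest_component(holes, _STRUCT4)
    # the inner region may itself enclose foreground (bundles); keep it solid
    inner = ndimage.binary_fill_holes(inner, structure=_STRUCT4)
    return SegmentedSection(
        whole_mask=BinaryMask(pixels=whole, threshold_used=mask.threshold_used),
        inner_mask=BinaryMask(pixels=inner, threshold_used=mask.threshold_used),
        plant_type=plant_type,
    )


def fill_holes(mask: BinaryMask, max_area_px: float) -> BinaryMask:
    """Fill enclosed background holes of area ≤ ``max_area_px``.

    4-connected background components that do not touch the image border
    and fit under the gate become foreground; larger holes (a lumen, a
    pith) are preserved.  Foreground never shrinks.
    """
    if max_area_px < 0:
        raise ValueError("max_area_px must be ≥ 0")
    if max_area_px == 0:
        return BinaryMask(pixels=mask.pixels.copy(), threshold_used=mask.threshold_used)
    bg = ~mask.pixels
    labels, n = ndimage.label(bg, structure=_STRUCT4)
    if n == 0:
        return BinaryMask(pixels=mask.pixels.copy(), threshold_used=mask.threshold_used)
    border_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    counts = np.bincount(labels.ravel())
    fill_ids = np.ones(n + 1, dtype=bool)
    fill_ids[0] = False
    fill_ids[border_labels] = False
    fill_ids[counts > max_area_px] = False
    out = mask.pixels | fill_ids[labels]
    return BinaryMask(pixels=out, threshold_used=mask.threshold_used)


def remove_specks(mask: BinaryMask, max_area_px: float) -> BinaryMask:
    """Delete 8-connected foreground components of area ≤ ``max_area_px``.

    Foreground never grows.
    """
    if max_area_px < 0:
        raise ValueError("max_area_px must be ≥ 0")
    if max_area_px == 0:
        return BinaryMask(pixels=mask.pixels.copy(), threshold_used=mask.threshold_used)
    labels, n = ndimage.label(mask.pixels, structure=_STRUCT8)
    if n == 0:
        return BinaryMask(pixels=mask.pixels.copy(), threshold_used=mask.threshold_used)
    counts = np.bincount(labels.ravel())
    keep = counts > max_area_px
    keep[0] = False
    return BinaryMask(pixels=keep[labels], threshold_used=mask.threshold_used)


def open_mask(mask: BinaryMask, radius_px: int) -> BinaryMask:
    """Morphological opening by a disk structuring element; radius 0 = identity."""
    if radius_px < 0:
        raise ValueError("radius_px must be ≥ 0")
    if radius_px == 0:
        return BinaryMask(pixels=mask.pixels.copy(), threshold_used=mask.threshold_used)
    opened = opening(mask.pixels, disk(radius_px)).astype(bool)
    return BinaryMask(pixels=opened, threshold_used=mask.threshold_used)


def smooth_mask(mask: BinaryMask, params: SmoothingParams, reference_area_px: float | None = None) -> BinaryMask:
    """The standard smoothing pipeline: speck removal, hole filling, and
    (optionally) opening, with area gates scaled by ``reference_area_px``
    (defaults to the filled area of the largest component)."""
    if reference_area_px is None:
        main = _largest_component(mask.pixels, _STRUCT8)
        reference_area_px = float(ndimage.binary_fill_holes(main, structure=_STRUCT4).sum())
    out = remove_specks(mask, params.speck_area_frac * reference_area_px)
    out = fill_holes(out, params.hole_area_frac * reference_area_px)
    out = open_mask(out, params.opening_radius)
    return out
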