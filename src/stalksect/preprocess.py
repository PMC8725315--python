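"""Grayscale conversion and binarization.

Foreground polarity is fixed package-wide: foreground = the *dark* pixel
class, i.e. stained / highly lignified tissue (rind, vascular bundles).
Hollow stems are well served by a global Otsu threshold (their histogram is
cleanly bimodal); pith-filled stems use a local adaptive threshold, which
tolerates the gentler rind/pith/bundle contrast and uneven illumination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import SectionImage

__all__ = [
    "GrayImage",
    "BinaryMask",
    "to_grayscale",
    "binarize_otsu",
    "binarize_adaptive",
    "otsu_threshold",
]

#: R/G/B luminance weights (ITU-R BT.601)
LUMA_WEIGHTS = (0.2989, 0.5870, 0.1140)

#: default local-mean window as a fraction of min(H, W).  The window must be
#: wider than the thickest single-intensity structure in the image (the rind
#: band), otherwise windows wholly inside it see no second class and the
#: relative threshold punches holes through it.
DEFAULT_WINDOW_FRACTION = 0.5
DEFAULT_SENSITIVITY = 0.5


@dataclass
class GrayImage:
    """Single-channel 8-bit image derived from a :class:`SectionImage`."""

    pixels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"GrayImage pixels must be H×W, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"GrayImage pixels must be uint8, got {px.dtype}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """Boolean mask; True marks the dark (stained/lignified) class."""

    pixels: np.ndarray
    threshold_used: str = ""
    foreground_meaning: str = "stained/lignified tissue (dark class)"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.dtype != bool:
            raise ValueError("BinaryMask pixels must be a 2-D boolean array")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def to_grayscale(img: SectionImage) -> GrayImage:
    """Luminance conversion with fixed weights, rounded half-up to 8-bit."""
    rgb = img.pixels.astype(np.float64)
    lum = rgb[:, :, 0] * LUMA_WEIGHTS[0] + rgb[:, :, 1] * LUMA_WEIGHTS[1] + rgb[:, :, 2] * LUMA_WEIGHTS[2]
    return GrayImage(pixels=np.floor(lum + 0.5).astype(np.uint8), provenance=img.path_or_id)


def otsu_threshold(gray: np.ndarray) -> int:
    """Otsu's threshold over gray levels 0..255.

    Returns the level t* minimizing the intensity within-class variance of
    the split {≤ t*} / {> t*}; ties broken toward the smaller threshold.
    """
    hist = np.bincount(gray.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)  # pixels at level ≤ t
    w1 = total - w0
    sum0 = np.cumsum(hist * levels)
    sum_total = sum0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = sum0 / w0
        mu1 = (sum_total - sum0) / w1
    # maximize between-class variance == minimize within-class variance
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    if not np.isfinite(sigma_b).any():
        raise ValueError("degenerate histogram: image has a single gray level, cannot threshold")
    return int(np.argmax(sigma_b))  # argmax takes the first (smallest) tie


def binarize_otsu(g: GrayImage) -> BinaryMask:
    """Global Otsu binarization; dark pixels (≤ t*) become foreground."""
    t = otsu_threshold(g.pixels)
    return BinaryMask(pixels=g.pixels <= t, threshold_used=f"otsu t*={t}")


def _sensitivity_factor(sensitivity: float) -> float:
    # factor 1 + offset(s): 0.70 at s=0, 0.85 at the 0.5 default, 1.00 at s=1.
    # Higher sensitivity raises the local threshold, admitting more pixels
    # into the dark foreground; the sub-unity default keeps uniform regions
    # from splitting on noise alone.
    return 0.70 + 0.30 * sensitivity


def binarize_adaptive(
    g: GrayImage,
    window_fraction: float = DEFAULT_WINDOW_FRACTION,
    sensitivity: float = DEFAULT_SENSITIVITY,
) -> BinaryMask:
    """Local-mean adaptive binarization; dark pixels become foreground.

    Each pixel is compared with the mean of a square window of side
    ``ceil(window_fraction · min(H, W))`` (forced odd; reflective border
    padding), scaled by a sensitivity factor below/at unity.  A pixel whose
    value is ≤ its scaled local mean is classified foreground.
    """
    if not 0 < window_fraction <= 1:
        raise ValueError(f"window_fraction must be in (0, 1], got {window_fraction}")
    if not 0 <= sensitivity <= 1:
        raise ValueError(f"sensitivity must be in [0, 1], got {sensitivity}")
    h, w = g.pixels.shape
    side = int(np.ceil(window_fraction * min(h, w)))
    if side % 2 == 0:
        side += 1
    if side < 3:
        raise ValueError(f"adaptive window of {side} px is too small (< 3 px)")
    local_mean = ndimage.uniform_filter(g.pixels.astype(np.float64), size=side, mode="reflect")
    thresh = local_mean * _sensitivity_factor(sensitivity)
    return BinaryMask(
        pixels=g.pixels.astype(np.float64) <= thresh,
        threshold_used=f"adaptive window={side}px sensitivity={sensitivity}",
    )
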