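"""Seeded synthetic cross-section phantoms with exact ground truth.

A phantom emulates a stained stalk cross-section as imaged under a
stereo microscope: a dark (lignified, stain-retaining) rind annulus on a
light background, enclosing either a lighter pith speckled with dark
vascular-bundle disks (pith-filled species such as maize and sorghum) or a
background-bright lumen (hollow species such as wheat and Arabidopsis).
Speck clusters — small light ellipses inside the rind and small dark
ellipses inside the pith/lumen — mimic the unwanted pixel clusters that
segmentation reveals in real sections, and i.i.d. Gaussian noise exercises
the thresholding stage.

Regions are rasterized with hard edges (no anti-aliasing), so the pixel
membership of every region is exact and recovery tests need no tolerance
for edge blending.  Every phenotype the measurement pipeline reports is
computed analytically from the generating parameters and returned as
:class:`GroundTruth`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

from .io import Calibration, SectionImage

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "make_phantom",
    "make_batch",
    "make_recovery_sweep",
    "maize_like_spec",
    "wheat_like_spec",
]

_PLACEMENT_RETRY_CAP = 10_000


@dataclass(frozen=True)
class PhantomSpec:
    """Generating parameters of one synthetic cross-section.

    Semi-axes and all lengths are in pixels, intensities in 0–255 gray
    levels.  The outer and inner ellipses share ``center`` and ``rotation``
    (concentric rind annulus).  Intensity classes that meet across a
    boundary must be separated by at least 4× ``noise_sd`` so that
    thresholding is well-posed.
    """

    plant_type: str = "pith-filled"
    outer_semi_axes: tuple[float, float] = (300.0, 260.0)
    inner_semi_axes: tuple[float, float] = (240.0, 208.0)
    rotation: float = 0.0
    center: tuple[float, float] | None = None  # None = image center
    n_bundles: int = 20
    bundle_radius_range: tuple[float, float] = (9.0, 13.0)
    bundle_min_separation: float = 32.0
    rind_intensity: int = 60
    pith_intensity: int = 180
    background_intensity: int = 235
    bundle_intensity: int = 50
    speck_count: int = 16
    speck_area_range: tuple[float, float] = (6.0, 60.0)
    noise_sd: float = 6.0
    image_size: tuple[int, int] = (680, 680)  # (width, height)
    px_per_mm: float = 100.0

    def __post_init__(self) -> None:
        a, b = self.outer_semi_axes
        ai, bi = self.inner_semi_axes
        if not (a >= b > 0):
            raise ValueError(f"outer semi-axes must satisfy a ≥ b > 0, got {(a, b)}")
        if not (ai >= bi > 0):
            raise ValueError(f"inner semi-axes must satisfy a_in ≥ b_in > 0, got {(ai, bi)}")
        if not (ai < a and bi < b):
            raise ValueError(
                f"inner ellipse must be strictly inside the outer (a_in < a and b_in < b), got {(ai, bi)} vs {(a, b)}"
            )
        if self.plant_type not in ("pith-filled", "hollow"):
            raise ValueError(f"plant_type must be 'pith-filled' or 'hollow', got {self.plant_type!r}")
        if self.plant_type == "hollow" and self.n_bundles > 0:
            raise ValueError("hollow phantoms carry no pith bundles; set n_bundles=0")
        if self.n_bundles < 0 or self.speck_count < 0:
            raise ValueError("n_bundles and speck_count must be ≥ 0")
        r_lo, r_hi = self.bundle_radius_range
        if not (0 < r_lo <= r_hi):
            raise ValueError(f"bundle_radius_range must satisfy 0 < lo ≤ hi, got {self.bundle_radius_range}")
        if self.n_bundles > 1 and self.bundle_min_separation < 2 * r_hi:
            raise ValueError(
                "bundle_min_separation must be ≥ 2× the maximum bundle radius "
                f"(non-overlap), got {self.bundle_min_separation} < {2 * r_hi}"
            )
        s_lo, s_hi = self.speck_area_range
        if not (1 <= s_lo <= s_hi):
            raise ValueError(f"speck_area_range must satisfy 1 ≤ lo ≤ hi, got {self.speck_area_range}")
        for name in ("rind_intensity", "pith_intensity", "background_intensity", "bundle_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must be an 8-bit gray level, got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        self._check_contrast()
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be > 0")
        self._check_fits()

    def _check_contrast(self) -> None:
        # only classes that meet across a boundary need to be separable
        if self.plant_type == "pith-filled":
            pairs = [
                ("rind_intensity", "pith_intensity"),
                ("rind_intensity", "background_intensity"),
                ("pith_intensity", "background_intensity"),
                ("bundle_intensity", "pith_intensity"),
            ]
        else:
            pairs = [("rind_intensity", "background_intensity")]
        for p, q in pairs:
            gap = abs(getattr(self, p) - getattr(self, q))
            if gap < 4 * self.noise_sd:
                raise ValueError(
                    f"intensity gap |{p} − {q}| = {gap} is below 4×noise_sd = {4 * self.noise_sd}; "
                    "thresholding would be ill-posed"
                )

    def _check_fits(self) -> None:
        w, h = self.image_size
        cx, cy = self.effective_center
        ex, ey = _ellipse_extents(*self.outer_semi_axes, self.rotation)
        if cx - ex < 10 or cy - ey < 10 or cx + ex > w - 1 - 10 or cy + ey > h - 1 - 10:
            raise ValueError(
                f"outer ellipse (extents ±{ex:.1f}, ±{ey:.1f} about center {(cx, cy)}) does not fit "
                f"inside a {w}×{h} image with a 10-px margin"
            )

    @property
    def effective_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        w, h = self.image_size
        return ((w - 1) / 2.0, (h - 1) / 2.0)


@dataclass(frozen=True)
class GroundTruth:
    """Analytically known phenotypes of a phantom, in the units the
    measurement pipeline reports (mm; counts; px for bundle centers).

    ``true_major_d``/``true_minor_d`` follow the caliper (Feret) convention
    — the ellipse axes 2a and 2b, invariant under rotation.  The
    axis-endpoint convention (centroid chords along the image axes) is
    reported separately since it depends on the section's orientation.
    """

    true_major_d: float
    true_minor_d: float
    true_axis_major_d: float
    true_axis_minor_d: float
    true_rind_thickness: float
    true_bundle_count: int
    true_bundle_centers: tuple[tuple[float, float], ...]
    true_whole_area: float
    true_inner_area: float


# ---------------------------------------------------------------------------
# analytic geometry helpers


def _ellipse_extents(a: float, b: float, rotation_deg: float) -> tuple[float, float]:
    th = math.radians(rotation_deg)
    ex = math.hypot(a * math.cos(th), b * math.sin(th))
    ey = math.hypot(a * math.sin(th), b * math.cos(th))
    return ex, ey


def _ellipse_mask(shape_hw: tuple[int, int], center: tuple[float, float], a: float, b: float, rotation_deg: float) -> np.ndarray:
    """Exact (hard-edged) pixel membership of a rotated ellipse."""
    h, w = shape_hw
    yy, xx = np.mgrid[0:h, 0:w]
    th = math.radians(rotation_deg)
    dx = xx - center[0]
    dy = yy - center[1]
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _ellipse_points(center: tuple[float, float], a: float, b: float, rotation_deg: float, n: int) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    th = math.radians(rotation_deg)
    u = a * np.cos(t)
    v = b * np.sin(t)
    x = center[0] + u * math.cos(th) - v * math.sin(th)
    y = center[1] + u * math.sin(th) + v * math.cos(th)
    return np.column_stack([x, y])


def _mean_boundary_gap(spec: PhantomSpec, n_outer: int = 1024, n_inner: int = 4096) -> float:
    """Mean shortest distance from the outer ellipse to the inner ellipse, px.

    Dense parametric sampling with point-to-polyline distances; exact for
    concentric circles (R_out − R_in) and converges quickly for ellipses.
    """
    import shapely

    c = spec.effective_center
    outer = _ellipse_points(c, *spec.outer_semi_axes, spec.rotation, n_outer)
    inner = _ellipse_points(c, *spec.inner_semi_axes, spec.rotation, n_inner)
    ring = shapely.LinearRing(inner)
    dists = shapely.distance(shapely.points(outer), ring)
    return float(np.mean(dists))


def _axis_chords(spec: PhantomSpec) -> tuple[float, float]:
    """Full chord lengths (px) through the center along image x and y."""
    a, b = spec.outer_semi_axes
    th = math.radians(spec.rotation)

    def radius(phi: float) -> float:
        psi = phi - th
        return a * b / math.hypot(b * math.cos(psi), a * math.sin(psi))

    return 2 * radius(0.0), 2 * radius(math.pi / 2)


def _ground_truth(spec: PhantomSpec, bundle_centers: np.ndarray) -> GroundTruth:
    a, b = spec.outer_semi_axes
    ai, bi = spec.inner_semi_axes
    s = spec.px_per_mm
    chord_x, chord_y = _axis_chords(spec)
    return GroundTruth(
        true_major_d=2 * a / s,
        true_minor_d=2 * b / s,
        true_axis_major_d=max(chord_x, chord_y) / s,
        true_axis_minor_d=min(chord_x, chord_y) / s,
        true_rind_thickness=_mean_boundary_gap(spec) / s,
        true_bundle_count=int(len(bundle_centers)),
        true_bundle_centers=tuple((float(x), float(y)) for x, y in bundle_centers),
        true_whole_area=math.pi * a * b / s**2,
        true_inner_area=math.pi * ai * bi / s**2,
    )


# ---------------------------------------------------------------------------
# stochastic placement


def _place_points(
    rng: np.random.Generator,
    allowed: np.ndarray,
    n: int,
    margin: float,
    min_separation: float,
    what: str,
) -> np.ndarray:
    """Rejection-sample ``n`` pixel centers inside ``allowed`` with clearance
    ``margin`` from its boundary and pairwise separation ``min_separation``."""
    if n == 0:
        return np.empty((0, 2))
    edt = ndimage.distance_transform_edt(allowed)
    candidates = np.argwhere(edt >= margin)  # (row, col)
    if len(candidates) == 0:
        raise RuntimeError(f"no room to place {what}: clearance {margin:.1f} px exceeds the region")
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > _PLACEMENT_RETRY_CAP:
            raise RuntimeError(
                f"could not place {n} {what} after {_PLACEMENT_RETRY_CAP} attempts "
                f"({len(placed)} placed); loosen separation or enlarge the region"
            )
        idx = rng.integers(0, len(candidates))
        r, c = candidates[idx]
        pt = np.array([float(c), float(r)])  # (x, y)
        if all(np.hypot(*(pt - p)) >= min_separation for p in placed):
            placed.append(pt)
    return np.array(placed)


def _draw_speck(
    gray: np.ndarray, rng: np.random.Generator, center: tuple[float, float], area: float, intensity: int
) -> None:
    aspect = rng.uniform(0.5, 1.0)
    sa = math.sqrt(area / (math.pi * aspect))
    sb = aspect * sa
    rot = rng.uniform(0.0, 180.0)
    ext = sa + 1
    x0 = max(0, int(center[0] - ext))
    x1 = min(gray.shape[1], int(center[0] + ext) + 2)
    y0 = max(0, int(center[1] - ext))
    y1 = min(gray.shape[0], int(center[1] + ext) + 2)
    sub = _ellipse_mask((y1 - y0, x1 - x0), (center[0] - x0, center[1] - y0), sa, sb, rot)
    gray[y0:y1, x0:x1][sub] = intensity


# ---------------------------------------------------------------------------
# generation


def make_phantom(spec: PhantomSpec, seed: int) -> tuple[SectionImage, GroundTruth]:
    """Render a phantom cross-section and its analytic ground truth.

    The same (spec, seed) pair always yields a bit-identical image.
    """
    rng = np.random.default_rng(seed)
    w, h = spec.image_size
    c = spec.effective_center

    outer = _ellipse_mask((h, w), c, *spec.outer_semi_axes, spec.rotation)
    inner = _ellipse_mask((h, w), c, *spec.inner_semi_axes, spec.rotation)
    rind = outer & ~inner

    gray = np.full((h, w), spec.background_intensity, dtype=np.float64)
    gray[rind] = spec.rind_intensity
    if spec.plant_type == "pith-filled":
        gray[inner] = spec.pith_intensity
    # hollow: the lumen keeps the background intensity

    # vascular bundles: disks wholly inside the pith, pairwise separated
    r_lo, r_hi = spec.bundle_radius_range
    bundle_centers = _place_points(
        rng, inner, spec.n_bundles, margin=r_hi + 2, min_separation=spec.bundle_min_separation, what="bundles"
    )
    bundle_mask = np.zeros((h, w), dtype=bool)
    bundle_radii = rng.uniform(r_lo, r_hi, size=len(bundle_centers))
    for (bx, by), br in zip(bundle_centers, bundle_radii):
        bundle_mask |= _ellipse_mask((h, w), (bx, by), br, br, 0.0)
    gray[bundle_mask] = spec.bundle_intensity

    # specks: light inside the rind, dark inside the pith/lumen (opposite class)
    if spec.speck_count > 0:
        s_lo, s_hi = spec.speck_area_range
        speck_ext = math.sqrt(s_hi / (math.pi * 0.5)) + 2  # widest possible speck
        n_rind = spec.speck_count // 2
        n_inner = spec.speck_count - n_rind
        light = spec.pith_intensity if spec.plant_type == "pith-filled" else spec.background_intensity
        # thin rinds cannot host a speck with clearance; those specks move to the pith
        rind_edt_max = ndimage.distance_transform_edt(rind).max()
        if rind_edt_max <= speck_ext:
            n_inner += n_rind
            n_rind = 0
        rind_pts = _place_points(rng, rind, n_rind, margin=speck_ext, min_separation=2 * speck_ext, what="rind specks")
        for pt in rind_pts:
            _draw_speck(gray, rng, tuple(pt), rng.uniform(s_lo, s_hi), light)
        inner_free = inner & ~ndimage.binary_dilation(bundle_mask, iterations=2)
        inner_pts = _place_points(
            rng, inner_free, n_inner, margin=speck_ext, min_separation=2 * speck_ext, what="pith specks"
        )
        for pt in inner_pts:
            _draw_speck(gray, rng, tuple(pt), rng.uniform(s_lo, s_hi), spec.rind_intensity)

    rgb = np.repeat(gray[:, :, None], 3, axis=2)
    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sd, size=rgb.shape)
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)

    image = SectionImage(
        pixels=rgb,
        path_or_id=f"phantom-{spec.plant_type}-seed{seed}",
        plant_type=spec.plant_type,
        calibration=Calibration(px_per_mm=spec.px_per_mm),
    )
    return image, _ground_truth(spec, bundle_centers)


_INT_FIELDS = {"n_bundles", "speck_count"}
_PAIR_FIELDS = {"outer_semi_axes", "inner_semi_axes", "bundle_radius_range", "speck_area_range", "image_size", "center"}


def make_batch(
    base_spec: PhantomSpec,
    n: int,
    jitter: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> list[tuple[SectionImage, GroundTruth]]:
    """Generate ``n`` phantoms with spec fields drawn uniformly within
    ``jitter`` ranges (field name → (low, high)); reproducible for a fixed
    seed.  With ``n=1`` and no jitter the result equals
    ``make_phantom(base_spec, derived_seed)``.

    Besides scalar spec fields, the pseudo-field ``size_scale`` is
    accepted: a multiplicative factor applied to both semi-axis pairs,
    i.e. diameter jitter at a fixed rind fraction.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    jitter = dict(jitter or {})
    for name, rng_pair in jitter.items():
        if name != "size_scale" and (not hasattr(base_spec, name) or name in _PAIR_FIELDS):
            raise ValueError(f"cannot jitter field {name!r}")
        lo, hi = rng_pair
        if lo > hi:
            raise ValueError(f"invalid jitter range for {name!r}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    out = []
    for i in range(n):
        draws = {}
        for name, (lo, hi) in jitter.items():
            if name in _INT_FIELDS:
                draws[name] = int(rng.integers(int(lo), int(hi) + 1))
            else:
                draws[name] = float(rng.uniform(lo, hi))
        scale = draws.pop("size_scale", None)
        if scale is not None:
            a, b = base_spec.outer_semi_axes
            ai, bi = base_spec.inner_semi_axes
            draws["outer_semi_axes"] = (a * scale, b * scale)
            draws["inner_semi_axes"] = (ai * scale, bi * scale)
        spec_i = replace(base_spec, **draws) if draws else base_spec
        out.append(make_phantom(spec_i, int(child_seeds[i])))
    return out


# ---------------------------------------------------------------------------
# reference specs and the recovery sweep


def maize_like_spec(**overrides) -> PhantomSpec:
    """A pith-filled phantom resembling a stained maize section."""
    return PhantomSpec(**overrides) if overrides else PhantomSpec()


def wheat_like_spec(**overrides) -> PhantomSpec:
    """A hollow phantom resembling a stained wheat section."""
    base = dict(
        plant_type="hollow",
        outer_semi_axes=(160.0, 150.0),
        inner_semi_axes=(120.0, 112.0),
        n_bundles=0,
        speck_count=8,
        image_size=(400, 400),
        px_per_mm=160.0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def make_recovery_sweep(n: int, seed: int) -> list[tuple[PhantomSpec, SectionImage, GroundTruth]]:
    """The standard phantom sweep used for end-to-end recovery validation.

    Conditions: outer diameters drawn uniformly over 2–20 mm with the
    magnification (px/mm) varied so the outer radius spans roughly 100–220
    px (as a microscope operator would switch lenses); aspect ratio 0.85–1;
    rind radial fraction 10–35 %; random rotation; roughly 60 % pith-filled
    sections with up to 40 vascular bundles (capped by what physically fits
    at the drawn pith size) and 40 % hollow sections; speck noise on.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        d_mm = rng.uniform(2.0, 20.0)
        r_px = rng.uniform(100.0, 220.0)
        px_per_mm = r_px / (d_mm / 2.0)
        aspect = rng.uniform(0.85, 1.0)
        a, b = r_px, aspect * r_px
        rind_frac = rng.uniform(0.10, 0.35)
        ai, bi = a * (1 - rind_frac), b * (1 - rind_frac)
        rotation = rng.uniform(0.0, 180.0)
        side = int(2 * (a + 16))
        hollow = rng.uniform() < 0.4
        # bundle disks sized so they clear the speck-removal threshold
        # (0.1 % of whole area) yet stay below the per-bundle area cap
        # (2 % of pith area), across the whole diameter range
        r_lo = 0.05 * math.sqrt(a * b)
        r_hi = min(0.10 * math.sqrt(ai * bi), 1.5 * r_lo)
        sep = 2 * r_hi + 4.0
        if hollow:
            n_bundles = 0
        else:
            # hexagonal-packing style feasibility cap for rejection sampling
            pith_area = math.pi * (ai - r_hi - 2) * (bi - r_hi - 2) if min(ai, bi) > r_hi + 2 else 0.0
            cap = int(0.5 * pith_area / sep**2)
            n_bundles = int(min(rng.integers(0, 41), max(cap, 0)))
        speck_hi = max(5.0, 0.6 * 0.001 * math.pi * a * b)
        spec = PhantomSpec(
            plant_type="hollow" if hollow else "pith-filled",
            outer_semi_axes=(a, b),
            inner_semi_axes=(ai, bi),
            rotation=rotation,
            n_bundles=n_bundles,
            bundle_radius_range=(r_lo, r_hi),
            bundle_min_separation=sep,
            speck_count=10,
            speck_area_range=(4.0, speck_hi),
            image_size=(side, side),
            px_per_mm=px_per_mm,
        )
        img, truth = make_phantom(spec, int(rng.integers(0, 2**31 - 1)))
        out.append((spec, img, truth))
    return out
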