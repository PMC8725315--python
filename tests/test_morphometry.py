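"""Boundary tracing, diameters, rind thickness, areas — against geometric oracles."""

import math

import numpy as np
import pytest

from stalksect import (
    Calibration,
    axis_diameters,
    feret_diameters,
    region_areas,
    rind_thickness,
    trace_boundaries,
)
from stalksect.morphometry import RindBoundaries, signed_area
from stalksect.preprocess import BinaryMask
from stalksect.segment import SegmentedSection

from conftest import disk_mask

CAL = Calibration(px_per_mm=100.0)


def _ellipse(shape, center, a, b, rot_deg=0.0):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    th = math.radians(rot_deg)
    dx, dy = xx - center[0], yy - center[1]
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1


def _seg(whole, inner):
    return SegmentedSection(
        whole_mask=BinaryMask(pixels=whole), inner_mask=BinaryMask(pixels=inner), plant_type="hollow"
    )


def _annulus_boundaries(r_out=300, r_in=240, center=(340, 340), shape=(680, 680), inner_center=None):
    whole = disk_mask(shape, center, r_out)
    inner = disk_mask(shape, inner_center or center, r_in)
    return trace_boundaries(_seg(whole, inner))


# --- tracing -----------------------------------------------------------------


def test_traced_circle_radii_match_spec():
    b = _annulus_boundaries()
    for poly, r_true in ((b.outer, 300.0), (b.inner, 240.0)):
        radii = np.hypot(poly[:, 0] - 340, poly[:, 1] - 340)
        assert np.max(np.abs(radii - r_true)) <= 1.0
    assert b.centroid_px == pytest.approx((340.0, 340.0), abs=0.05)


def test_outer_polygon_area_matches_pixel_count():
    whole = disk_mask((680, 680), (340, 340), 300)
    inner = disk_mask((680, 680), (340, 340), 240)
    b = trace_boundaries(_seg(whole, inner))
    assert abs(signed_area(b.outer)) == pytest.approx(whole.sum(), rel=0.02)


def test_orientation_canonicalization_round_trip():
    b = _annulus_boundaries()
    reversed_then_fixed = RindBoundaries(outer=b.outer[::-1], inner=b.inner, centroid_px=b.centroid_px)
    assert np.allclose(reversed_then_fixed.outer, b.outer)
    assert signed_area(b.outer) > 0 and signed_area(b.inner) > 0


def test_tiny_mask_rejected():
    whole = np.zeros((64, 64), dtype=bool)
    whole[30:32, 30:32] = True
    inner = np.zeros((64, 64), dtype=bool)
    inner[30, 30] = True
    with pytest.raises(ValueError, match="8"):
        trace_boundaries(_seg(whole, inner))


# --- diameters ---------------------------------------------------------------


def test_axis_diameters_of_axis_aligned_ellipse():
    whole = _ellipse((680, 680), (340, 340), 300, 200)
    inner = _ellipse((680, 680), (340, 340), 240, 160)
    b = trace_boundaries(_seg(whole, inner))
    d = axis_diameters(b, CAL)
    assert d.major_mm == pytest.approx(6.00, abs=0.01)
    assert d.minor_mm == pytest.approx(4.00, abs=0.01)
    assert d.convention == "axis-endpoint"


def test_circle_diameters_equal_everywhere():
    b = _annulus_boundaries()
    ax = axis_diameters(b, CAL)
    fe = feret_diameters(b, CAL)
    for val in (ax.major_mm, ax.minor_mm, fe.major_mm, fe.minor_mm):
        assert val == pytest.approx(6.00, abs=0.01)


def test_rotated_ellipse_axis_vs_feret_conventions():
    whole = _ellipse((680, 680), (340, 340), 300, 200, rot_deg=45.0)
    inner = _ellipse((680, 680), (340, 340), 240, 160, rot_deg=45.0)
    b = trace_boundaries(_seg(whole, inner))
    ax = axis_diameters(b, CAL)
    fe = feret_diameters(b, CAL)
    # chord oracle through the center at 0° for a 45°-rotated ellipse
    a, bb = 300.0, 200.0
    psi = math.radians(-45.0)
    chord_mm = 2 * a * bb / math.hypot(bb * math.cos(psi), a * math.sin(psi)) / 100.0
    assert ax.major_mm == pytest.approx(chord_mm, abs=0.02)
    assert ax.major_mm < 6.00
    assert fe.major_mm == pytest.approx(6.00, abs=0.01)
    assert fe.minor_mm == pytest.approx(4.00, abs=0.01)
    assert fe.major_mm >= ax.major_mm


def test_square_feret_oracle():
    whole = np.zeros((400, 400), dtype=bool)
    whole[100:301, 100:301] = True  # side 201 px
    inner = np.zeros((400, 400), dtype=bool)
    inner[180:221, 180:221] = True
    b = trace_boundaries(_seg(whole, inner))
    fe = feret_diameters(b, CAL)
    # brute force over all outer vertex pairs (max) and support directions (min)
    pts = b.outer[:-1]
    d2 = np.sum((pts[:, None] - pts[None, :]) ** 2, axis=-1)
    brute_max = math.sqrt(d2.max()) / 100.0
    angles = np.linspace(0, np.pi, 3600, endpoint=False)
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    proj = pts @ dirs.T
    brute_min = (proj.max(axis=0) - proj.min(axis=0)).min() / 100.0
    assert fe.major_mm == pytest.approx(brute_max, abs=1e-9)
    assert fe.major_mm == pytest.approx(2.01 * math.sqrt(2), abs=0.02)
    assert fe.minor_mm == pytest.approx(brute_min, abs=0.005)
    assert fe.minor_mm == pytest.approx(2.01, abs=0.02)


def test_degenerate_boundary_rejected():
    collinear = np.array([[float(i), 10.0] for i in range(10)] + [[0.0, 10.0]])
    b = RindBoundaries.__new__(RindBoundaries)
    b.outer = collinear
    b.inner = collinear
    b.centroid_px = (5.0, 10.0)
    with pytest.raises(ValueError):
        feret_diameters(b, CAL)


# --- rind thickness ----------------------------------------------------------


def test_concentric_annulus_thickness():
    b = _annulus_boundaries(r_out=300, r_in=240)
    t = rind_thickness(b, CAL)
    assert t.mean_mm == pytest.approx(0.60, abs=0.01)
    assert t.mean_mm == pytest.approx(np.mean(t.per_point_mm))
    assert np.all(t.per_point_mm > 0)
    assert t.segments_px.shape[1:] == (2, 2)


def test_eccentric_annulus_thickness_span():
    # inner circle shifted by d: per-point thickness spans ~[R-r-d, R-r+d]
    d = 20
    b = _annulus_boundaries(r_out=300, r_in=240, inner_center=(340 + d, 340))
    t = rind_thickness(b, CAL)
    per_px = t.per_point_mm * 100.0
    assert per_px.min() == pytest.approx(300 - 240 - d, abs=1.5)
    assert per_px.max() == pytest.approx(300 - 240 + d, abs=1.5)
    assert t.mean_mm == pytest.approx(0.60, abs=0.01)  # offsets cancel to first order


def test_concentric_ellipse_thickness_against_dense_sampling_oracle():
    whole = _ellipse((680, 680), (340, 340), 300, 220)
    inner = _ellipse((680, 680), (340, 340), 250, 150)
    b = trace_boundaries(_seg(whole, inner))
    t = rind_thickness(b, CAL)
    # oracle: dense parametric sampling of both true ellipses, vertex-to-vertex
    s = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
    outer_pts = np.column_stack([340 + 300 * np.cos(s), 340 + 220 * np.sin(s)])
    dense = np.linspace(0, 2 * np.pi, 20000, endpoint=False)
    inner_pts = np.column_stack([340 + 250 * np.cos(dense), 340 + 150 * np.sin(dense)])
    dmat = np.sqrt(((outer_pts[:, None] - inner_pts[None]) ** 2).sum(-1)).min(axis=1)
    oracle_mm = dmat.mean() / 100.0
    assert t.mean_mm == pytest.approx(oracle_mm, rel=0.02)
    gap_min, gap_max = (300 - 250) / 100.0, (220 - 150) / 100.0
    assert gap_min <= t.mean_mm <= gap_max


def test_intersecting_boundaries_rejected():
    b = _annulus_boundaries()
    with pytest.raises(ValueError, match="intersect"):
        rind_thickness(RindBoundaries(outer=b.inner, inner=b.outer, centroid_px=b.centroid_px), CAL)


# --- areas -------------------------------------------------------------------


def test_annulus_region_areas():
    whole = disk_mask((680, 680), (340, 340), 300)
    inner = disk_mask((680, 680), (340, 340), 240)
    seg = _seg(whole, inner)
    w_mm2, i_mm2 = region_areas(seg, CAL)
    assert w_mm2 == pytest.approx(math.pi * 3.0**2, rel=0.02)
    assert i_mm2 < w_mm2
    # doubling px_per_mm quarters both areas
    w2, i2 = region_areas(seg, Calibration(px_per_mm=200.0))
    assert w2 == pytest.approx(w_mm2 / 4) and i2 == pytest.approx(i_mm2 / 4)


def test_all_lengths_scale_with_calibration(maize_phantom):
    _, img, _ = maize_phantom
    from stalksect import PipelineConfig, analyze_section

    _, art = analyze_section(img, PipelineConfig(px_per_mm=100.0))
    b = art["boundaries"]
    for cal_a, cal_b in [(Calibration(px_per_mm=100.0), Calibration(px_per_mm=50.0))]:
        da = axis_diameters(b, cal_a)
        db = axis_diameters(b, cal_b)
        assert db.major_mm == pytest.approx(2 * da.major_mm)
        ta = rind_thickness(b, cal_a)
        tb = rind_thickness(b, cal_b)
        assert tb.mean_mm == pytest.approx(2 * ta.mean_mm)
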