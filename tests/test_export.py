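"""World-coordinate conversion, decimation, FE-script and neutral-format round trips."""

import json

import numpy as np
import pytest

from stalksect import (
    Calibration,
    PipelineConfig,
    analyze_section,
    decimate_boundary,
    emit_fe_script,
    export_neutral,
    import_neutral_csv,
    mm_to_px,
    parse_fe_script,
    to_world,
)
from stalksect.export import WorldGeometry, sheet_size_for
from stalksect.morphometry import signed_area


@pytest.fixture(scope="module")
def maize_geometry(maize_phantom):
    spec, img, _ = maize_phantom
    config = PipelineConfig(plant_type=spec.plant_type, px_per_mm=spec.px_per_mm)
    record, art = analyze_section(img, config)
    geom = to_world(art["boundaries"], art["bundles"], img.calibration)
    return record, art, geom


def test_world_origin_is_the_centroid(maize_geometry):
    _, art, geom = maize_geometry
    b = art["boundaries"]
    cal = Calibration(px_per_mm=100.0, origin_px=b.centroid_px, y_up=True)
    from stalksect import px_to_mm

    assert px_to_mm([b.centroid_px], cal)[0] == pytest.approx((0.0, 0.0))
    outer = geom.splines[geom.names.index("outer_rind")]
    assert np.abs(outer.mean(axis=0)) == pytest.approx((0.0, 0.0), abs=0.02)


def test_circular_annulus_exports_at_true_radius():
    from stalksect.phantoms import PhantomSpec, make_phantom

    spec = PhantomSpec(
        outer_semi_axes=(300.0, 300.0), inner_semi_axes=(240.0, 240.0),
        n_bundles=0, speck_count=0, plant_type="hollow", px_per_mm=100.0,
    )
    img, _ = make_phantom(spec, 1)
    _, art = analyze_section(img, PipelineConfig(plant_type="hollow", px_per_mm=100.0))
    geom = to_world(art["boundaries"], None, img.calibration)
    outer = geom.splines[0]
    radii = np.hypot(outer[:, 0], outer[:, 1])
    # outer spline vertices at radius 3.00 ± 0.01 mm for R_out = 300 px at 100 px/mm
    assert radii.mean() == pytest.approx(3.0, abs=0.01)
    assert np.max(np.abs(radii - 3.0)) <= 0.015


def test_world_vertices_round_trip_to_pixels(maize_geometry):
    _, art, geom = maize_geometry
    b = art["boundaries"]
    cal = Calibration(px_per_mm=100.0, origin_px=b.centroid_px, y_up=True)
    back = mm_to_px(geom.splines[0], cal)
    assert np.max(np.abs(back - b.outer)) < 1e-9


def test_names_and_sheet_size(maize_geometry):
    _, _, geom = maize_geometry
    assert geom.names[:2] == ["outer_rind", "inner_rind"]
    assert geom.names[2] == "bundle_001"
    need = 2 * np.hypot(*(np.vstack(geom.splines).max(0) - np.vstack(geom.splines).min(0)))
    assert geom.sheet_size_mm > need
    assert np.log10(geom.sheet_size_mm) == pytest.approx(round(np.log10(geom.sheet_size_mm)))


# --- decimation --------------------------------------------------------------


def _circle_spline(n=1000, r=3.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([r * np.cos(t), r * np.sin(t)])
    return np.vstack([pts, pts[0]])


def test_decimation_zero_tolerance_is_identity():
    sp = _circle_spline()
    assert np.array_equal(decimate_boundary(sp, 0.0), sp)


def test_decimation_bounds_radial_error_and_reduces_vertices():
    sp = _circle_spline(1000, r=3.0)
    out = decimate_boundary(sp, 0.01)
    assert len(out) <= len(sp) / 10
    assert np.allclose(out[0], out[-1])
    radii = np.hypot(out[:, 0], out[:, 1])
    assert np.max(np.abs(radii - 3.0)) <= 0.01 + 1e-12
    # chord sag between kept vertices is what the tolerance bounds
    dense = _circle_spline(100000, r=3.0)[:-1]
    import shapely

    ring = shapely.LinearRing(out)
    assert shapely.distance(shapely.points(dense), ring).max() <= 0.01 + 1e-9


def test_decimated_area_stays_within_half_percent():
    sp = _circle_spline(1000, r=3.0)
    out = decimate_boundary(sp, 0.005)  # ≤ 0.5 % of the 3 mm radius... 0.005/3
    assert abs(abs(signed_area(out)) - abs(signed_area(sp))) / abs(signed_area(sp)) < 0.005


# --- FE script ---------------------------------------------------------------


def test_fe_script_statement_counts(maize_geometry):
    _, _, geom = maize_geometry
    text = emit_fe_script(geom)
    n = len(geom.splines)
    assert text.count("ConstrainedSketch(") == n
    assert text.count("s.Spline(points=(") == n
    assert text.count("changeKey(") == n
    assert "mdb.Model(" in text and "sheetSize = " in text
    assert text.splitlines()[2].startswith("mdb.Model(")  # model before sketches


def test_fe_script_round_trip_exact_at_printed_precision(maize_geometry):
    _, _, geom = maize_geometry
    back = parse_fe_script(emit_fe_script(geom))
    assert back.names == geom.names
    assert back.sheet_size_mm == pytest.approx(geom.sheet_size_mm)
    for sp, sp_back in zip(geom.splines, back.splines):
        assert np.max(np.abs(np.round(sp, 6) - sp_back)) == 0.0


def test_fe_script_deterministic(maize_geometry, tmp_path):
    _, _, geom = maize_geometry
    p1, p2 = tmp_path / "a.py", tmp_path / "b.py"
    emit_fe_script(geom, p1)
    emit_fe_script(geom, p2)
    assert p1.read_bytes() == p2.read_bytes()


# --- neutral formats ---------------------------------------------------------


def test_csv_round_trip_is_exact(maize_geometry, tmp_path):
    _, _, geom = maize_geometry
    path = tmp_path / "geom.csv"
    export_neutral(geom, "csv", path)
    back = import_neutral_csv(path)
    assert back.names == geom.names
    assert back.sheet_size_mm == geom.sheet_size_mm
    for sp, sp_back in zip(geom.splines, back.splines):
        assert np.array_equal(sp, sp_back)


def test_geojson_polygon_count_and_area(maize_geometry, tmp_path):
    record, _, geom = maize_geometry
    path = tmp_path / "geom.geojson"
    export_neutral(geom, "geojson", path)
    payload = json.loads(path.read_text())
    assert len(payload["features"]) == len(geom.splines)
    outer = next(f for f in payload["features"] if f["properties"]["name"] == "outer_rind")
    ring = np.asarray(outer["geometry"]["coordinates"][0])
    shoelace = abs(signed_area(ring))
    assert shoelace == pytest.approx(record.whole_area_mm2, rel=0.02)


def test_svg_written_with_one_path_per_spline(maize_geometry, tmp_path):
    _, _, geom = maize_geometry
    path = tmp_path / "geom.svg"
    export_neutral(geom, "svg", path)
    text = path.read_text()
    assert text.startswith("<svg")
    assert text.count("<path") == len(geom.splines)


def test_unknown_format_rejected(maize_geometry, tmp_path):
    _, _, geom = maize_geometry
    with pytest.raises(ValueError, match="unknown export format"):
        export_neutral(geom, "dxf", tmp_path / "x.dxf")


def test_world_geometry_validation():
    sq = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0], [0.0, 0.0]])
    with pytest.raises(ValueError, match="sheet_size"):
        WorldGeometry(splines=[sq], names=["outer_rind"], sheet_size_mm=1.0)
    with pytest.raises(ValueError, match="empty"):
        WorldGeometry(splines=[], names=[], sheet_size_mm=10.0)
    geom = WorldGeometry(splines=[sq[:-1]], names=["outer_rind"], sheet_size_mm=sheet_size_for([sq]))
    assert np.allclose(geom.splines[0][0], geom.splines[0][-1])  # auto-closed
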