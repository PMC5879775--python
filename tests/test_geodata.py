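"""Unit tests for the geographic layer: loaders, distances, water lengths."""

import json

import numpy as np
import pandas as pd
import pytest

from sahelsim.geodata import (NONPERENNIAL_CLASS, PERENNIAL_CLASS, KM_PER_DEG_LAT,
                              SimulationBounds, WaterSegment, distance_km,
                              load_rainfall, load_settlements, load_water_courses,
                              water_length_within)

from conftest import offset_lonlat


# ---------------------------------------------------------------------- distance

def test_distance_zero_and_one_degree_latitude():
    assert distance_km(3.0, 10.0, 3.0, 10.0) == 0.0
    # one degree of latitude on a 6371 km sphere
    assert distance_km(12.0, 5.0, 12.0, 6.0) == pytest.approx(111.195, abs=0.01)
    assert distance_km(-100.0, -40.0, -100.0, -41.0) == pytest.approx(111.195, abs=0.01)


def test_distance_agrees_with_spherical_law_of_cosines():
    rng = np.random.default_rng(1)
    lon1, lon2 = rng.uniform(-10, 10, (2, 50))
    lat1, lat2 = rng.uniform(0, 25, (2, 50))
    got = distance_km(lon1, lat1, lon2, lat2)
    # independent formula: spherical law of cosines
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(lon2 - lon1)
    expected = 6371.0 * np.arccos(np.clip(
        np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl), -1, 1))
    np.testing.assert_allclose(got, expected, rtol=0.005)


def test_distance_symmetry_and_triangle_inequality():
    rng = np.random.default_rng(2)
    for _ in range(50):
        a, b, c = rng.uniform([-5, 8], [3, 17], size=(3, 2))
        dab = distance_km(a[0], a[1], b[0], b[1])
        dba = distance_km(b[0], b[1], a[0], a[1])
        assert dab == pytest.approx(dba, rel=1e-12)
        dac = distance_km(a[0], a[1], c[0], c[1])
        dcb = distance_km(c[0], c[1], b[0], b[1])
        assert dab <= dac + dcb + 1e-9


# ---------------------------------------------------------------------- settlements

def test_settlement_bounds_filter(tmp_path, bounds100):
    inside = [offset_lonlat(bounds100, x, 0.0) for x in (-20.0, 0.0, 20.0)]
    outside = [offset_lonlat(bounds100, 200.0, 0.0)]
    df = pd.DataFrame(inside + outside, columns=["lon", "lat"])
    path = tmp_path / "s.csv"
    df.to_csv(path, index=False)
    got = load_settlements(path, bounds100)
    assert len(got) == 3
    assert list(got["id"]) == [0, 1, 2]


def test_settlement_bad_coordinate_is_row_indexed_error(tmp_path, bounds100):
    path = tmp_path / "s.csv"
    path.write_text("lon,lat\n-1.7,12.3\n-1.8,NaN\n")
    with pytest.raises(ValueError, match=r"rows \[1\]"):
        load_settlements(path, bounds100)
    got = load_settlements(path, bounds100, errors="skip")
    assert len(got) == 1


def test_settlement_duplicates_retained(tmp_path, bounds100):
    path = tmp_path / "s.csv"
    path.write_text("lon,lat\n-1.737,12.274\n-1.737,12.274\n")
    assert len(load_settlements(path, bounds100)) == 2


def test_empty_settlements_fatal(tmp_path, bounds100):
    path = tmp_path / "s.csv"
    path.write_text("lon,lat\n50.0,50.0\n")
    with pytest.raises(ValueError, match="no settlements"):
        load_settlements(path, bounds100)


# ---------------------------------------------------------------------- water

def _write_geojson(path, features):
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def test_square_polygon_becomes_ring_of_perimeter_length(tmp_path, bounds100):
    # 10 km square polygon -> one boundary ring of length 40 km
    corners_km = [(-5, -5), (5, -5), (5, 5), (-5, 5), (-5, -5)]
    coords = [list(offset_lonlat(bounds100, x, y)) for x, y in corners_km]
    _write_geojson(tmp_path / "w.geojson", [{
        "type": "Feature", "properties": {"class": PERENNIAL_CLASS},
        "geometry": {"type": "Polygon", "coordinates": [coords]},
    }])
    segs = load_water_courses(tmp_path / "w.geojson", bounds100)
    assert len(segs) == 1
    assert segs[0].perennial
    assert segs[0].length_km == pytest.approx(40.0, rel=0.005)


def test_line_crossing_boundary_is_clipped(tmp_path, bounds100):
    # horizontal line from centre to 30 km past the east edge: keep ~50 km
    coords = [list(offset_lonlat(bounds100, x, 0.0)) for x in (0.0, 80.0)]
    _write_geojson(tmp_path / "w.geojson", [{
        "type": "Feature", "properties": {"class": NONPERENNIAL_CLASS},
        "geometry": {"type": "LineString", "coordinates": coords},
    }])
    segs = load_water_courses(tmp_path / "w.geojson", bounds100)
    assert len(segs) == 1
    assert not segs[0].perennial
    assert segs[0].length_km == pytest.approx(50.0, rel=0.01)


def test_unknown_class_fatal(tmp_path, bounds100):
    _write_geojson(tmp_path / "w.geojson", [{
        "type": "Feature", "properties": {"class": "sometimes wet"},
        "geometry": {"type": "LineString", "coordinates": [[-1.7, 12.2], [-1.6, 12.2]]},
    }])
    with pytest.raises(ValueError, match="sometimes wet"):
        load_water_courses(tmp_path / "w.geojson", bounds100)


# ---------------------------------------------------------------------- rainfall

def test_daily_to_weekly_aggregation(tmp_path, bounds100):
    rows = [{"day": d, "lat": 12.25, "lon": -1.75, "rain_mm": 2.0} for d in range(14)]
    path = tmp_path / "r.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    grid = load_rainfall(path, bounds100)
    assert grid.weekly.shape[0] == 2
    np.testing.assert_allclose(grid.weekly[:, 0, 0], [14.0, 14.0])


def test_all_zero_rainfall(tmp_path, bounds100):
    rows = [{"day": d, "lat": 12.25, "lon": -1.75, "rain_mm": 0.0} for d in range(7)]
    path = tmp_path / "r.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    assert load_rainfall(path, bounds100).weekly.sum() == 0.0


def test_rainfall_gap_and_negative_fatal(tmp_path, bounds100):
    rows = [{"day": d, "lat": 12.25, "lon": -1.75, "rain_mm": 1.0}
            for d in range(14) if d != 5]
    path = tmp_path / "r.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    with pytest.raises(ValueError, match="gaps"):
        load_rainfall(path, bounds100)
    rows = [{"day": d, "lat": 12.25, "lon": -1.75, "rain_mm": -1.0} for d in range(7)]
    pd.DataFrame(rows).to_csv(path, index=False)
    with pytest.raises(ValueError, match="negative"):
        load_rainfall(path, bounds100)


def test_seasonal_sinusoid_matches_analytic_integral(tmp_path, bounds100):
    # daily rain A*(1 + sin(2*pi*t/364)) over 364 days: total = 364*A exactly
    # (the sine integrates to zero over whole periods)
    A = 3.0
    t = np.arange(364)
    daily = A * (1.0 + np.sin(2 * np.pi * t / 364.0))
    rows = [{"day": int(d), "lat": 12.25, "lon": -1.75, "rain_mm": float(v)}
            for d, v in zip(t, daily)]
    path = tmp_path / "r.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    grid = load_rainfall(path, bounds100)
    assert grid.weekly[:, 0, 0].sum() == pytest.approx(364.0 * A, rel=1e-9)


def test_netcdf_round_trip(tmp_path, bounds100):
    import xarray as xr

    daily = np.abs(np.random.default_rng(3).normal(2.0, 1.0, size=(21, 2, 2)))
    ds = xr.Dataset(
        {"tp": (("time", "lat", "lon"), daily)},
        coords={"time": pd.date_range("2001-06-01", periods=21, freq="D"),
                "lat": [12.0, 12.5], "lon": [-2.0, -1.5]})
    ds.to_netcdf(tmp_path / "r.nc", engine="scipy")
    grid = load_rainfall(tmp_path / "r.nc", bounds100)
    assert grid.weekly.shape == (3, 2, 2)
    np.testing.assert_allclose(grid.weekly,
                               daily.reshape(3, 7, 2, 2).sum(axis=1))
    assert grid.start_doy == 152  # 1 June


# ---------------------------------------------------------------------- length within radius

def test_water_length_within_empty():
    assert water_length_within(-1.7, 12.3, [], 2.0) == (0.0, 0.0)


def test_perennial_chord_through_centre(bounds100):
    lw = 2.0
    a = offset_lonlat(bounds100, -10.0, 0.0)
    b = offset_lonlat(bounds100, 10.0, 0.0)
    seg = WaterSegment(np.array([a, b]), perennial=True)
    lon, lat = offset_lonlat(bounds100, 0.0, 0.0)
    w_p, w_n = water_length_within(lon, lat, [seg], lw)
    assert w_p == pytest.approx(2.0 * lw, rel=0.005)
    assert w_n == 0.0


def test_water_length_matches_point_sampling_oracle(bounds100):
    rng = np.random.default_rng(4)
    segments = []
    for _ in range(20):
        x0, y0 = rng.uniform(-8, 8, 2)
        n_v = rng.integers(2, 6)
        pts_km = np.cumsum(np.vstack([[x0, y0], rng.normal(0, 2.0, (n_v - 1, 2))]), axis=0)
        verts = np.array([offset_lonlat(bounds100, x, y) for x, y in pts_km])
        segments.append(WaterSegment(verts, perennial=bool(rng.integers(0, 2))))
    lon, lat = offset_lonlat(bounds100, 0.0, 0.0)
    L_w = 5.0
    got_p, got_n = water_length_within(lon, lat, segments, L_w)

    # oracle: resample every segment densely and sum sub-segment lengths
    # whose midpoints fall inside the disc
    exp = {True: 0.0, False: 0.0}
    for seg in segments:
        v = seg.vertices
        for i in range(len(v) - 1):
            n_sub = 4000
            ts = np.linspace(0, 1, n_sub + 1)
            pts = v[i][None, :] + ts[:, None] * (v[i + 1] - v[i])[None, :]
            mid = 0.5 * (pts[:-1] + pts[1:])
            sub_len = distance_km(pts[:-1, 0], pts[:-1, 1], pts[1:, 0], pts[1:, 1])
            inside = distance_km(mid[:, 0], mid[:, 1], lon, lat) <= L_w
            exp[seg.perennial] += float(sub_len[inside].sum())
    assert got_p == pytest.approx(exp[True], rel=0.01)
    assert got_n == pytest.approx(exp[False], rel=0.01)
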