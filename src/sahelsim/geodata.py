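"""Geographic inputs: settlements, water courses and rainfall.

The simulator treats mosquito populations as a network of sites located at
human settlements inside a square study region.  This module loads and
validates the three geographic layers the model consumes —

* a settlement point table (longitude/latitude plus optional labels),
* water-course line/polygon geometries classified as perennial or
  non-perennial,
* a gridded weekly-rainfall series at (by default) 0.5 degree resolution,

and provides the distance and length primitives used by the habitat and
movement modules.  All coordinates are WGS84 decimal degrees; all distances
are kilometres on a spherical Earth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, box, shape

EARTH_RADIUS_KM = 6371.0
KM_PER_DEG_LAT = np.pi * EARTH_RADIUS_KM / 180.0  # ~111.19 km

#: canonical class strings used by the inland-water source data
PERENNIAL_CLASS = "perennial or permanent"
NONPERENNIAL_CLASS = "non-perennial, intermittent, or fluctuating"

#: default study region: a 1000 km square centred on the mid-point of
#: Burkina Faso.
DEFAULT_CENTRE = (-1.737, 12.274)
DEFAULT_SIDE_KM = 1000.0


def distance_km(lon1, lat1, lon2, lat2):
    """Great-circle (haversine) distance in km; accepts scalars or arrays."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class SimulationBounds:
    """Square simulation region: side length in km, centred on (lon, lat)."""

    centre_lon: float = DEFAULT_CENTRE[0]
    centre_lat: float = DEFAULT_CENTRE[1]
    side_km: float = DEFAULT_SIDE_KM

    @property
    def half_lat_deg(self) -> float:
        return self.side_km / 2.0 / KM_PER_DEG_LAT

    @property
    def half_lon_deg(self) -> float:
        return self.side_km / 2.0 / (KM_PER_DEG_LAT * np.cos(np.radians(self.centre_lat)))

    @property
    def west(self) -> float:
        return self.centre_lon - self.half_lon_deg

    @property
    def east(self) -> float:
        return self.centre_lon + self.half_lon_deg

    @property
    def south(self) -> float:
        return self.centre_lat - self.half_lat_deg

    @property
    def north(self) -> float:
        return self.centre_lat + self.half_lat_deg

    def contains(self, lon, lat):
        """Vectorised point-in-square test (edges inclusive)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return ((lon >= self.west) & (lon <= self.east)
                & (lat >= self.south) & (lat <= self.north))

    def polygon(self):
        return box(self.west, self.south, self.east, self.north)

    def to_local_km(self, lon, lat):
        """Equirectangular projection about the centre, in km (x east, y north)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        x = (lon - self.centre_lon) * KM_PER_DEG_LAT * np.cos(np.radians(self.centre_lat))
        y = (lat - self.centre_lat) * KM_PER_DEG_LAT
        return x, y


@dataclass
class WaterSegment:
    """A polyline of linear larval habitat (river reach or lake shore)."""

    vertices: np.ndarray  # (k, 2) lon/lat
    perennial: bool

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (k, 2) lon/lat array")
        if len(self.vertices) < 2:
            raise ValueError("a water segment needs at least 2 vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("non-finite vertex coordinate")
        if self.length_km <= 0:
            raise ValueError("zero-length water segment")

    @property
    def length_km(self) -> float:
        v = self.vertices
        return float(np.sum(distance_km(v[:-1, 0], v[:-1, 1], v[1:, 0], v[1:, 1])))


class RainfallGrid:
    """Weekly total rainfall (mm/week) on a regular lon/lat grid.

    ``weekly`` has shape (n_weeks, n_lat, n_lon); cell (i, j) spans
    latitudes [lat0 + i*cs, lat0 + (i+1)*cs) and similarly for longitude,
    with (lon0, lat0) the south-west grid origin.  ``start_doy`` is the
    day-of-year (1..365, no-leap calendar) of the first day of week 0.
    """

    def __init__(self, lon0: float, lat0: float, cell_size_deg: float,
                 weekly: np.ndarray, start_doy: int = 1) -> None:
        weekly = np.asarray(weekly, dtype=float)
        if weekly.ndim != 3:
            raise ValueError("weekly rainfall must be (n_weeks, n_lat, n_lon)")
        if np.any(weekly < 0) or not np.all(np.isfinite(weekly)):
            raise ValueError("rainfall totals must be finite and >= 0")
        if not 1 <= start_doy <= 365:
            raise ValueError("start_doy must be in 1..365")
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self.cell_size_deg = float(cell_size_deg)
        self.weekly = weekly
        self.start_doy = int(start_doy)

    @property
    def n_weeks(self) -> int:
        return self.weekly.shape[0]

    @property
    def shape(self):
        return self.weekly.shape

    def cell_index(self, lon, lat):
        """Containing-cell lookup (no interpolation). Returns (row, col)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon0) / self.cell_size_deg).astype(int)
        row = np.floor((lat - self.lat0) / self.cell_size_deg).astype(int)
        n_lat, n_lon = self.weekly.shape[1:]
        bad = (col < 0) | (col >= n_lon) | (row < 0) | (row >= n_lat)
        if np.any(bad):
            raise ValueError("point(s) outside the rainfall grid")
        return row, col

    def series(self, lon, lat) -> np.ndarray:
        """Weekly rainfall series (mm/week) for the cell containing a point."""
        row, col = self.cell_index(lon, lat)
        return self.weekly[:, row, col]


@dataclass
class Landscape:
    """One geographic scene: settlements + water + rainfall + bounds."""

    settlements: pd.DataFrame
    water: list
    rain: RainfallGrid
    bounds: SimulationBounds = field(default_factory=SimulationBounds)

    def __post_init__(self) -> None:
        s = self.settlements
        for col in ("id", "lon", "lat"):
            if col not in s.columns:
                raise ValueError(f"settlement table missing column {col!r}")
        if s["id"].duplicated().any():
            raise ValueError("settlement ids must be unique")
        if not np.all(np.isfinite(s[["lon", "lat"]].to_numpy())):
            raise ValueError("non-finite settlement coordinate")
        inside = self.bounds.contains(s["lon"].to_numpy(), s["lat"].to_numpy())
        if not np.all(inside):
            raise ValueError("settlement(s) outside the simulation square")
        # every settlement must map to exactly one rainfall cell
        self.rain.cell_index(s["lon"].to_numpy(), s["lat"].to_numpy())

    @property
    def n_settlements(self) -> int:
        return len(self.settlements)

    @property
    def coords(self):
        """(lon, lat) arrays of settlement coordinates."""
        return (self.settlements["lon"].to_numpy(),
                self.settlements["lat"].to_numpy())

    def settlement_rain_series(self) -> np.ndarray:
        """(n_weeks, n_settlements) weekly rainfall bound per settlement."""
        lon, lat = self.coords
        row, col = self.rain.cell_index(lon, lat)
        return self.rain.weekly[:, row, col]


# ---------------------------------------------------------------------------
# loaders


def load_settlements(path, bounds: SimulationBounds,
                     lon_col: str = "lon", lat_col: str = "lat",
                     sep: str | None = None, errors: str = "raise") -> pd.DataFrame:
    """Read a delimited settlement table, keeping points inside ``bounds``.

    Duplicate coordinates are retained — each row is its own potential
    population site.  Rows with missing or unparseable coordinates raise a
    ``ValueError`` naming the offending row indices (``errors="skip"`` drops
    them with a warning instead).  An empty result is fatal.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if lon_col not in df.columns or lat_col not in df.columns:
        raise ValueError(f"no {lon_col!r}/{lat_col!r} columns in {path}")
    lon = pd.to_numeric(df[lon_col], errors="coerce")
    lat = pd.to_numeric(df[lat_col], errors="coerce")
    bad = ~(np.isfinite(lon.to_numpy(dtype=float)) & np.isfinite(lat.to_numpy(dtype=float)))
    if bad.any():
        rows = list(df.index[bad])
        if errors == "raise":
            raise ValueError(f"unparseable coordinates at rows {rows}")
        warnings.warn(f"skipping {len(rows)} rows with bad coordinates: {rows}")
    keep = ~bad & bounds.contains(lon.fillna(np.inf).to_numpy(),
                                  lat.fillna(np.inf).to_numpy())
    out = pd.DataFrame({
        "lon": lon[keep].to_numpy(dtype=float),
        "lat": lat[keep].to_numpy(dtype=float),
    })
    for label in ("name", "region", "country"):
        if label in df.columns:
            out[label] = df.loc[keep, label].to_numpy()
    out.insert(0, "id", np.arange(len(out)))
    if len(out) == 0:
        raise ValueError("no settlements inside the simulation square")
    return out


def _classify(value, perennial_value: str | None, nonperennial_value: str | None) -> bool:
    pv = (perennial_value or PERENNIAL_CLASS).strip().lower()
    nv = (nonperennial_value or NONPERENNIAL_CLASS).strip().lower()
    v = str(value).strip().lower()
    if v == pv:
        return True
    if v == nv:
        return False
    raise ValueError(f"unknown water-course class {value!r}")


def _linework(geom) -> list:
    """Decompose a geometry into LineStrings; polygons contribute their
    boundary rings (periphery breeding), unsupported types are skipped."""
    gt = geom.geom_type
    if gt == "LineString":
        return [geom]
    if gt == "LinearRing":
        return [LineString(geom.coords)]
    if gt == "Polygon":
        rings = [LineString(geom.exterior.coords)]
        rings += [LineString(r.coords) for r in geom.interiors]
        return rings
    if gt in ("MultiLineString", "MultiPolygon", "GeometryCollection"):
        out = []
        for g in geom.geoms:
            out.extend(_linework(g))
        return out
    warnings.warn(f"skipping unsupported geometry type {gt}")
    return []


def load_water_courses(path, bounds: SimulationBounds,
                       class_attr: str = "class",
                       perennial_value: str | None = None,
                       nonperennial_value: str | None = None) -> list:
    """Load water courses from GeoJSON, clipped to the simulation square.

    Polygon geometries (lakes, wide rivers) are converted to their boundary
    rings and treated as linear habitat.  Each feature must carry a class
    attribute distinguishing perennial from non-perennial courses; an
    unrecognised class string is fatal.
    """
    with open(path) as fh:
        gj = json.load(fh)
    clip = bounds.polygon()
    segments: list[WaterSegment] = []
    for feat in gj.get("features", []):
        perennial = _classify(feat.get("properties", {}).get(class_attr),
                              perennial_value, nonperennial_value)
        for line in _linework(shape(feat["geometry"])):
            clipped = line.intersection(clip)
            if clipped.is_empty:
                continue
            parts = (clipped.geoms if clipped.geom_type.startswith("Multi")
                     or clipped.geom_type == "GeometryCollection" else [clipped])
            for part in parts:
                if part.geom_type != "LineString" or part.length == 0:
                    continue
                segments.append(WaterSegment(np.asarray(part.coords), perennial))
    return segments


def _weekly_from_daily(daily: np.ndarray) -> np.ndarray:
    """Sum a (n_days, n_lat, n_lon) daily stack into full weeks."""
    n_full = daily.shape[0] // 7
    if n_full == 0:
        raise ValueError("need at least 7 days of rainfall")
    if daily.shape[0] % 7:
        warnings.warn(f"dropping {daily.shape[0] % 7} trailing days (partial week)")
    return daily[: n_full * 7].reshape(n_full, 7, *daily.shape[1:]).sum(axis=1)


def _doy_noleap(ts) -> int:
    return min(int(pd.Timestamp(ts).dayofyear), 365)


def load_rainfall(path, bounds: SimulationBounds, var: str | None = None,
                  cell_size_deg: float = 0.5, start_doy: int | None = None) -> RainfallGrid:
    """Load daily precipitation and aggregate to weekly totals per grid cell.

    Two dialects are accepted: NetCDF with (time, lat, lon) coordinates, or a
    long-format CSV with columns ``lat``, ``lon``, ``rain_mm`` and either a
    ``date`` column or an integer ``day`` column (0-based from the series
    start; pass ``start_doy`` for the calendar anchor).  Gaps in the time
    axis and negative totals are fatal.
    """
    path = str(path)
    if path.endswith((".nc", ".nc4", ".cdf")):
        import xarray as xr

        ds = xr.open_dataset(path, engine="scipy")
        if var is None:
            var = next(iter(ds.data_vars))
        da = ds[var].transpose("time", "lat", "lon")
        times = pd.DatetimeIndex(da["time"].to_numpy())
        deltas = np.diff(times.to_numpy()).astype("timedelta64[D]").astype(int)
        if len(deltas) and not np.all(deltas == 1):
            raise ValueError("gaps in the rainfall time axis")
        daily = da.to_numpy()
        lat = np.sort(da["lat"].to_numpy())
        lon = np.sort(da["lon"].to_numpy())
        if np.any(daily < 0):
            raise ValueError("negative precipitation")
        sd = start_doy if start_doy is not None else _doy_noleap(times[0])
        return RainfallGrid(lon0=float(lon.min()) - cell_size_deg / 2.0,
                            lat0=float(lat.min()) - cell_size_deg / 2.0,
                            cell_size_deg=cell_size_deg,
                            weekly=_weekly_from_daily(daily), start_doy=sd)

    df = pd.read_csv(path)
    if "date" in df.columns:
        dates = pd.to_datetime(df["date"])
        day = (dates - dates.min()).dt.days.to_numpy()
        sd = start_doy if start_doy is not None else _doy_noleap(dates.min())
    elif "day" in df.columns:
        day = df["day"].to_numpy(dtype=int)
        sd = start_doy if start_doy is not None else 1
    else:
        raise ValueError("rainfall CSV needs a 'date' or 'day' column")
    rain = df["rain_mm"].to_numpy(dtype=float)
    if np.any(rain < 0) or not np.all(np.isfinite(rain)):
        raise ValueError("negative or non-finite precipitation")
    lats = np.sort(df["lat"].unique())
    lons = np.sort(df["lon"].unique())
    n_days = int(day.max()) + 1
    if set(np.unique(day)) != set(range(n_days)):
        raise ValueError("gaps in the rainfall time axis")
    daily = np.zeros((n_days, len(lats), len(lons)))
    row = np.searchsorted(lats, df["lat"].to_numpy())
    col = np.searchsorted(lons, df["lon"].to_numpy())
    counts = np.zeros_like(daily)
    np.add.at(daily, (day, row, col), rain)
    np.add.at(counts, (day, row, col), 1.0)
    if np.any(counts == 0):
        raise ValueError("missing (day, cell) entries in rainfall CSV")
    return RainfallGrid(lon0=float(lons.min()) - cell_size_deg / 2.0,
                        lat0=float(lats.min()) - cell_size_deg / 2.0,
                        cell_size_deg=cell_size_deg,
                        weekly=_weekly_from_daily(daily), start_doy=sd)


# ---------------------------------------------------------------------------
# length-within-radius primitive


def _project_segment(seg: WaterSegment, lon: float, lat: float) -> np.ndarray:
    """Project a segment's vertices into local km about (lon, lat)."""
    coslat = np.cos(np.radians(lat))
    x = (seg.vertices[:, 0] - lon) * KM_PER_DEG_LAT * coslat
    y = (seg.vertices[:, 1] - lat) * KM_PER_DEG_LAT
    return np.column_stack([x, y])


def water_length_within(lon: float, lat: float, segments: Sequence[WaterSegment],
                        L_w: float, quad_segs: int = 128):
    """Total (perennial, non-perennial) water-course length, in km, of the
    segment portions lying within ``L_w`` km of the point (lon, lat).

    Segments are projected to a local tangent plane around the settlement,
    then intersected with a disc of radius ``L_w`` (shapely, ``quad_segs``
    arcs per quadrant).
    """
    if L_w <= 0:
        raise ValueError("L_w must be > 0")
    disc = Point(0.0, 0.0).buffer(L_w, quad_segs=quad_segs)
    w_p = 0.0
    w_n = 0.0
    for seg in segments:
        xy = _project_segment(seg, lon, lat)
        # cheap bounding-box reject before the exact intersection
        if (xy[:, 0].min() > L_w or xy[:, 0].max() < -L_w
                or xy[:, 1].min() > L_w or xy[:, 1].max() < -L_w):
            continue
        clipped = LineString(xy).intersection(disc)
        if clipped.is_empty:
            continue
        if seg.perennial:
            w_p += clipped.length
        else:
            w_n += clipped.length
    return w_p, w_n
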