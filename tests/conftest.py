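import numpy as np
import pandas as pd
import pytest

from sahelsim.geodata import (KM_PER_DEG_LAT, Landscape, RainfallGrid,
                              SimulationBounds, WaterSegment)


@pytest.fixture(scope="session")
def bounds100():
    """A 100 km square centred on the default study-region centre."""
    return SimulationBounds(-1.737, 12.274, 100.0)


def offset_lonlat(bounds, x_km, y_km):
    """Convert a local (east, north) km offset from the centre to lon/lat."""
    lon = bounds.centre_lon + x_km / (KM_PER_DEG_LAT * np.cos(np.radians(bounds.centre_lat)))
    lat = bounds.centre_lat + y_km / KM_PER_DEG_LAT
    return lon, lat


def toy_landscape(bounds, xy_km, water=None, weekly_rain=None, start_doy=152):
    """Hand-built Landscape: settlements at local-km offsets, optional
    water segments, and a single rainfall cell covering the square."""
    lon, lat = zip(*(offset_lonlat(bounds, x, y) for x, y in xy_km))
    settlements = pd.DataFrame({"id": range(len(xy_km)), "lon": lon, "lat": lat})
    if weekly_rain is None:
        weekly_rain = np.zeros(52)
    weekly = np.asarray(weekly_rain, dtype=float)[:, None, None]
    cell = 2.0 * max(bounds.half_lon_deg, bounds.half_lat_deg) + 0.1
    rain = RainfallGrid(bounds.west - 0.05, bounds.south - 0.05, cell,
                        np.broadcast_to(weekly, (len(weekly), 1, 1)).copy(),
                        start_doy=start_doy)
    return Landscape(settlements, water or [], rain, bounds)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
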