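"""Planar geometry helpers: local projection and minimal GeoJSON I/O.

All internal geometry is planar, in metres. Synthetic layers use an abstract
planar frame; real longitude/latitude input is projected with a local
east-north tangent plane (ENU) anchored at a reference point on the WGS84
ellipsoid, which is metre-accurate at city scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from shapely.geometry import Point, Polygon, mapping, shape

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)


def _geodetic_to_ecef(lon_rad: np.ndarray, lat_rad: np.ndarray) -> tuple[np.ndarray, ...]:
    sin_lat = np.sin(lat_rad)
    n = _A / np.sqrt(1.0 - _E2 * sin_lat**2)
    x = n * np.cos(lat_rad) * np.cos(lon_rad)
    y = n * np.cos(lat_rad) * np.sin(lon_rad)
    z = n * (1.0 - _E2) * sin_lat
    return x, y, z


@dataclass(frozen=True)
class LocalProjection:
    """East-north local tangent plane anchored at (lon0, lat0) on WGS84.

    ``forward`` maps geographic degrees to planar metres; the 'up' component
    is dropped, which introduces sub-metre error within a few tens of km of
    the anchor — adequate for 1 km grid assignment.
    """

    lon0: float
    lat0: float

    def forward(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        lon = np.radians(np.asarray(lon, dtype=float))
        lat = np.radians(np.asarray(lat, dtype=float))
        lon0, lat0 = math.radians(self.lon0), math.radians(self.lat0)
        x, y, z = _geodetic_to_ecef(lon, lat)
        x0, y0, z0 = _geodetic_to_ecef(np.array(lon0), np.array(lat0))
        dx, dy, dz = x - x0, y - y0, z - z0
        sin_l0, cos_l0 = math.sin(lon0), math.cos(lon0)
        sin_p0, cos_p0 = math.sin(lat0), math.cos(lat0)
        east = -sin_l0 * dx + cos_l0 * dy
        north = -sin_p0 * cos_l0 * dx - sin_p0 * sin_l0 * dy + cos_p0 * dz
        return east, north


def write_geojson(path, features: Iterable[tuple[object, dict]]) -> None:
    """Write (geometry, properties) pairs as an RFC 7946 FeatureCollection."""
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
            for geom, props in features
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)


def read_geojson(path) -> list[tuple[object, dict]]:
    """Read a FeatureCollection into (shapely geometry, properties) pairs."""
    with open(path) as fh:
        fc = json.load(fh)
    return [(shape(f["geometry"]), f.get("properties") or {}) for f in fc["features"]]


def cell_polygon(cell_id: str, origin: tuple[float, float] = (0.0, 0.0),
                 cell_size_m: float = 1000.0) -> Polygon:
    """Reconstruct the axis-aligned square for a serialised cell id 'ix_iy'."""
    ix, iy = (int(tok) for tok in cell_id.split("_"))
    x0 = origin[0] + ix * cell_size_m
    y0 = origin[1] + iy * cell_size_m
    return Polygon([(x0, y0), (x0 + cell_size_m, y0),
                    (x0 + cell_size_m, y0 + cell_size_m), (x0, y0 + cell_size_m)])


def point_cell_id(x, y, origin: tuple[float, float] = (0.0, 0.0),
                  cell_size_m: float = 1000.0) -> np.ndarray:
    """Serialise points into half-open grid cells [x0, x0+s) x [y0, y0+s)."""
    ix = np.floor((np.asarray(x, dtype=float) - origin[0]) / cell_size_m).astype(int)
    iy = np.floor((np.asarray(y, dtype=float) - origin[1]) / cell_size_m).astype(int)
    return np.char.add(np.char.add(ix.astype(str), "_"), iy.astype(str))


__all__ = ["LocalProjection", "write_geojson", "read_geojson", "cell_polygon",
           "point_cell_id", "Point", "Polygon"]
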