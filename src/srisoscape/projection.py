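"""Coordinate reference systems for isoscape grids.

Isoscape work needs an equal-area working projection so that grid cells
represent equal ground area and distance-based statistics (variograms,
correlograms) are meaningful.  Two CRS families are supported:

* ``"wgs84"`` — geographic longitude/latitude in decimal degrees.
* ``"cea:<lon0>:<lat_ts>"`` — Lambert cylindrical equal-area on a spherical
  Earth, centred on meridian ``lon0`` with true-scale latitude ``lat_ts``
  (both degrees).  Coordinates are metres.

The cylindrical equal-area projection is exact on the sphere:

    x = R (λ − λ0) cos φts
    y = R sin φ / cos φts

with R the authalic Earth radius.  Any equal-area CRS serves the method
equally well; this one has a closed-form inverse and no external
dependencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_M = 6_371_007.2  # authalic sphere radius


class CRSError(ValueError):
    """Raised for unknown or malformed CRS identifiers."""


@dataclass(frozen=True)
class CRS:
    """A coordinate reference system keyed by its identifier string."""

    crs_id: str

    def __post_init__(self) -> None:
        _parse(self.crs_id)  # validate eagerly

    @property
    def is_geographic(self) -> bool:
        return _parse(self.crs_id)[0] == "wgs84"

    def to_lonlat(self, x, y):
        """Map projected coordinates (or pass through lon/lat) to degrees."""
        kind, lon0, lat_ts = _parse(self.crs_id)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if kind == "wgs84":
            return x, y
        c = math.cos(math.radians(lat_ts))
        lon = lon0 + np.degrees(x / (EARTH_RADIUS_M * c))
        sinphi = np.clip(y * c / EARTH_RADIUS_M, -1.0, 1.0)
        lat = np.degrees(np.arcsin(sinphi))
        return lon, lat

    def from_lonlat(self, lon, lat):
        """Map longitude/latitude in degrees into this CRS."""
        kind, lon0, lat_ts = _parse(self.crs_id)
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if kind == "wgs84":
            return lon, lat
        c = math.cos(math.radians(lat_ts))
        x = EARTH_RADIUS_M * np.radians(lon - lon0) * c
        y = EARTH_RADIUS_M * np.sin(np.radians(lat)) / c
        return x, y


def transform(src: CRS, dst: CRS, x, y):
    """Transform coordinate arrays from ``src`` to ``dst``."""
    if src.crs_id == dst.crs_id:
        return np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    lon, lat = src.to_lonlat(x, y)
    return dst.from_lonlat(lon, lat)


def _parse(crs_id: str):
    if crs_id == "wgs84":
        return "wgs84", 0.0, 0.0
    parts = crs_id.split(":")
    if len(parts) == 3 and parts[0] == "cea":
        try:
            lon0, lat_ts = float(parts[1]), float(parts[2])
        except ValueError as exc:
            raise CRSError(f"malformed CRS id {crs_id!r}") from exc
        if not (-180 <= lon0 <= 180 and -90 < lat_ts < 90):
            raise CRSError(f"CRS parameters out of range in {crs_id!r}")
        return "cea", lon0, lat_ts
    raise CRSError(
        f"unknown CRS id {crs_id!r}; expected 'wgs84' or 'cea:<lon0>:<lat_ts>'"
    )
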