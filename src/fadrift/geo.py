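"""Spherical-earth geometry helpers shared across the package.

All longitudes are kept on a 0–360 degrees-east convention internally
because the study domain (120°E–90°W) crosses the antimeridian; helpers
here convert between conventions and between degrees and ground metres.
"""

from __future__ import annotations

import numpy as np

#: Mean Earth radius [m], spherical approximation.
EARTH_RADIUS_M = 6_371_000.0

#: Ground metres per degree of latitude (and of longitude at the equator).
METERS_PER_DEGREE = EARTH_RADIUS_M * np.pi / 180.0

#: Mean month length in days (Gregorian average), used for month→week maths.
DAYS_PER_MONTH = 30.4375


def wrap_lon(lon):
    """Wrap longitudes into [0, 360)."""
    return np.asarray(lon, dtype=float) % 360.0


def lon_to_180(lon):
    """Convert 0–360 longitudes to the −180..180 convention (for GeoJSON I/O)."""
    lon = wrap_lon(lon)
    return np.where(lon >= 180.0, lon - 360.0, lon)


def meters_per_degree_lon(lat):
    """Ground metres per degree of longitude at latitude ``lat`` (degrees)."""
    return METERS_PER_DEGREE * np.cos(np.deg2rad(lat))


def ms_to_deg_per_day(u, v, lat):
    """Convert (u, v) in m/s to (dlon/dt, dlat/dt) in degrees/day at ``lat``."""
    sec_per_day = 86400.0
    dlat = v * sec_per_day / METERS_PER_DEGREE
    dlon = u * sec_per_day / meters_per_degree_lon(lat)
    return dlon, dlat


def months_to_weeks(months: float) -> int:
    """Drift-horizon conversion: months → whole weekly archive steps (floored)."""
    return int(np.floor(months * DAYS_PER_MONTH / 7.0))
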