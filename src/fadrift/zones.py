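"""Spatial vocabulary of the experiment: deployment and habitat zones.

Three zone roles exist:

* **EZ** — equatorial zones: 16 idealized release rectangles of
  20° longitude × 10° latitude tiling the band 10°S–10°N (scenario 1).
* **FZ** — FAD zones: 1° cells whose observed buoy density or deployment
  count exceeds the 90th percentile of their ocean basin (scenario 2).
* **TZ** — turtle zones: named habitat polygons/rectangles for leatherback
  and hawksbill sea turtles.  A default set of 12 ships with the package
  as an editable YAML config; its coordinates are approximate
  reconstructions of published habitat maps, not authoritative boundaries.

All geometry lives on the 0–360 longitude convention; rectangles may span
the antimeridian and polygons are unwrapped zone-locally so containment
tests are wrap-safe.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import shapely
import yaml
from shapely.geometry import Polygon

from .geo import lon_to_180, wrap_lon

__all__ = [
    "Zone",
    "DensityGrid",
    "ZoneError",
    "make_equatorial_zones",
    "select_fz_cells",
    "load_turtle_zones",
    "load_zone_config",
    "point_in_zone",
    "zones_to_geojson",
    "zones_from_geojson",
]


class ZoneError(ValueError):
    """Invalid zone geometry or configuration."""


def _unwrap_ring(vertices: np.ndarray) -> np.ndarray:
    """Unwrap a lon/lat vertex ring so consecutive lons differ by < 180°."""
    lon = wrap_lon(vertices[:, 0]).astype(float)
    for i in range(1, lon.size):
        d = lon[i] - lon[i - 1]
        if d > 180.0:
            lon[i:] -= 360.0
        elif d < -180.0:
            lon[i:] += 360.0
    out = vertices.astype(float).copy()
    out[:, 0] = lon
    return out


@dataclass
class Zone:
    """A named region with a role (EZ/FZ/TZ) and rectangle or polygon geometry.

    Rectangles are ``(west, south, east, north)`` in degrees with
    inclusive west/south and exclusive east/north edges; a rectangle whose
    east, wrapped to 0–360, is ≤ its west spans the antimeridian.
    """

    id: str
    kind: str  # "EZ" | "FZ" | "TZ"
    rect: tuple[float, float, float, float] | None = None
    polygon: np.ndarray | None = None  # (n, 2) lon/lat vertices
    attributes: dict = field(default_factory=dict)
    _poly: Polygon = field(init=False, repr=False, default=None)
    _lon_range: tuple[float, float] = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        if self.kind not in ("EZ", "FZ", "TZ"):
            raise ZoneError(f"zone {self.id}: unknown kind {self.kind!r}")
        if (self.rect is None) == (self.polygon is None):
            raise ZoneError(f"zone {self.id}: exactly one of rect/polygon required")
        if self.rect is not None:
            w, s, e, n = (float(x) for x in self.rect)
            w, e = wrap_lon(w), wrap_lon(e)
            if e <= w:
                e += 360.0  # antimeridian span
            if not (-90 <= s < n <= 90) or e - w <= 0 or e - w > 360:
                raise ZoneError(f"zone {self.id}: degenerate rectangle {self.rect}")
            self.rect = (w, s, e, n)
        else:
            verts = np.asarray(self.polygon, dtype=float)
            if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
                raise ZoneError(f"zone {self.id}: polygon needs ≥3 lon/lat vertices")
            if np.allclose(verts[0], verts[-1]):
                verts = verts[:-1]  # drop explicit closure
            if verts.shape[0] < 3:
                raise ZoneError(f"zone {self.id}: polygon needs ≥3 distinct vertices")
            if np.any(np.abs(verts[:, 1]) > 90):
                raise ZoneError(f"zone {self.id}: latitude outside [-90, 90]")
            verts = _unwrap_ring(verts)
            self.polygon = verts
            self._poly = Polygon(verts)
            if self._poly.area <= 0 or not self._poly.is_valid:
                raise ZoneError(f"zone {self.id}: degenerate or invalid polygon")
            self._lon_range = (float(verts[:, 0].min()), float(verts[:, 0].max()))

    # -- queries --------------------------------------------------------
    def contains(self, lon, lat):
        """Vectorized point-in-zone test (west/south inclusive, east/north
        exclusive for rectangles; even–odd interior for polygons)."""
        lon = wrap_lon(lon)
        lat = np.asarray(lat, dtype=float)
        if self.rect is not None:
            w, s, e, n = self.rect
            lonq = np.where(lon < w, lon + 360.0, lon)
            return (lonq >= w) & (lonq < e) & (lat >= s) & (lat < n)
        lo, hi = self._lon_range
        # shift each query into the polygon's unwrapped lon frame
        lonq = lon + 360.0 * np.round(((lo + hi) / 2 - lon) / 360.0)
        lonq, latq = np.broadcast_arrays(lonq, lat)
        return shapely.contains_xy(self._poly, lonq, latq)

    def area_sr(self) -> float:
        """Spherical area in steradians (shoelace over (lon_rad, sin lat))."""
        if self.rect is not None:
            w, s, e, n = self.rect
            return float(np.deg2rad(e - w) * (np.sin(np.deg2rad(n)) - np.sin(np.deg2rad(s))))
        lam = np.deg2rad(self.polygon[:, 0])
        z = np.sin(np.deg2rad(self.polygon[:, 1]))
        return float(abs(np.sum(lam * np.roll(z, -1) - np.roll(lam, -1) * z)) / 2.0)

    def bounds(self) -> tuple[float, float, float, float]:
        if self.rect is not None:
            return self.rect
        lo, hi = self._lon_range
        return (lo, float(self.polygon[:, 1].min()), hi, float(self.polygon[:, 1].max()))


def point_in_zone(zone: Zone, lon: float, lat: float) -> bool:
    """Scalar convenience wrapper around :meth:`Zone.contains`."""
    return bool(np.asarray(zone.contains(lon, lat)))


# ---------------------------------------------------------------------------
# Equatorial release zones (scenario 1)
# ---------------------------------------------------------------------------

def make_equatorial_zones(domain_lon_bounds=(120.0, 270.0), rows: int = 2,
                          box_lon_width: float = 20.0,
                          box_lat_height: float = 10.0,
                          lat_band=(-10.0, 10.0),
                          clip_east: bool = True,
                          id_prefix: str = "EZ") -> list[Zone]:
    """Tile the equatorial band into release rectangles.

    Default layout: two latitude rows (0–10°N then 10°S–0) of 8 contiguous
    20°-wide boxes each, numbered west→east with the northern row first
    (EZ1–8) and the southern row second (EZ9–16).  Boxes overrunning the
    eastern domain edge are clipped (``clip_east=True``) or dropped.
    """
    w0, e0 = (float(x) for x in domain_lon_bounds)
    w0, e0 = wrap_lon(w0), wrap_lon(e0)
    if e0 <= w0:
        e0 += 360.0
    if e0 - w0 < box_lon_width:
        raise ZoneError("domain narrower than one box")
    s_band, n_band = lat_band
    if rows * box_lat_height != n_band - s_band:
        raise ZoneError("rows × box height must equal the latitude band height")
    n_cols = int(np.ceil((e0 - w0) / box_lon_width - 1e-9))
    zones: list[Zone] = []
    k = 0
    for row in range(rows):  # northern row first
        north = n_band - row * box_lat_height
        south = north - box_lat_height
        for col in range(n_cols):
            west = w0 + col * box_lon_width
            east = min(west + box_lon_width, e0)
            if east - west <= 0:
                continue
            if east - west < box_lon_width and not clip_east:
                continue
            k += 1
            zones.append(Zone(id=f"{id_prefix}{k}", kind="EZ",
                              rect=(west, south, east % 360.0, north),
                              attributes={"row": row, "col": col}))
    return zones


# ---------------------------------------------------------------------------
# FAD-density grid and FZ selection (scenario 2)
# ---------------------------------------------------------------------------

@dataclass
class DensityGrid:
    """1°×1° buoy-density or deployment-count surface with per-cell basin
    labels (WCPO / EPO); cell centres sit on half-degree offsets."""

    lon_centers: np.ndarray
    lat_centers: np.ndarray
    values: np.ndarray  # (nlat, nlon)
    basin: np.ndarray   # (nlat, nlon) str

    def __post_init__(self) -> None:
        self.lon_centers = wrap_lon(self.lon_centers)
        self.lat_centers = np.asarray(self.lat_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.basin = np.asarray(self.basin)
        shape = (self.lat_centers.size, self.lon_centers.size)
        if self.values.shape != shape or self.basin.shape != shape:
            raise ZoneError("values/basin shape does not match cell centres")
        if np.any(self.values < 0):
            raise ZoneError("density values must be non-negative")
        for name, c in (("lon", self.lon_centers), ("lat", self.lat_centers)):
            if not np.allclose(c % 1.0, 0.5):
                raise ZoneError(f"{name} cell centres must sit on half-degree offsets")

    def to_csv(self, path) -> Path:
        path = Path(path)
        LON, LAT = np.meshgrid(self.lon_centers, self.lat_centers)
        import pandas as pd
        pd.DataFrame({
            "lon": LON.ravel(), "lat": LAT.ravel(),
            "value": self.values.ravel(), "basin": self.basin.ravel(),
        }).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path) -> "DensityGrid":
        import pandas as pd
        df = pd.read_csv(path)
        lon_c = np.unique(wrap_lon(df["lon"].to_numpy()))
        lat_c = np.unique(df["lat"].to_numpy())
        vals = np.zeros((lat_c.size, lon_c.size))
        basin = np.empty((lat_c.size, lon_c.size), dtype=object)
        iy = np.searchsorted(lat_c, df["lat"].to_numpy())
        ix = np.searchsorted(lon_c, wrap_lon(df["lon"].to_numpy()))
        vals[iy, ix] = df["value"].to_numpy()
        basin[iy, ix] = df["basin"].to_numpy()
        return cls(lon_centers=lon_c, lat_centers=lat_c,
                   values=vals, basin=basin.astype(str))


def select_fz_cells(grid: DensityGrid, percentile: float = 90.0,
                    per_basin: bool = True, tag: str = "") -> list[Zone]:
    """Select high-density 1° cells as FZ release zones.

    For each basin independently, the stated percentile (linear
    interpolation) of the *positive* cell values is computed and cells
    whose value is strictly greater are returned as 1°×1° FZ zones tagged
    with their basin.  An empty basin yields an empty selection with a
    warning.
    """
    basins = np.unique(grid.basin) if per_basin else np.array(["ALL"])
    zones: list[Zone] = []
    for basin in basins:
        sel = np.ones_like(grid.values, dtype=bool) if basin == "ALL" \
            else (grid.basin == basin)
        vals = grid.values[sel]
        pos = vals[vals > 0]
        if pos.size == 0:
            warnings.warn(f"basin {basin}: no positive-density cells, "
                          f"empty FZ selection", stacklevel=2)
            continue
        threshold = np.percentile(pos, percentile)
        iy, ix = np.nonzero(sel & (grid.values > threshold))
        for j, i in zip(iy.tolist(), ix.tolist()):
            clon, clat = grid.lon_centers[i], grid.lat_centers[j]
            zid = f"FZ{'-' + tag if tag else ''}-{basin}-{int(clon * 2)}_{int(clat * 2)}"
            zones.append(Zone(
                id=zid, kind="FZ",
                rect=(clon - 0.5, clat - 0.5, (clon + 0.5) % 360.0, clat + 0.5),
                attributes={"basin": str(basin), "value": float(grid.values[j, i]),
                            "percentile": percentile},
            ))
    return zones


# ---------------------------------------------------------------------------
# Turtle-zone registry
# ---------------------------------------------------------------------------

def load_zone_config(path) -> list[Zone]:
    """Load a YAML zone config (list of mappings with id/kind/rect|polygon)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    entries = cfg["zones"] if isinstance(cfg, dict) else cfg
    zones: list[Zone] = []
    seen: set[str] = set()
    for entry in entries:
        zid = entry["id"]
        if zid in seen:
            raise ZoneError(f"duplicate zone id {zid!r}")
        seen.add(zid)
        zones.append(Zone(
            id=zid,
            kind=entry.get("kind", "TZ"),
            rect=tuple(entry["rect"]) if "rect" in entry else None,
            polygon=np.asarray(entry["polygon"], dtype=float) if "polygon" in entry else None,
            attributes=entry.get("attributes", {}),
        ))
    return zones


def load_turtle_zones(config_path=None) -> list[Zone]:
    """Load turtle-habitat zones; with no path, the shipped default set of
    12 (EP1, EP2, EEP, KE1, KE2, CCE, IND, PNG, SB, MHI, MX, CR-NG)."""
    if config_path is None:
        ref = resources.files("fadrift").joinpath("data/turtle_zones.yaml")
        with resources.as_file(ref) as p:
            return load_zone_config(p)
    return load_zone_config(config_path)


# ---------------------------------------------------------------------------
# GeoJSON interchange
# ---------------------------------------------------------------------------

def _rect_ring(rect):
    w, s, e, n = rect
    return [[w, s], [e, s], [e, n], [w, n], [w, s]]


def zones_to_geojson(zones: list[Zone], path) -> Path:
    """Write zones as a GeoJSON FeatureCollection (lons in −180..180)."""
    features = []
    for z in zones:
        ring = _rect_ring(z.rect) if z.rect is not None else \
            np.vstack([z.polygon, z.polygon[:1]]).tolist()
        ring = [[float(lon_to_180(x)), float(y)] for x, y in ring]
        features.append({
            "type": "Feature",
            "properties": {"id": z.id, "kind": z.kind,
                           "is_rect": z.rect is not None, **z.attributes},
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        })
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features},
                               indent=1))
    return path


def zones_from_geojson(path) -> list[Zone]:
    obj = json.loads(Path(path).read_text())
    zones = []
    for feat in obj["features"]:
        props = dict(feat["properties"])
        zid, kind = props.pop("id"), props.pop("kind")
        is_rect = props.pop("is_rect", False)
        ring = np.asarray(feat["geometry"]["coordinates"][0], dtype=float)
        if is_rect:
            lons = wrap_lon(ring[:-1, 0])
            lats = ring[:-1, 1]
            zones.append(Zone(id=zid, kind=kind,
                              rect=(lons[0], float(lats.min()),
                                    lons[1], float(lats.max())),
                              attributes=props))
        else:
            zones.append(Zone(id=zid, kind=kind, polygon=ring, attributes=props))
    return zones
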