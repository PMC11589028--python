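"""Gridded ocean-velocity containers: reading, depth-averaging, interpolation.

The physical forcing for the drift simulations is a gridded field of zonal
(``u``) and meridional (``v``) current velocity in m/s over
``(time[, depth], lat, lon)``.  Real forcing of this shape comes from ocean
reanalyses; the :mod:`fadrift.synth` generators build the same containers
analytically.  Two containers are defined:

:class:`VelocityField`
    The full 3-D (+time) field with optional depth layers.
:class:`FieldSlab`
    A 2-D (+time) field, typically the thickness-weighted average of the
    top 50 m — the drift layer a netted FAD raft samples.

Conventions
-----------
* Longitudes are stored on 0–360 degrees east; files using −180..180 are
  remapped and re-sorted on read.
* Time is stored as float days since the field's ``epoch`` (a calendar
  date string); files are read with CF time decoding disabled and the
  ``days since ...`` units parsed directly.
* Land is a boolean mask over (lat, lon); velocities at land nodes are
  stored as zero so that land contributes zero velocity to the bilinear
  interpolation stencil (particles decelerate toward coasts and can
  strand).  Files may encode land either as a mask variable or as fill
  values in the velocity variables; both dialects are accepted.
* A field with a single time level is treated as time-invariant.  Fields
  with several time levels refuse temporal extrapolation outright.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import xarray as xr

from .geo import wrap_lon

__all__ = [
    "VelocityField",
    "FieldSlab",
    "FormatError",
    "ValidationError",
    "OutOfDomainError",
    "read_velocity",
    "write_velocity",
    "depth_average",
    "sample_velocity",
]

_U_NAMES = ("u", "uo", "U", "water_u", "zonal_velocity")
_V_NAMES = ("v", "vo", "V", "water_v", "meridional_velocity")
_LON_NAMES = ("lon", "longitude", "xt_ocean")
_LAT_NAMES = ("lat", "latitude", "yt_ocean")
_TIME_NAMES = ("time", "Time")
_DEPTH_NAMES = ("depth", "st_ocean", "lev", "z")

DEFAULT_EPOCH = "2000-01-01"


class FormatError(ValueError):
    """A file lacks a required variable or coordinate."""


class ValidationError(ValueError):
    """A field violates a structural invariant (axes, shapes, finiteness)."""


class OutOfDomainError(ValueError):
    """A query point lies outside the field's spatial or temporal coverage."""


def _check_axis(name: str, axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size == 0:
        raise ValidationError(f"{name} axis must be a non-empty 1-D array")
    if axis.size > 1 and not np.all(np.diff(axis) > 0):
        raise ValidationError(f"{name} axis must be strictly increasing")
    if not np.all(np.isfinite(axis)):
        raise ValidationError(f"{name} axis contains non-finite values")
    return axis


@dataclass
class VelocityField:
    """Gridded u/v ocean currents over (time, depth, lat, lon).

    ``depth_interfaces`` holds the nz+1 layer boundaries in metres,
    positive downward (``None`` for a field with no depth axis, in which
    case ``u``/``v`` are (time, lat, lon)).
    """

    lon: np.ndarray
    lat: np.ndarray
    time: np.ndarray
    u: np.ndarray
    v: np.ndarray
    land_mask: np.ndarray
    depth_interfaces: np.ndarray | None = None
    epoch: str = DEFAULT_EPOCH

    def __post_init__(self) -> None:
        self.lon = _check_axis("lon", self.lon)
        self.lat = _check_axis("lat", self.lat)
        self.time = _check_axis("time", self.time)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        if self.depth_interfaces is not None:
            self.depth_interfaces = _check_axis("depth", self.depth_interfaces)
            nz = self.depth_interfaces.size - 1
            expected = (self.time.size, nz, self.lat.size, self.lon.size)
        else:
            expected = (self.time.size, self.lat.size, self.lon.size)
        for name, arr in (("u", self.u), ("v", self.v)):
            if arr.shape != expected:
                raise ValidationError(
                    f"{name} has shape {arr.shape}, expected {expected}"
                )
        if self.land_mask.shape != (self.lat.size, self.lon.size):
            raise ValidationError("land_mask shape does not match grid")
        # Land velocities are forced to zero; ocean values must be finite.
        ocean = ~self.land_mask
        for name, arr in (("u", self.u), ("v", self.v)):
            arr[..., self.land_mask] = 0.0
            if not np.all(np.isfinite(arr[..., ocean])):
                raise ValidationError(f"{name} has non-finite ocean values")

    @property
    def n_layers(self) -> int:
        return 0 if self.depth_interfaces is None else self.depth_interfaces.size - 1


@dataclass
class FieldSlab:
    """Depth-free velocity field (time, lat, lon) with a provenance note."""

    lon: np.ndarray
    lat: np.ndarray
    time: np.ndarray
    u: np.ndarray
    v: np.ndarray
    land_mask: np.ndarray
    epoch: str = DEFAULT_EPOCH
    provenance: str = ""
    # cached cell-edge arrays for nearest-cell lookups
    _lon_edges: np.ndarray = field(init=False, repr=False)
    _lat_edges: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        vf = VelocityField(
            lon=self.lon, lat=self.lat, time=self.time,
            u=self.u, v=self.v, land_mask=self.land_mask, epoch=self.epoch,
        )
        self.lon, self.lat, self.time = vf.lon, vf.lat, vf.time
        self.u, self.v, self.land_mask = vf.u, vf.v, vf.land_mask
        self._lon_edges = _node_edges(self.lon)
        self._lat_edges = _node_edges(self.lat)

    # -- bounds ---------------------------------------------------------
    @property
    def lon_bounds(self) -> tuple[float, float]:
        return float(self.lon[0]), float(self.lon[-1])

    @property
    def lat_bounds(self) -> tuple[float, float]:
        return float(self.lat[0]), float(self.lat[-1])

    @property
    def time_bounds(self) -> tuple[float, float]:
        return float(self.time[0]), float(self.time[-1])

    def covers_time(self, t0: float, t1: float) -> bool:
        if self.time.size == 1:
            return True
        lo, hi = self.time_bounds
        return lo <= t0 and t1 <= hi

    # -- sampling -------------------------------------------------------
    def _time_bracket(self, t: float) -> tuple[int, int, float]:
        if self.time.size == 1:
            return 0, 0, 0.0
        lo, hi = self.time_bounds
        if t < lo or t > hi:
            raise OutOfDomainError(
                f"time {t} outside forcing coverage [{lo}, {hi}] "
                f"(days since {self.epoch}); extrapolation is refused"
            )
        k = int(np.searchsorted(self.time, t, side="right")) - 1
        k = min(max(k, 0), self.time.size - 2)
        w = (t - self.time[k]) / (self.time[k + 1] - self.time[k])
        return k, k + 1, float(w)

    def sample_raw(self, lon, lat, t: float):
        """Vectorized bilinear/linear sampling.

        Returns ``(u, v, on_land, in_bounds)``.  Out-of-bounds points get
        zero velocity and ``in_bounds=False`` (the advection loop turns
        these into domain exits).  Temporal extrapolation raises.
        """
        lon = wrap_lon(lon)
        lat = np.asarray(lat, dtype=float)
        k0, k1, wt = self._time_bracket(t)

        in_bounds = (
            (lon >= self.lon[0]) & (lon <= self.lon[-1])
            & (lat >= self.lat[0]) & (lat <= self.lat[-1])
        )
        lonq = np.clip(lon, self.lon[0], self.lon[-1])
        latq = np.clip(lat, self.lat[0], self.lat[-1])

        nx, ny = self.lon.size, self.lat.size
        ix = np.clip(np.searchsorted(self.lon, lonq, side="right") - 1, 0, max(nx - 2, 0))
        iy = np.clip(np.searchsorted(self.lat, latq, side="right") - 1, 0, max(ny - 2, 0))
        if nx > 1:
            fx = (lonq - self.lon[ix]) / (self.lon[ix + 1] - self.lon[ix])
            ix1 = ix + 1
        else:
            fx = np.zeros_like(lonq)
            ix1 = ix
        if ny > 1:
            fy = (latq - self.lat[iy]) / (self.lat[iy + 1] - self.lat[iy])
            iy1 = iy + 1
        else:
            fy = np.zeros_like(latq)
            iy1 = iy

        def bilinear(a2d):
            return (
                (1 - fy) * ((1 - fx) * a2d[iy, ix] + fx * a2d[iy, ix1])
                + fy * ((1 - fx) * a2d[iy1, ix] + fx * a2d[iy1, ix1])
            )

        if k0 == k1:
            uq = bilinear(self.u[k0])
            vq = bilinear(self.v[k0])
        else:
            uq = (1 - wt) * bilinear(self.u[k0]) + wt * bilinear(self.u[k1])
            vq = (1 - wt) * bilinear(self.v[k0]) + wt * bilinear(self.v[k1])

        # containing cell = nearest grid node's cell
        jx = np.where(fx > 0.5, ix1, ix)
        jy = np.where(fy > 0.5, iy1, iy)
        on_land = self.land_mask[jy, jx] & in_bounds

        uq = np.where(in_bounds, uq, 0.0)
        vq = np.where(in_bounds, vq, 0.0)
        return uq, vq, on_land, in_bounds

    def land_adjacent(self, lon, lat):
        """True where the containing cell or one of its 8 neighbours is land."""
        lon = wrap_lon(np.asarray(lon, dtype=float))
        lat = np.asarray(lat, dtype=float)
        jx = _nearest_index(self._lon_edges, np.clip(lon, self.lon[0], self.lon[-1]))
        jy = _nearest_index(self._lat_edges, np.clip(lat, self.lat[0], self.lat[-1]))
        out = np.zeros(jx.shape, dtype=bool)
        ny, nx = self.land_mask.shape
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                out |= self.land_mask[
                    np.clip(jy + dy, 0, ny - 1), np.clip(jx + dx, 0, nx - 1)
                ]
        return out


def _node_edges(axis: np.ndarray) -> np.ndarray:
    """Midpoint cell edges for a node axis (cells centred on the nodes)."""
    if axis.size == 1:
        return np.array([-np.inf, np.inf])
    mid = 0.5 * (axis[:-1] + axis[1:])
    first = axis[0] - (mid[0] - axis[0])
    last = axis[-1] + (axis[-1] - mid[-1])
    return np.concatenate([[first], mid, [last]])


def _nearest_index(edges: np.ndarray, x: np.ndarray) -> np.ndarray:
    return np.clip(np.searchsorted(edges, x, side="right") - 1, 0, edges.size - 2)


# ---------------------------------------------------------------------------
# NetCDF I/O (CF-style dialect; scipy engine → NetCDF3 classic)
# ---------------------------------------------------------------------------

def _find_name(ds: xr.Dataset, candidates, kind: str, required: bool = True):
    for name in candidates:
        if name in ds.variables:
            return name
    if required:
        raise FormatError(
            f"no {kind} variable found (looked for {', '.join(candidates)})"
        )
    return None


def _parse_epoch(units: str | None) -> str:
    if not units:
        return DEFAULT_EPOCH
    m = re.match(r"\s*days\s+since\s+(\d{4}-\d{2}-\d{2})", units)
    return m.group(1) if m else DEFAULT_EPOCH


def read_velocity(path) -> VelocityField | FieldSlab:
    """Read a CF-style NetCDF velocity file.

    Returns a :class:`VelocityField` when a depth axis is present, else a
    :class:`FieldSlab`.  Longitudes are normalized to 0–360 and re-sorted;
    land is taken from a ``land_mask`` variable if present, otherwise from
    fill values (NaN) in the velocity variables.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        ds.load()
    uname = _find_name(ds, _U_NAMES, "zonal velocity")
    vname = _find_name(ds, _V_NAMES, "meridional velocity")
    lonname = _find_name(ds, _LON_NAMES, "longitude coordinate")
    latname = _find_name(ds, _LAT_NAMES, "latitude coordinate")
    timename = _find_name(ds, _TIME_NAMES, "time coordinate")
    depthname = _find_name(ds, _DEPTH_NAMES, "depth coordinate", required=False)

    lon = wrap_lon(ds[lonname].values)
    order = np.argsort(lon)
    lon = lon[order]
    lat = np.asarray(ds[latname].values, dtype=float)
    time = np.asarray(ds[timename].values, dtype=float)
    epoch = _parse_epoch(ds[timename].attrs.get("units"))

    u = np.asarray(ds[uname].values, dtype=float)[..., order]
    v = np.asarray(ds[vname].values, dtype=float)[..., order]

    if "land_mask" in ds.variables:
        mask = np.asarray(ds["land_mask"].values, dtype=bool)[..., order]
    else:
        mask = ~np.isfinite(u).all(axis=tuple(range(u.ndim - 2)))
    u = np.nan_to_num(u)
    v = np.nan_to_num(v)

    if depthname is not None:
        if "depth_interfaces" in ds.variables:
            interfaces = np.asarray(ds["depth_interfaces"].values, dtype=float)
        else:
            # reconstruct interfaces from mid-layer depths (midpoint rule)
            centers = np.asarray(ds[depthname].values, dtype=float)
            interfaces = _node_edges(centers)
            interfaces[0] = max(interfaces[0], 0.0)
        return VelocityField(
            lon=lon, lat=lat, time=time, u=u, v=v,
            land_mask=mask, depth_interfaces=interfaces, epoch=epoch,
        )
    return FieldSlab(
        lon=lon, lat=lat, time=time, u=u, v=v, land_mask=mask, epoch=epoch,
        provenance=str(ds.attrs.get("provenance", f"read from {path.name}")),
    )


def write_velocity(fld: VelocityField | FieldSlab, path) -> Path:
    """Write a field in the CF-style NetCDF dialect :func:`read_velocity` reads."""
    path = Path(path)
    coords = {
        "time": ("time", fld.time, {"units": f"days since {fld.epoch}"}),
        "lat": ("lat", fld.lat, {"units": "degrees_north"}),
        "lon": ("lon", fld.lon, {"units": "degrees_east"}),
    }
    if isinstance(fld, VelocityField) and fld.depth_interfaces is not None:
        centers = 0.5 * (fld.depth_interfaces[:-1] + fld.depth_interfaces[1:])
        coords["depth"] = ("depth", centers, {"units": "m", "positive": "down"})
        dims = ("time", "depth", "lat", "lon")
        extra = {"depth_interfaces": (("depth_edge",), fld.depth_interfaces, {"units": "m"})}
    else:
        dims = ("time", "lat", "lon")
        extra = {}
    data_vars = {
        "u": (dims, fld.u, {"units": "m s-1", "long_name": "zonal velocity"}),
        "v": (dims, fld.v, {"units": "m s-1", "long_name": "meridional velocity"}),
        "land_mask": (("lat", "lon"), fld.land_mask.astype(np.int8),
                      {"flag_meanings": "ocean land", "flag_values": "0 1"}),
    }
    data_vars.update(extra)
    attrs = {"Conventions": "CF-1.8 (subset)"}
    prov = getattr(fld, "provenance", "")
    if prov:
        attrs["provenance"] = prov
    ds = xr.Dataset(
        {k: xr.DataArray(d, dims=dm, attrs=at) for k, (dm, d, at) in data_vars.items()},
        coords={k: xr.DataArray(d, dims=(dm,), attrs=at) for k, (dm, d, at) in coords.items()},
        attrs=attrs,
    )
    ds.to_netcdf(path, engine="scipy")
    return path


# ---------------------------------------------------------------------------
# Depth averaging
# ---------------------------------------------------------------------------

def depth_average(fld: VelocityField | FieldSlab, z_max: float = 50.0) -> FieldSlab:
    """Thickness-weighted mean of u and v over the depth range [0, z_max] m.

    Each layer contributes a weight equal to the thickness of its overlap
    with [0, z_max]; layers entirely below z_max contribute nothing.  This
    emulates the depth-integrated drift of a FAD whose netting hangs
    through the upper tens of metres.  A field with no depth axis passes
    through unchanged (with a provenance note).
    """
    if z_max <= 0:
        raise ValidationError("z_max must be positive")
    if isinstance(fld, FieldSlab) or fld.depth_interfaces is None:
        slab = fld if isinstance(fld, FieldSlab) else FieldSlab(
            lon=fld.lon, lat=fld.lat, time=fld.time, u=fld.u, v=fld.v,
            land_mask=fld.land_mask, epoch=fld.epoch,
        )
        return replace(slab, provenance=(slab.provenance + "; " if slab.provenance else "")
                       + "no depth axis: passed through unchanged")
    tops = fld.depth_interfaces[:-1]
    bottoms = fld.depth_interfaces[1:]
    weights = np.clip(np.minimum(bottoms, z_max) - np.maximum(tops, 0.0), 0.0, None)
    if weights.sum() <= 0:
        raise ValidationError(
            f"no depth layer overlaps [0, {z_max}] m "
            f"(shallowest interface at {tops[0]} m)"
        )
    w = weights / weights.sum()
    u = np.tensordot(fld.u, w, axes=([1], [0]))  # (time, lat, lon)
    v = np.tensordot(fld.v, w, axes=([1], [0]))
    return FieldSlab(
        lon=fld.lon, lat=fld.lat, time=fld.time, u=u, v=v,
        land_mask=fld.land_mask, epoch=fld.epoch,
        provenance=f"thickness-weighted mean over top {z_max:g} m "
                   f"({weights.size} layers, weights {np.round(weights, 3).tolist()})",
    )


def sample_velocity(slab: FieldSlab, lon, lat, t: float):
    """Sample (u, v, on_land) at points; raises :class:`OutOfDomainError`
    if any query lies outside the spatial or temporal coverage."""
    u, v, on_land, in_bounds = slab.sample_raw(lon, lat, t)
    if not np.all(in_bounds):
        raise OutOfDomainError("query point outside the field's spatial bounds")
    return u, v, on_land
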