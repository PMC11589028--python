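"""From trajectory archives to connectivity matrices and density maps.

The headline statistic of the experiment is *connectivity*: the
percentage of particles released in an origin zone whose **first arrival**
in a turtle zone (TZ) happens within a drift horizon (cumulative 3, 12 or
24 months).  Arrival detection works on the weekly archived snapshots —
a particle inside a TZ at some archived week has arrived; sub-weekly
transits through a small TZ can be missed, which is a documented
limitation of the archiving cadence.

Density maps are the complementary spatial picture: the share of archived
particle-weeks falling in each 1° cell during a drift window (short
[0, 3), moderate [3, 12), long [12, 24] months), normalized to sum to one
over the pooled particle set.

Repeated runs (distinct forcings, shared schedule) are pooled by
weeks-since-release, not calendar date.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .advection import EXITED, TrajectorySet
from .geo import months_to_weeks, wrap_lon
from .zones import Zone

__all__ = [
    "ConnectivityMatrix", "DensityMap",
    "detect_arrivals", "connectivity", "density_map", "pool_runs",
    "drift_windows", "write_outputs",
]

#: Cumulative connectivity horizons in months.
DEFAULT_HORIZONS = (3.0, 12.0, 24.0)

#: Density-map drift windows in months: short, moderate, long.
DRIFT_WINDOWS = ((0.0, 3.0), (3.0, 12.0), (12.0, 24.0))


def drift_windows():
    """The standard (short, moderate, long) drift windows in months."""
    return DRIFT_WINDOWS


# ---------------------------------------------------------------------------
# Arrival detection
# ---------------------------------------------------------------------------

def detect_arrivals(trajset: TrajectorySet, turtle_zones: list[Zone]) -> pd.DataFrame:
    """First-arrival records: one row per (particle, TZ) that was ever hit.

    Columns: ``particle_id``, ``origin_zone``, ``tz_id``,
    ``first_arrival_week`` (weeks since that particle's release).
    Beached positions count (a particle stranded inside a coastal TZ has
    arrived); exited particles stop accruing arrivals at their exit week.
    """
    ids = [z.id for z in turtle_zones]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate TZ ids: {dupes}")
    valid = trajset.status != EXITED  # (P, W+1)
    rows = []
    weeks = np.arange(trajset.n_archives)
    for zone in turtle_zones:
        inside = np.asarray(zone.contains(trajset.lon, trajset.lat)) & valid
        hit = inside.any(axis=1)
        if not np.any(hit):
            continue
        first = np.where(inside[hit], weeks[None, :], trajset.n_archives).min(axis=1)
        rows.append(pd.DataFrame({
            "particle_id": trajset.particle_id[hit],
            "origin_zone": trajset.origin_zone[hit],
            "tz_id": zone.id,
            "first_arrival_week": first.astype(int),
        }))
    if not rows:
        return pd.DataFrame(columns=["particle_id", "origin_zone", "tz_id",
                                     "first_arrival_week"])
    return pd.concat(rows, ignore_index=True)


def released_counts(trajset: TrajectorySet) -> pd.Series:
    """Particles released per origin zone."""
    return pd.Series(trajset.origin_zone).value_counts().sort_index()


# ---------------------------------------------------------------------------
# Connectivity matrix
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityMatrix:
    """Origin × TZ × horizon percentages plus released counts and the
    "other" share (particles that reached no TZ by the final horizon)."""

    table: pd.DataFrame        # index: origin; columns: MultiIndex (tz, months)
    released: pd.Series        # per-origin release counts
    other: pd.Series           # per-origin % that arrived in no TZ
    horizons: tuple            # months

    def entry(self, origin: str, tz: str, months: float) -> float:
        return float(self.table.loc[origin, (tz, months)])

    def is_monotone(self) -> bool:
        tzs = self.table.columns.get_level_values(0).unique()
        for tz in tzs:
            sub = self.table[tz][list(self.horizons)].to_numpy()
            if np.any(np.diff(sub, axis=1) < -1e-12):
                return False
        return True

    def to_csv(self, path) -> Path:
        flat = self.table.copy()
        flat.columns = [f"{tz}_{m:g}mo" for tz, m in flat.columns]
        flat.insert(0, "released", self.released.reindex(flat.index))
        flat["other"] = self.other.reindex(flat.index)
        flat.index.name = "origin"
        # pinned float formatting so identical runs give identical bytes
        flat.to_csv(path, float_format="%.6f")
        return Path(path)

    @classmethod
    def from_csv(cls, path) -> "ConnectivityMatrix":
        flat = pd.read_csv(path, index_col="origin")
        released = flat.pop("released")
        other = flat.pop("other")
        pairs = []
        for col in flat.columns:
            tz, mo = col.rsplit("_", 1)
            pairs.append((tz, float(mo[:-2])))
        flat.columns = pd.MultiIndex.from_tuples(pairs)
        horizons = tuple(sorted(set(m for _, m in pairs)))
        return cls(table=flat, released=released, other=other, horizons=horizons)


def connectivity(records: pd.DataFrame, released: pd.Series,
                 horizons=DEFAULT_HORIZONS,
                 tz_ids: list[str] | None = None) -> ConnectivityMatrix:
    """Cumulative connectivity percentages from first-arrival records.

    ``entry(o, z, H) = 100 · #{particles from o with first_arrival_week ≤
    weeks(H)} / released(o)`` with the same months→weeks flooring used by
    the advection archive.  ``other`` is 100 minus the percentage that
    arrived in at least one TZ by the final horizon.
    """
    released = pd.Series(released).astype(float)
    if (released <= 0).any():
        raise ValueError("released counts must be positive for every origin")
    if len(records) and not set(records["origin_zone"]) <= set(released.index):
        unknown = sorted(set(records["origin_zone"]) - set(released.index))
        raise ValueError(f"records reference unknown origin zones: {unknown}")
    horizons = tuple(float(h) for h in horizons)
    if tz_ids is None:
        tz_ids = sorted(records["tz_id"].unique()) if len(records) else []
    origins = list(released.index)
    cols = pd.MultiIndex.from_product([tz_ids, horizons])
    table = pd.DataFrame(0.0, index=origins, columns=cols)
    for h in horizons:
        wmax = months_to_weeks(h)
        sub = records[records["first_arrival_week"] <= wmax] if len(records) else records
        if len(sub):
            counts = sub.groupby(["origin_zone", "tz_id"]).size()
            for (o, z), c in counts.items():
                if z in tz_ids:
                    table.loc[o, (z, h)] = 100.0 * c / released[o]
    # "other": particles that reached no TZ within the final horizon
    other = pd.Series(100.0, index=origins)
    if len(records):
        wmax = months_to_weeks(max(horizons))
        reached = records[records["first_arrival_week"] <= wmax] \
            .groupby("origin_zone")["particle_id"].nunique()
        for o in origins:
            other[o] = 100.0 * (1.0 - reached.get(o, 0) / released[o])
    return ConnectivityMatrix(table=table, released=released.astype(int),
                              other=other, horizons=horizons)


# ---------------------------------------------------------------------------
# Density maps
# ---------------------------------------------------------------------------

@dataclass
class DensityMap:
    """Gridded share of archived particle-weeks per cell in a drift window."""

    lon_edges: np.ndarray
    lat_edges: np.ndarray
    values: np.ndarray          # (nlat, nlon), sums to 1 if n_positions > 0
    window_months: tuple
    n_positions: int
    meta: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.n_positions == 0

    def to_dataset(self) -> xr.Dataset:
        lon_c = 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])
        lat_c = 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])
        return xr.Dataset(
            {"density": (("lat", "lon"), self.values)},
            coords={"lon": ("lon", lon_c, {"units": "degrees_east"}),
                    "lat": ("lat", lat_c, {"units": "degrees_north"})},
            attrs={"window_months": list(self.window_months),
                   "n_positions": self.n_positions,
                   **{k: str(v) for k, v in self.meta.items()}},
        )

    def to_netcdf(self, path) -> Path:
        self.to_dataset().to_netcdf(path, engine="scipy")
        return Path(path)


def _window_weeks(window_months, max_week: int) -> tuple[int, int, bool]:
    w0, w1 = window_months
    lo, hi = months_to_weeks(w0), months_to_weeks(w1)
    inclusive = hi >= max_week  # final window closes the archive
    return lo, hi, inclusive


def density_map(trajsets, window_months=(0.0, 3.0), resolution: float = 1.0,
                lon_bounds=(120.0, 270.0), lat_bounds=(-30.0, 50.0)) -> DensityMap:
    """Bin archived positions with week-offset inside the window.

    Pooling across runs happens before normalization; exited particles'
    frozen boundary positions are excluded.  An empty window returns an
    all-zero map flagged empty instead of dividing by zero.
    """
    if isinstance(trajsets, TrajectorySet):
        trajsets = [trajsets]
    lon_edges = np.arange(lon_bounds[0], lon_bounds[1] + resolution / 2, resolution)
    lat_edges = np.arange(lat_bounds[0], lat_bounds[1] + resolution / 2, resolution)
    counts = np.zeros((lat_edges.size - 1, lon_edges.size - 1))
    total = 0
    for ts in trajsets:
        lo, hi, inclusive = _window_weeks(window_months, ts.n_archives - 1)
        hi_idx = min(hi + (1 if inclusive else 0), ts.n_archives)
        if hi_idx <= lo:
            continue
        lon = ts.lon[:, lo:hi_idx]
        lat = ts.lat[:, lo:hi_idx]
        keep = ts.status[:, lo:hi_idx] != EXITED
        lon = wrap_lon(lon[keep])
        lat = lat[keep]
        if lon.size == 0:
            continue
        H, _, _ = np.histogram2d(lat, lon, bins=[lat_edges, lon_edges])
        counts += H
        total += lon.size
    values = counts / total if total > 0 else counts
    return DensityMap(lon_edges=lon_edges, lat_edges=lat_edges, values=values,
                      window_months=tuple(window_months), n_positions=int(total),
                      meta={"runs_pooled": len(trajsets),
                            "resolution_deg": resolution})


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------

def pool_runs(trajsets: list[TrajectorySet]) -> TrajectorySet:
    """Concatenate repeated runs into one particle set, re-keying ids.

    Runs must share the release schedule and archive shape; alignment is
    by weeks-since-release, never calendar date, so repetitions forced by
    different years pool cleanly.
    """
    if not trajsets:
        raise ValueError("no runs to pool")
    ref = trajsets[0]
    sched = ref.meta.get("schedule")
    for ts in trajsets[1:]:
        if ts.n_archives != ref.n_archives:
            raise ValueError("runs have different archive lengths")
        if ts.meta.get("schedule") != sched:
            raise ValueError("runs have different release schedules")
    offsets = np.cumsum([0] + [ts.n_particles for ts in trajsets[:-1]])
    return TrajectorySet(
        lon=np.vstack([ts.lon for ts in trajsets]),
        lat=np.vstack([ts.lat for ts in trajsets]),
        status=np.vstack([ts.status for ts in trajsets]),
        origin_zone=np.concatenate([ts.origin_zone for ts in trajsets]),
        release_time=np.concatenate([ts.release_time for ts in trajsets]),
        particle_id=np.concatenate(
            [ts.particle_id + off for ts, off in zip(trajsets, offsets)]),
        epoch=ref.epoch,
        meta={**ref.meta, "runs_pooled": len(trajsets),
              "forcings": [ts.meta.get("forcing", "?") for ts in trajsets]},
    )


# ---------------------------------------------------------------------------
# Output bundle
# ---------------------------------------------------------------------------

def write_outputs(matrix: ConnectivityMatrix, maps: list[DensityMap],
                  outdir, manifest: dict | None = None) -> dict:
    """Write the connectivity CSV, density-map NetCDFs and a run manifest.

    Returns a dict of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"connectivity": matrix.to_csv(outdir / "connectivity.csv")}
    for dmap in maps:
        w0, w1 = dmap.window_months
        p = outdir / f"density_{w0:g}-{w1:g}mo.nc"
        dmap.to_netcdf(p)
        paths[f"density_{w0:g}-{w1:g}mo"] = p
    man = {
        "horizons_months": list(matrix.horizons),
        "windows_months": [list(m.window_months) for m in maps],
        "released_total": int(matrix.released.sum()),
        **(manifest or {}),
    }
    mp = outdir / "manifest.json"
    mp.write_text(json.dumps(man, indent=1, default=str))
    paths["manifest"] = mp
    return paths
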