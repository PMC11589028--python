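"""Synthetic velocity fields, land masks and buoy-density grids.

Everything downstream of the forcing — seeding, RK4 advection, arrival
detection, connectivity, density maps — is testable against these
generators because their structure is known in closed form:

* :func:`make_uniform_flow` — constant (u0, v0) everywhere; RK4 is exact.
* :func:`make_solid_rotation` — rigid rotation in a local equirectangular
  plane; trajectories are exact circles with a known period.
* :func:`make_double_gyre` — the standard time-periodic two-gyre benchmark
  on a [0, 2] × [0, 1] plane mapped onto the grid rectangle; divergence-free
  and widely used to validate Lagrangian integrators.
* :func:`make_equatorial_system` — a deliberately qualitative idealization
  of the tropical Pacific: a westward South Equatorial Current, an eastward
  countercurrent, two subtropical gyres, a western archipelago arc
  (a PNG/Solomons-like barrier) and an eastern continental wall.
* :func:`make_density_grid` — a 1° buoy-density / deployment surface with
  Gaussian hotspots, standing in for observed FAD-buoy databases.

All generators are pure functions of (parameters, grid, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .fields import FieldSlab
from .geo import METERS_PER_DEGREE
from .zones import DensityGrid

__all__ = [
    "Grid",
    "FlowSpec",
    "make_flow",
    "make_uniform_flow",
    "make_solid_rotation",
    "make_double_gyre",
    "make_equatorial_system",
    "make_density_grid",
    "land_template",
    "LAND_TEMPLATES",
]


@dataclass
class Grid:
    """Lon/lat/time axes for a generated field (lon degrees east 0–360,
    lat degrees north, time days since the epoch)."""

    lon: np.ndarray
    lat: np.ndarray
    time: np.ndarray
    epoch: str = "2000-01-01"

    @classmethod
    def regular(cls, lon_bounds=(120.0, 270.0), lat_bounds=(-30.0, 50.0),
                resolution=1.0, time_days=(0.0, 730.0), epoch="2000-01-01"):
        lon = np.arange(lon_bounds[0], lon_bounds[1] + resolution / 2, resolution)
        lat = np.arange(lat_bounds[0], lat_bounds[1] + resolution / 2, resolution)
        return cls(lon=lon, lat=lat, time=np.asarray(time_days, dtype=float),
                   epoch=epoch)

    def mesh(self):
        return np.meshgrid(self.lon, self.lat)  # (LON, LAT) each (nlat, nlon)


@dataclass
class FlowSpec:
    """Serializable recipe for a synthetic flow (config-file friendly)."""

    kind: str  # uniform | solid_rotation | double_gyre | equatorial_system
    parameters: dict = dc_field(default_factory=dict)
    grid: dict = dc_field(default_factory=dict)
    seed: int = 0


def make_flow(spec: FlowSpec) -> FieldSlab:
    """Build the FieldSlab described by a :class:`FlowSpec`."""
    grid = Grid.regular(**spec.grid) if spec.grid else Grid.regular()
    makers = {
        "uniform": lambda: make_uniform_flow(grid=grid, **spec.parameters),
        "solid_rotation": lambda: make_solid_rotation(grid=grid, **spec.parameters),
        "double_gyre": lambda: make_double_gyre(grid=grid, **spec.parameters),
        "equatorial_system": lambda: make_equatorial_system(
            grid=grid, seed=spec.seed, **spec.parameters),
    }
    if spec.kind not in makers:
        raise ValueError(
            f"unknown flow kind {spec.kind!r}; expected one of {sorted(makers)}"
        )
    return makers[spec.kind]()


def _steady(grid: Grid, U: np.ndarray, V: np.ndarray, mask=None,
            provenance: str = "") -> FieldSlab:
    """Broadcast a steady (lat, lon) velocity over the grid's time axis."""
    nt = grid.time.size
    if mask is None:
        mask = np.zeros((grid.lat.size, grid.lon.size), dtype=bool)
    u = np.broadcast_to(U, (nt, *U.shape)).copy()
    v = np.broadcast_to(V, (nt, *V.shape)).copy()
    return FieldSlab(lon=grid.lon, lat=grid.lat, time=grid.time,
                     u=u, v=v, land_mask=mask, epoch=grid.epoch,
                     provenance=provenance)


def make_uniform_flow(u0: float, v0: float, grid: Grid) -> FieldSlab:
    """Constant (u0, v0) m/s at every ocean node; no land."""
    if not (np.isfinite(u0) and np.isfinite(v0)):
        raise ValueError("u0 and v0 must be finite")
    shape = (grid.lat.size, grid.lon.size)
    return _steady(grid, np.full(shape, float(u0)), np.full(shape, float(v0)),
                   provenance=f"uniform flow u0={u0} v0={v0} m/s")


def make_solid_rotation(center_lon: float, center_lat: float,
                        omega: float, grid: Grid) -> FieldSlab:
    """Rigid rotation about a centre, ``omega`` in rad/day (positive =
    counterclockwise).

    The rotation is rigid in the local equirectangular plane
    ``X = R cos(lat_c) (lon − lon_c)``, ``Y = R (lat − lat_c)`` (radians):
    plane velocity (dX/dt, dY/dt) = (−ω Y, ω X).  The *ground* zonal
    velocity therefore carries a cos(lat)/cos(lat_c) factor, which makes
    simulated trajectories exact circles of period 2π/ω in that plane —
    a closed-form oracle for the integrator.
    """
    LON, LAT = grid.mesh()
    coslatc = np.cos(np.deg2rad(center_lat))
    dlon = (LON - center_lon + 180.0) % 360.0 - 180.0  # shortest wrap
    X = METERS_PER_DEGREE * coslatc * dlon
    Y = METERS_PER_DEGREE * (LAT - center_lat)
    omega_s = omega / 86400.0  # rad/s
    coslat = np.cos(np.deg2rad(LAT))
    U = -omega_s * Y * coslat / coslatc
    V = omega_s * X
    return _steady(grid, U, V,
                   provenance=f"solid rotation centre=({center_lon},{center_lat}) "
                              f"omega={omega} rad/day")


def make_double_gyre(A: float, epsilon: float, omega: float,
                     grid: Grid) -> FieldSlab:
    """Time-periodic double-gyre benchmark flow.

    Stream function ψ(x, y, t) = A sin(π f(x, t)) sin(π y) on the plane
    rectangle [0, 2] × [0, 1] (mapped from the grid's lon/lat rectangle),
    with f(x, t) = ε sin(ωt) x² + (1 − 2ε sin(ωt)) x; velocities
    u = −∂ψ/∂y, v = ∂ψ/∂x.  ``A`` is a velocity scale in m/s, ``omega``
    in rad/day.  ψ vanishes on the rectangle boundary, so the normal
    velocity there is zero and the flow is divergence-free.  With ε = 0
    the two counter-rotating gyres are steady and symmetric.
    """
    if A <= 0:
        raise ValueError("A must be positive")
    if not (0 <= epsilon < 0.5):
        raise ValueError("epsilon must lie in [0, 0.5)")
    LON, LAT = grid.mesh()
    x = 2.0 * (LON - grid.lon[0]) / (grid.lon[-1] - grid.lon[0])
    y = (LAT - grid.lat[0]) / (grid.lat[-1] - grid.lat[0])
    nt = grid.time.size
    u = np.empty((nt, *x.shape))
    v = np.empty((nt, *x.shape))
    omega_s = omega / 86400.0
    for k, t in enumerate(grid.time * 86400.0):
        s = epsilon * np.sin(omega_s * t)
        f = s * x**2 + (1 - 2 * s) * x
        dfdx = 2 * s * x + (1 - 2 * s)
        u[k] = -np.pi * A * np.sin(np.pi * f) * np.cos(np.pi * y)
        v[k] = np.pi * A * np.cos(np.pi * f) * np.sin(np.pi * y) * dfdx
    mask = np.zeros(x.shape, dtype=bool)
    return FieldSlab(lon=grid.lon, lat=grid.lat, time=grid.time, u=u, v=v,
                     land_mask=mask, epoch=grid.epoch,
                     provenance=f"double gyre A={A} eps={epsilon} omega={omega}")


# ---------------------------------------------------------------------------
# Idealized equatorial Pacific
# ---------------------------------------------------------------------------

#: Default jet/gyre parameters for the idealized equatorial current system.
#: Latitudes in degrees, speeds in m/s (negative zonal = westward), widths
#: are Gaussian sigmas in degrees.  Values are rounded climatological
#: magnitudes for the tropical Pacific surface circulation.
EQUATORIAL_DEFAULTS = {
    "sec_lat": -3.0, "sec_speed": -0.40, "sec_width": 5.0,      # South Equatorial Current
    "necc_lat": 7.0, "necc_speed": 0.30, "necc_width": 2.5,     # N. Equatorial Countercurrent
    "nec_lat": 15.0, "nec_speed": -0.20, "nec_width": 4.0,      # North Equatorial Current
    "north_gyre_lat": 30.0, "north_gyre_lon": 190.0,
    "south_gyre_lat": -22.0, "south_gyre_lon": 210.0,
    "gyre_strength": 0.25,   # peak rotational speed, m/s
    "gyre_radius": 18.0,     # degrees
    "noise_amplitude": 0.0,  # optional seeded stationary noise, m/s
}


def _archipelago_mask(grid: Grid) -> np.ndarray:
    """Idealized western-Pacific archipelago arc + eastern continental wall."""
    LON, LAT = grid.mesh()
    mask = np.zeros(LON.shape, dtype=bool)
    # western archipelago: arc of island blocks from ~(128E, 2N) down to
    # ~(162E, 11S), loosely the Indonesia–PNG–Solomons line
    arc = [
        (124.0, 131.0, -8.0, 4.0),    # Indonesian block
        (130.0, 140.0, -9.0, -1.0),
        (138.0, 150.0, -11.0, -4.0),  # New Guinea
        (148.0, 156.0, -11.0, -5.0),
        (155.0, 163.0, -12.0, -6.0),  # Solomons
    ]
    for w, e, s, n in arc:
        mask |= (LON >= w) & (LON < e) & (LAT >= s) & (LAT < n)
    # eastern continental wall (the Americas)
    mask |= LON >= grid.lon[-1] - 3.0
    return mask


LAND_TEMPLATES = {
    "none": lambda grid: np.zeros((grid.lat.size, grid.lon.size), dtype=bool),
    "idealized_pacific": _archipelago_mask,
}


def land_template(name: str, grid: Grid) -> np.ndarray:
    try:
        return LAND_TEMPLATES[name](grid)
    except KeyError:
        raise ValueError(
            f"unknown land template {name!r}; expected one of {sorted(LAND_TEMPLATES)}"
        ) from None


def make_equatorial_system(grid: Grid, params: dict | None = None,
                           land: str = "idealized_pacific",
                           seed: int = 0) -> FieldSlab:
    """Qualitative idealization of the equatorial-Pacific current system.

    Gaussian-in-latitude zonal jets (SEC westward, NECC eastward, NEC
    westward) blended with two subtropical gyre circulations built from
    Gaussian stream-function blobs; zero velocity on land.  The intent is
    directionally faithful drift behaviour (FADs tracking westward along
    the equator, entrainment into the gyres, stranding on the western
    archipelago), not geophysical realism.
    """
    p = dict(EQUATORIAL_DEFAULTS)
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise ValueError(f"unknown equatorial-system parameters: {sorted(unknown)}")
        p.update(params)
    LON, LAT = grid.mesh()
    U = np.zeros(LON.shape)
    V = np.zeros(LON.shape)
    for latc, speed, width in (
        (p["sec_lat"], p["sec_speed"], p["sec_width"]),
        (p["necc_lat"], p["necc_speed"], p["necc_width"]),
        (p["nec_lat"], p["nec_speed"], p["nec_width"]),
    ):
        U += speed * np.exp(-(((LAT - latc) / width) ** 2))

    # gyres via stream-function blobs: psi = S r0 exp(-r^2 / (2 r0^2)),
    # u = -dpsi/dy, v = dpsi/dx gives peak speed ~S at r = r0
    for lonc, latc, sign in (
        (p["north_gyre_lon"], p["north_gyre_lat"], -1.0),   # anticyclonic NH
        (p["south_gyre_lon"], p["south_gyre_lat"], 1.0),    # anticyclonic SH
    ):
        r0 = p["gyre_radius"]
        S = sign * p["gyre_strength"] * np.exp(0.5)
        dx = (LON - lonc) * np.cos(np.deg2rad(latc))
        dy = LAT - latc
        expo = np.exp(-(dx**2 + dy**2) / (2 * r0**2))
        U += S * dy / r0 * expo
        V += -S * dx / r0 * expo

    if p["noise_amplitude"] > 0:
        rng = np.random.default_rng(seed)
        U = U + rng.normal(0.0, p["noise_amplitude"], U.shape)
        V = V + rng.normal(0.0, p["noise_amplitude"], V.shape)

    mask = land_template(land, grid)
    U[mask] = 0.0
    V[mask] = 0.0
    return _steady(grid, U, V, mask=mask,
                   provenance=f"idealized equatorial system (land={land}, seed={seed})")


# ---------------------------------------------------------------------------
# Synthetic buoy-density / deployment grids
# ---------------------------------------------------------------------------

def make_density_grid(lon_bounds=(120.0, 270.0), lat_bounds=(-10.0, 10.0),
                      hotspots=(), baseline: float = 1.0, seed: int = 0,
                      noise: float = 0.0, basin_split_lon: float = 210.0,
                      land_mask_fn=None) -> DensityGrid:
    """Synthetic 1° buoy-density (or deployment-count) surface.

    ``hotspots`` is a list of ``(center_lon, center_lat, amplitude,
    radius_deg)`` Gaussian bumps added to a uniform ``baseline``; optional
    seeded log-normal noise.  Cells west of ``basin_split_lon`` are
    labelled WCPO, the rest EPO.
    """
    lon_c = np.arange(np.floor(lon_bounds[0]) + 0.5, lon_bounds[1], 1.0)
    lat_c = np.arange(np.floor(lat_bounds[0]) + 0.5, lat_bounds[1], 1.0)
    LON, LAT = np.meshgrid(lon_c, lat_c)
    vals = np.full(LON.shape, float(baseline))
    for clon, clat, amp, radius in hotspots:
        d2 = ((LON - clon) * np.cos(np.deg2rad(clat))) ** 2 + (LAT - clat) ** 2
        vals += amp * np.exp(-d2 / (2 * radius**2))
    if noise > 0:
        rng = np.random.default_rng(seed)
        vals *= rng.lognormal(0.0, noise, vals.shape)
    if land_mask_fn is not None:
        vals[land_mask_fn(LON, LAT)] = 0.0
    basin = np.where(LON < basin_split_lon, "WCPO", "EPO")
    return DensityGrid(lon_centers=lon_c, lat_centers=lat_c,
                       values=vals, basin=basin)
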