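# fadrift

Lagrangian drift simulation of **drifting fish aggregating devices
(dFADs)** and their connectivity with **sea-turtle habitat zones** in the
Pacific Ocean.

Tropical tuna purse-seine fleets deploy tens of thousands of dFADs —
rafts with netting hanging through the upper tens of metres — which drift
with the currents for months to years. Lost or abandoned dFADs can
entangle sea turtles at sea and damage coastal habitat when they strand.
`fadrift` simulates virtual FADs (vFADs) as passive Lagrangian particles
in gridded ocean-current fields and quantifies where they go: which
turtle habitats they reach, how fast, and where they accumulate or
strand. It is aimed at movement ecologists and fisheries scientists who
want a tested, reproducible drift-connectivity pipeline that runs on
anything from analytic test flows to full ocean-reanalysis forcing.

## The model

Each particle obeys pure advection by the depth-averaged upper-ocean
flow (no diffusion, windage or Stokes drift):

```
dx/dt = u(x, t)        u = thickness-weighted mean of the top 50 m currents
```

integrated with classic fourth-order Runge–Kutta at a 6-hour step,
bilinear velocity interpolation in space and linear in time, positions
archived weekly for up to 24 months. Particles are released weekly for a
year starting 1 July, either uniformly across sixteen 20°×10° equatorial
boxes (EZ, scenario 1; 30 particles per 1° ocean cell ⇒ 6000 per box) or
in 1° cells whose observed buoy density/deployment count exceeds the
90th percentile of their ocean basin (FZ, scenario 2). Particles strand
("beach") when they enter a land cell or stall next to the coast, and
freeze when they exit the domain (120°E–90°W, 30°S–50°N).

The headline statistic is the **connectivity matrix**

```
C(o, z, H) = 100 · #{particles released in o whose first arrival in turtle zone z
                     occurred within drift horizon H} / #released(o)
```

for cumulative horizons H ∈ {3, 12, 24} months, against twelve named
turtle zones (EP1, EP2, EEP, KE1, KE2, CCE, IND, PNG, SB, MHI, MX,
CR-NG). Density maps give the complementary spatial picture: the share
of archived particle-weeks per 1° cell in the short (<3 mo), moderate
(3–12 mo) and long (12–24 mo) drift windows.

A synthetic-data module generates forcing with known closed-form
structure — uniform flow, rigid rotation, the time-periodic double-gyre
benchmark, an idealized equatorial-Pacific current system with a western
archipelago and eastern continental wall, and synthetic buoy-density
grids — so every pipeline stage is validated without external data.

## Worked example

```python
from fadrift.experiments import idealized_demo

trajset, s = idealized_demo(seed=0)   # 16 boxes × 200 particles × 4 releases, 12 mo
m = s["matrix"]
print(f"released {s['n_released']} particles, {s['n_archives']} weekly archives")
print(f"beached: {100*s['beached_fraction']:.1f}%  "
      f"stranded on western archipelago: {100*s['stranded_west_fraction']:.1f}%")
print(f"southern-band mean zonal displacement: "
      f"{s['southern_band_mean_dlon_deg']:.2f} deg")
print(f"EZ16 -> EP2 within 3 mo: {m.entry('EZ16', 'EP2', 3.0):.1f}%")
```

prints

```
released 12800 particles, 53 weekly archives
beached: 37.5%  stranded on western archipelago: 27.3%
southern-band mean zonal displacement: -3.01 deg
EZ16 -> EP2 within 3 mo: 26.2%
```

Reading: of 12,800 particles released across the 16 equatorial boxes,
37.5% strand within a year (27.3% on the idealized PNG/Solomons
archipelago arc); particles seeded in the southwestern equatorial band
drift west on average (−3° of longitude), carried by the South
Equatorial Current; and a quarter of the particles from the
southeasternmost box reach the eastern-Pacific leatherback foraging zone
EP2 within three months. The numbers are properties of the idealized
synthetic forcing — directionally faithful, not geophysical estimates.

The same pipeline runs from the shell against a YAML config:

```sh
fadrift synth   config.yaml    # write forcing (and density grid) files
fadrift simulate config.yaml   # seed + advect, write trajectories.nc
fadrift connect config.yaml    # arrivals, connectivity.csv, density maps
```

Real forcing is ingested from CF-style NetCDF (zonal/meridional
velocity over time × depth × lat × lon; land as a mask variable or fill
values; either longitude convention) and depth-averaged over the top
50 m before advection.

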