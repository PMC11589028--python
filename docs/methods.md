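# Methods

## Physical model and assumptions

Virtual FADs are passive tracers of the depth-averaged upper-ocean
velocity: `dx/dt = u(x, t)`. The model deliberately excludes diffusion,
windage, Stokes drift, vertical motion and any dFAD decay or loss
process — drift is advection by the resolved currents only, which
matches how netted dFAD rafts (median net depth 40–50 m) sample the
upper water column more than the surface skin. The drift layer is the
thickness-weighted mean of the velocity over 0–50 m: each depth layer
contributes the thickness of its overlap with [0, 50 m], which is
correct for unevenly spaced model levels (a plain level mean is not).

Coordinates live on a spherical Earth (R = 6371 km) with longitudes on
0–360°E internally, because the study domain (120°E–90°W) crosses the
antimeridian; all I/O accepts either longitude convention, and
conversion from m/s to degrees scales the zonal component by
1/cos(latitude).

## Integration and archiving

Classic fourth-order Runge–Kutta with a 6-hour step; velocities are
sampled bilinearly in space and linearly in time at every stage.
Positions are archived every 7 days; a track of M months spans
`floor(M × 30.4375 / 7)` weekly archives (24 months ⇒ 104 archives after
release). Temporal extrapolation of the forcing is a hard error — the
forcing must cover release through the end of tracking, checked before
any integration — while a single-time-level field is treated as steady.

**Coastal behaviour.** Land cells contribute zero velocity to the
bilinear stencil, so particles decelerate smoothly toward coasts rather
than bouncing off a masked stencil. A particle is **beached** when its
containing grid cell is land, or when its weekly-mean speed stays below
`beach_speed_eps` (default 10⁻³ m/s ≈ 600 m/week) for `beach_weeks`
(default 4) consecutive archives while within one cell of land. Both
thresholds are configurable and recorded in run metadata; no published
stranding criterion exists for dFADs at this scale, so the rule is the
package's own, chosen to make stranding an emergent property of the
coastal deceleration. Beached particles keep their frozen position in
all later archives and still count toward arrivals and densities — a
dFAD stranded inside a coastal habitat zone has plainly arrived there.
A particle that crosses the domain bounds (default 120°E–90°W,
30°S–50°N) is **exited**: frozen at the crossing, it accrues no further
arrivals, and its frozen boundary position is excluded from density
maps so edge cells are not artificially inflated.

In a divergence-free flow without land neither rule can fire, which the
tests assert.

## Release design

Weekly releases (default 52) starting 1 July, tracked 24 months. Two
seeding modes:

* `per_cell_density` (default 30): N particles in every 1°×1° cell whose
  centre is ocean and inside the zone, uniform within the cell. This is
  the implementation of "~30 particles / 100 km²": a 1° equatorial cell
  is ≈ 12,300 km², but the published count of ≈6000 particles per
  20°×10° box fixes the intended reading at 30 per 1° cell (200 cells ×
  30 = 6000), so the cell-count interpretation is used and machine-checked.
* `per_zone_count`: exactly that many uniform-random ocean points per
  zone, by rejection sampling against the land mask (error after 200
  rounds, naming the zone).

Randomness derives from `(seed, release_index)` so any single release
can be reproduced without rerunning the schedule. Repeated runs under
distinct forcings (the interannual-sensitivity design) share schedule
and seed and are pooled by weeks-since-release before analysis.

## Zones

* **EZ** — two rows (0–10°N, 10°S–0) of eight 20°-wide boxes numbered
  west→east, northern row first (EZ1–8, then EZ9–16). The 150°-wide
  domain does not divide evenly by 20°, so the easternmost box of each
  row is clipped to 10°; dropping instead of clipping is a flag.
* **FZ** — per ocean basin (WCPO/EPO, split at 150°W by default), the
  90th percentile (linear interpolation) of the *positive* cell values
  is computed and cells **strictly above** it are selected. Strict
  inequality makes the degenerate all-equal grid select nothing, and the
  rule is recorded in output metadata. Density and deployment grids are
  thresholded separately and unioned.
* **TZ** — twelve named habitat zones shipped as an editable YAML
  config whose coordinates are approximate reconstructions of published
  habitat maps (the sources print names and a map, not vertices); any
  user-supplied zone set is accepted. Rectangles use inclusive
  west/south, exclusive east/north edges; polygons use the even–odd
  interior rule, unwrapped zone-locally so antimeridian-spanning
  geometry works. Areas are computed in steradians via the shoelace
  formula over (longitude, sin latitude), an equal-area mapping.

## Arrival detection and statistics

Arrivals are detected on the weekly snapshots: the first archived week a
particle sits inside a TZ. Sub-weekly transits through a small zone can
be missed; this mirrors the weekly archiving cadence of the experiment
design and is the documented trade-off of snapshot semantics.
Connectivity horizons are cumulative (within 3 / 12 / 24 months,
converted to weeks with the same flooring as the archive length), which
makes ties between successive horizons natural. Per origin, the "other"
share is 100 minus the percentage that reached at least one TZ by the
final horizon; because first-arrival records are kept per (particle,
TZ), per-TZ percentages may legitimately sum above the arrived-in-≥1
share.

Density maps bin archived positions per drift window — short [0, 3),
moderate [3, 12), long [12, 24] months, the last closed so week 104 is
counted — and normalize by the total binned count after pooling, so a
map is a spatial probability distribution (cells sum to 1) and panels
from different windows are comparable.

## Synthetic forcing

The generators are pure functions of (parameters, grid, seed):

* **uniform** — RK4 is exact on a constant field; used for exactness
  tests (0.1 m/s × 6 h = 2160 m) and the constructed westward-channel
  transfer test.
* **solid rotation** — rigid rotation in the local equirectangular plane
  scaled by cos(centre latitude). The ground zonal velocity carries a
  cos(lat)/cos(lat_c) factor so trajectories are *exact* circles of
  period 2π/ω in that plane, making orbit closure a closed-form oracle
  rather than an approximation.
* **double gyre** — the standard time-periodic benchmark
  ψ = A sin(πf(x,t)) sin(πy) with f = ε sin(ωt)x² + (1−2ε sin(ωt))x on
  the plane rectangle [0,2]×[0,1] mapped onto the grid (ψ vanishes on
  the boundary, so the normal velocity is zero and the flow is
  divergence-free). The convergence benchmark integrates three tracers
  for 20 days (A = 1 m/s, ε = 0.3, 5-day period) on a 0.05° grid against
  a 2-minute-step reference; the fine grid matters because bilinear
  interpolation has derivative kinks at cell edges that would otherwise
  floor the error below RK4's truncation term. Observed order ≈ 3.8.
* **equatorial system** — Gaussian-in-latitude zonal jets (SEC westward
  at 0.40 m/s around 3°S, NECC eastward at 0.30 m/s around 7°N, NEC
  westward at 0.20 m/s around 15°N — rounded climatological magnitudes)
  blended with two anticyclonic subtropical gyres from Gaussian
  stream-function blobs, an idealized western archipelago arc
  (Indonesia–PNG–Solomons line) and an eastern continental wall. It is
  deliberately qualitative: it reproduces the *directions* of the
  tropical Pacific drift story (westward equatorial transport, gyre
  entrainment, western stranding), not eddies, ENSO phases or the real
  coastline. No test asserts a specific connectivity percentage on it —
  published percentages are tied to eddy-resolving reanalysis forcing
  and are not reproducible from synthetic fields.
* **density grid** — baseline plus Gaussian hotspots with optional
  seeded log-normal noise on a 1° lattice with WCPO/EPO basin labels.

What passing tests therefore show: the *machinery* (seeding arithmetic,
integrator order, arrival accounting, percentile selection,
normalization, pooling, determinism) is correct, and the pipeline's
qualitative behaviour on an idealized Pacific is directionally right.
What they do not show: quantitative agreement with drift statistics
under real ocean forcing.

## Problem sizes and defaults

The full experiment design (16 zones × ~6000 particles × 52 releases ×
24 months × 3 forcings ≈ 8 million particles) is what the schedule
defaults encode. The package's canned demonstration
(`fadrift.experiments.idealized_demo`) runs a structurally complete
scaled version — 16 zones × 200 particles × 4 releases × 12 months
(12,800 particles) — chosen as the size at which the whole pipeline
completes in about half a minute on one CPU while still exercising
seeding, advection, beaching, exit, arrivals, connectivity and density
stages; the full size is a matter of the same code and more hours.

## Numerical details and edge cases

* Months→weeks conversion: `floor(months × 30.4375 / 7)` everywhere
  (archive length and horizon binning use the identical rule).
* Nearest-node semantics define the "containing cell" for the land
  check; the bilinear stencil itself is never masked.
* Fields are validated on construction: strictly increasing axes, finite
  ocean velocities, mask/grid shape agreement; land velocities are
  stored as zero.
* NetCDF I/O uses xarray's scipy backend (NetCDF3 classic) with CF-style
  units attributes; time is float days since a per-file epoch, parsed
  without CF calendar decoding.
* Connectivity CSVs pin float formatting (`%.6f`) so identical
  config+seed gives byte-identical outputs.
* Degenerate inputs: all-equal density grids select no FZ cells; empty
  basins warn and select nothing; all-land zones seed zero particles
  with a warning; empty density windows return a flagged empty map.

## Known limitations

* Weekly-snapshot arrival detection misses sub-weekly transits through
  small zones.
* The beaching rule is an artifact-level construction; stranding
  *rates* on real coastlines should not be read off it.
* Uniform-in-degrees seeding slightly oversamples poleward cell area;
  within the 10°S–10°N release band the cos(latitude) distortion is
  ≤ 1.5%.
* The shipped turtle-zone coordinates are approximate reconstructions
  intended as a working default, not habitat authority.
* No diffusion/windage means simulated spread is narrower than that of
  real drifting objects; connectivity on real forcing should be treated
  as a lower-variance estimate of the advective pathway.
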