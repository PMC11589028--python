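"""Experiment configuration: one YAML file binding forcing, zones,
schedule and integration settings to a scenario.

Scenario vocabulary:

* ``"1"``  — release from the 16 equatorial boxes (EZ).
* ``"2a"`` — release from high-deployment 1° cells (FZ, deployment grid).
* ``"2b"`` — release from high-density 1° cells (FZ, density grid).

A single global ``seed`` fans out to per-release RNG streams via the
``(seed, release_index)`` counter scheme in :mod:`fadrift.advection`, so
partial reruns reproduce exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .advection import ConfigurationError, IntegrationSettings, ReleaseSchedule
from .fields import FieldSlab, depth_average, read_velocity
from .synth import FlowSpec, make_flow
from .zones import DensityGrid, Zone, load_turtle_zones, make_equatorial_zones, \
    select_fz_cells

__all__ = ["ExperimentConfig"]

_SCENARIOS = ("1", "2a", "2b")


@dataclass
class ExperimentConfig:
    scenario: str = "1"
    forcing: dict = field(default_factory=dict)     # {"path": ...} or {"flow": FlowSpec fields}
    zones: dict = field(default_factory=dict)       # ez params / density_grid / turtle_config
    schedule: dict = field(default_factory=dict)
    settings: dict = field(default_factory=dict)
    output_dir: str = "out"
    seed: int = 0
    depth_average_m: float = 50.0

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        cfg.scenario = str(cfg.scenario)
        return cfg

    # -- validation (dry-run mode) --------------------------------------
    def validate(self) -> list[str]:
        """Check referenced files and invariants; returns human-readable
        notes (raises on hard errors)."""
        notes = []
        if self.scenario not in _SCENARIOS:
            raise ConfigurationError(
                f"scenario must be one of {_SCENARIOS}, got {self.scenario!r}")
        if "path" in self.forcing:
            if not Path(self.forcing["path"]).exists():
                raise ConfigurationError(
                    f"forcing file not found: {self.forcing['path']}")
            notes.append(f"forcing from file {self.forcing['path']}")
        elif "flow" in self.forcing:
            notes.append(f"synthetic forcing: {self.forcing['flow'].get('kind')}")
        else:
            raise ConfigurationError("forcing requires 'path' or 'flow'")
        if self.scenario.startswith("2"):
            dg = self.zones.get("density_grid")
            if not dg:
                raise ConfigurationError(
                    "scenario 2 requires zones.density_grid (CSV path)")
            if not Path(dg).exists():
                raise ConfigurationError(f"density grid not found: {dg}")
        tz = self.zones.get("turtle_config")
        if tz and not Path(tz).exists():
            raise ConfigurationError(f"turtle-zone config not found: {tz}")
        self.make_schedule()
        self.make_settings()
        return notes

    # -- resolution into pipeline objects -------------------------------
    def make_slab(self) -> FieldSlab:
        if "path" in self.forcing:
            fld = read_velocity(self.forcing["path"])
            return depth_average(fld, z_max=self.depth_average_m)
        spec = FlowSpec(seed=self.seed, **self.forcing["flow"])
        return make_flow(spec)

    def make_release_zones(self, slab: FieldSlab | None = None) -> list[Zone]:
        if self.scenario == "1":
            return make_equatorial_zones(**self.zones.get("ez", {}))
        grid = DensityGrid.from_csv(self.zones["density_grid"])
        tag = "depl" if self.scenario == "2a" else "dens"
        return select_fz_cells(grid, percentile=self.zones.get("percentile", 90.0),
                               tag=tag)

    def make_turtle_zones(self) -> list[Zone]:
        return load_turtle_zones(self.zones.get("turtle_config"))

    def make_schedule(self) -> ReleaseSchedule:
        kw = dict(self.schedule)
        kw.setdefault("seed", self.seed)
        if "per_zone_count" in kw:
            kw.setdefault("per_cell_density", None)
        return ReleaseSchedule(**kw)

    def make_settings(self) -> IntegrationSettings:
        return IntegrationSettings(**self.settings)

    def resolved(self) -> dict:
        """The fully resolved configuration, for the run manifest."""
        return {
            "scenario": self.scenario, "seed": self.seed,
            "forcing": self.forcing, "zones": self.zones,
            "schedule": self.make_schedule().to_dict(),
            "settings": self.make_settings().to_dict(),
            "depth_average_m": self.depth_average_m,
            "output_dir": self.output_dir,
        }
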