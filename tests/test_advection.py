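"""Particle seeding and RK4 advection: exactness on constant fields,
analytic orbits, beaching/exit bookkeeping and reproducibility."""

import numpy as np
import pytest

from fadrift.advection import (
    BEACHED, DRIFTING, EXITED, ConfigurationError, IntegrationSettings,
    ReleaseSchedule, TrajectorySet, advect, rk4_step, run_experiment,
    run_schedule, seed_release,
)
from fadrift.fields import FieldSlab
from fadrift.geo import METERS_PER_DEGREE
from fadrift.synth import Grid, make_double_gyre
from fadrift.zones import Zone


def _zone(rect, zid="A"):
    return Zone(id=zid, kind="EZ", rect=rect)


class TestSeeding:
    def _schedule(self, **kw):
        kw.setdefault("per_cell_density", 30)
        kw.setdefault("seed", 3)
        return ReleaseSchedule(n_releases=1, **kw)

    def test_ocean_box_at_30_per_cell_gives_6000(self, make_slab):
        # a fully oceanic 20°×10° zone at 30 particles per 1° cell
        slab = make_slab(lon_bounds=(178, 222), lat_bounds=(-12, 12))
        lon, lat, origin = seed_release([_zone((180, -10, 200, 0))], slab,
                                        self._schedule(), 0)
        assert lon.size == 6000
        assert np.all(origin == "A")
        assert np.all((lon >= 180) & (lon < 200) & (lat >= -10) & (lat < 0))

    def test_per_zone_count_exact(self, make_slab):
        slab = make_slab(lon_bounds=(178, 222), lat_bounds=(-12, 12))
        sched = self._schedule(per_cell_density=None, per_zone_count=137)
        lon, lat, _ = seed_release([_zone((180, -10, 200, 0))], slab, sched, 0)
        assert lon.size == 137

    def test_all_land_zone_seeds_nothing_with_warning(self, small_grid):
        mask = np.ones((small_grid.lat.size, small_grid.lon.size), dtype=bool)
        slab = FieldSlab(lon=small_grid.lon, lat=small_grid.lat,
                         time=small_grid.time,
                         u=np.zeros((2, small_grid.lat.size, small_grid.lon.size)),
                         v=np.zeros((2, small_grid.lat.size, small_grid.lon.size)),
                         land_mask=mask)
        with pytest.warns(UserWarning, match="no ocean"):
            lon, _, _ = seed_release([_zone((185, -5, 195, 5))], slab,
                                     self._schedule(), 0)
        assert lon.size == 0

    def test_land_cells_excluded(self, small_grid):
        mask = np.zeros((small_grid.lat.size, small_grid.lon.size), dtype=bool)
        mask[:, small_grid.lon < 190.0] = True  # western half land
        slab = FieldSlab(lon=small_grid.lon, lat=small_grid.lat,
                         time=small_grid.time,
                         u=np.zeros((2, small_grid.lat.size, small_grid.lon.size)),
                         v=np.zeros((2, small_grid.lat.size, small_grid.lon.size)),
                         land_mask=mask)
        lon, _, _ = seed_release([_zone((182, -5, 198, 5))], slab,
                                 self._schedule(), 0)
        assert lon.size > 0 and np.all(lon >= 190.0)

    def test_same_seed_and_release_reproduces_exactly(self, uniform_slab):
        z = [_zone((182, -8, 198, 8))]
        a = seed_release(z, uniform_slab, self._schedule(), 4)
        b = seed_release(z, uniform_slab, self._schedule(), 4)
        c = seed_release(z, uniform_slab, self._schedule(), 5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
        assert not np.array_equal(a[0], c[0])


class TestRK4:
    def test_constant_field_displacement_exact(self, uniform_slab):
        lon, lat, ok = rk4_step(uniform_slab, np.array([190.0]),
                                np.array([0.0]), 0.0, 6.0)
        # 0.1 m/s for 21600 s = 2160 m eastward, exact for RK4
        assert (lon[0] - 190.0) * METERS_PER_DEGREE == pytest.approx(2160.0, abs=1e-6)
        assert lat[0] == 0.0 and ok[0]

    def test_constant_field_at_latitude_ground_speed_preserved(self, make_slab):
        slab = make_slab(u0=0.1, lat_bounds=(30, 50))
        lon, lat, _ = rk4_step(slab, np.array([190.0]), np.array([40.0]), 0.0, 6.0)
        ground = (lon[0] - 190.0) * METERS_PER_DEGREE * np.cos(np.deg2rad(40.0))
        assert ground == pytest.approx(2160.0, rel=1e-12)

    def test_zero_flow_is_identity(self, make_slab):
        slab = make_slab(u0=0.0, v0=0.0)
        lon, lat, _ = rk4_step(slab, np.array([190.0]), np.array([3.0]), 0.0, 6.0)
        assert lon[0] == 190.0 and lat[0] == 3.0

    def test_out_of_forcing_time_raises(self, uniform_slab):
        from fadrift.fields import OutOfDomainError
        with pytest.raises(OutOfDomainError):
            rk4_step(uniform_slab, np.array([190.0]), np.array([0.0]), 99.9, 6.0)

    def test_spatial_exit_flagged_not_raised(self, uniform_slab):
        _, _, ok = rk4_step(uniform_slab, np.array([199.99]), np.array([0.0]),
                            0.0, 24.0)
        assert not ok[0]


class TestSettings:
    def test_dt_must_divide_archive_interval(self):
        with pytest.raises(ConfigurationError, match="divide"):
            IntegrationSettings(dt_hours=5.0)

    def test_months_to_weeks_default_archive_count(self):
        assert ReleaseSchedule(per_cell_density=30).track_weeks == 104
        assert ReleaseSchedule(per_cell_density=30, track_months=12).track_weeks == 52


class TestAdvect:
    def _settings(self, **kw):
        kw.setdefault("domain_bounds", (120.0, 270.0, -30.0, 50.0))
        return IntegrationSettings(**kw)

    def test_count_conserved_and_archive_length(self, make_slab):
        slab = make_slab(u0=0.05, time_days=(0.0, 400.0))
        rng = np.random.default_rng(0)
        lon0 = rng.uniform(185, 195, 40)
        lat0 = rng.uniform(-5, 5, 40)
        ts = advect(lon0, lat0, "A", 0.0, slab, self._settings(), track_weeks=10)
        assert ts.n_particles == 40
        assert ts.n_archives == 11
        assert set(np.unique(ts.status)) <= {DRIFTING, BEACHED, EXITED}

    def test_archive_timestamps_weekly(self, make_slab):
        slab = make_slab(time_days=(0.0, 400.0))
        ts = advect([190.0], [0.0], "A", 0.0, slab, self._settings(),
                    track_weeks=8)
        np.testing.assert_array_equal(ts.archive_offsets_days(),
                                      7.0 * np.arange(9))

    def test_coastal_dead_zone_beaches_and_freezes(self, small_grid):
        # zero flow next to land: the stall rule must fire after
        # beach_weeks consecutive slow archives, then freeze the position
        ny, nx = small_grid.lat.size, small_grid.lon.size
        mask = np.zeros((ny, nx), dtype=bool)
        mask[:, -3:] = True
        slab = FieldSlab(lon=small_grid.lon, lat=small_grid.lat,
                         time=np.array([0.0, 400.0]),
                         u=np.zeros((2, ny, nx)), v=np.zeros((2, ny, nx)),
                         land_mask=mask)
        start_lon = small_grid.lon[-4]  # ocean, adjacent to land
        ts = advect([start_lon], [0.0], "A", 0.0, slab,
                    self._settings(beach_weeks=4), track_weeks=10)
        assert ts.status[0, 4] == BEACHED
        assert np.all(ts.status[0, 4:] == BEACHED)
        assert np.all(ts.lon[0, 4:] == ts.lon[0, 4])
        # and not before the threshold
        assert np.all(ts.status[0, :4] == DRIFTING)

    def test_domain_exit_freezes_at_crossing(self, make_slab):
        slab = make_slab(u0=0.5, lon_bounds=(150, 250), time_days=(0.0, 400.0))
        settings = self._settings(domain_bounds=(150.0, 200.0, -30.0, 50.0))
        ts = advect([198.0], [0.0], "A", 0.0, slab, settings, track_weeks=10)
        assert ts.status[0, -1] == EXITED
        week_exit = int(np.argmax(ts.status[0] == EXITED))
        assert np.all(ts.lon[0, week_exit:] == ts.lon[0, week_exit])
        assert ts.lon[0, week_exit] <= 200.5

    def test_no_beaching_in_divergence_free_flow_without_land(self):
        grid = Grid.regular(lon_bounds=(180, 200), lat_bounds=(-5, 5),
                            resolution=0.25, time_days=(0.0, 400.0))
        slab = make_double_gyre(A=0.5, epsilon=0.0, omega=1.0, grid=grid)
        rng = np.random.default_rng(1)
        ts = advect(rng.uniform(182, 198, 30), rng.uniform(-4, 4, 30), "A",
                    0.0, slab, self._settings(), track_weeks=12)
        assert not np.any(ts.status == BEACHED)

    def test_forcing_shortfall_detected_before_integration(self, make_slab):
        slab = make_slab(time_days=(0.0, 30.0))
        with pytest.raises(ConfigurationError, match="forcing"):
            advect([190.0], [0.0], "A", 0.0, slab, self._settings(),
                   track_weeks=10)

    def test_trajectory_matches_fine_step_reference(self):
        # 30-day double-gyre trajectories at the production step (6 h)
        # stay within 0.01° of a 2-minute reference integration
        grid = Grid.regular(lon_bounds=(180, 200), lat_bounds=(-5, 5),
                            resolution=0.1, time_days=(0.0, 60.0))
        slab = make_double_gyre(A=0.5, epsilon=0.25, omega=2 * np.pi / 10.0,
                                grid=grid)

        def integrate(dt_h):
            lon = np.array([186.0, 194.0])
            lat = np.array([-2.0, 2.0])
            t = 0.0
            for _ in range(int(round(30 * 24 / dt_h))):
                lon, lat, _ = rk4_step(slab, lon, lat, t, dt_h)
                t += dt_h / 24.0
            return lon, lat

        ref_lon, ref_lat = integrate(2.0 / 60.0)
        lon, lat = integrate(6.0)
        assert np.max(np.hypot(lon - ref_lon, lat - ref_lat)) < 0.01


class TestRunExperiment:
    def _setup(self, make_slab):
        slab = make_slab(u0=0.05, time_days=(0.0, 400.0))
        zones = [_zone((182, -8, 198, 8))]
        sched = ReleaseSchedule(start_date=0.0, n_releases=2,
                                per_zone_count=25, per_cell_density=None,
                                track_months=2, seed=9)
        return slab, zones, sched

    def test_identical_forcings_identical_trajectories(self, make_slab):
        slab, zones, sched = self._setup(make_slab)
        settings = IntegrationSettings(domain_bounds=(120, 270, -30, 50))
        runs = run_experiment([slab, slab, slab], zones, sched, settings)
        assert len(runs) == 3
        np.testing.assert_array_equal(runs[0].lon, runs[1].lon)
        np.testing.assert_array_equal(runs[1].lat, runs[2].lat)
        np.testing.assert_array_equal(runs[0].status, runs[2].status)

    def test_single_forcing_gives_list_of_one(self, make_slab):
        slab, zones, sched = self._setup(make_slab)
        runs = run_experiment([slab], zones, sched)
        assert len(runs) == 1 and runs[0].n_particles == 50  # 25 × 2 releases

    def test_netcdf_round_trip(self, make_slab, tmp_path):
        slab, zones, sched = self._setup(make_slab)
        ts = run_schedule(zones, slab, sched)
        back = TrajectorySet.from_netcdf(ts.to_netcdf(tmp_path / "t.nc"))
        np.testing.assert_allclose(back.lon, ts.lon)
        np.testing.assert_array_equal(back.status, ts.status)
        np.testing.assert_array_equal(back.origin_zone, ts.origin_zone)
        assert back.meta["archive_interval_days"] == 7.0
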