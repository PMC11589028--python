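"""Arrival detection, connectivity matrices, density maps and pooling."""

import numpy as np
import pandas as pd
import pytest

from fadrift.advection import BEACHED, EXITED, TrajectorySet
from fadrift.connectivity import (
    ConnectivityMatrix, connectivity, density_map, detect_arrivals,
    drift_windows, pool_runs, released_counts, write_outputs,
)
from fadrift.geo import months_to_weeks
from fadrift.zones import Zone


def _trajset(lon, lat, status=None, origins=None, seed_meta=True):
    lon = np.asarray(lon, dtype=float)
    P, W1 = lon.shape
    lat = np.asarray(lat, dtype=float)
    status = np.zeros((P, W1), dtype=np.int8) if status is None else \
        np.asarray(status, dtype=np.int8)
    origins = np.asarray(origins if origins is not None else ["A"] * P,
                         dtype=object)
    return TrajectorySet(
        lon=lon, lat=lat, status=status, origin_zone=origins,
        release_time=np.zeros(P), particle_id=np.arange(P),
        meta={"archive_interval_days": 7.0,
              **({"schedule": {"s": 1}} if seed_meta else {})},
    )


def _stationary(points, weeks=10, **kw):
    """One particle per (lon, lat), sitting still for all archives."""
    pts = np.asarray(points, dtype=float)
    lon = np.repeat(pts[:, :1], weeks + 1, axis=1)
    lat = np.repeat(pts[:, 1:], weeks + 1, axis=1)
    return _trajset(lon, lat, **kw)


TZ_A = Zone(id="ZA", kind="TZ", rect=(200, 0, 210, 10))
TZ_B = Zone(id="ZB", kind="TZ", rect=(220, 0, 230, 10))


class TestDetectArrivals:
    def test_first_arrival_is_min_week(self):
        # particle enters ZA at week 5 and stays through week 9
        lon = np.full((1, 11), 150.0)
        lon[0, 5:10] = 205.0
        lat = np.full((1, 11), 5.0)
        rec = detect_arrivals(_trajset(lon, lat), [TZ_A])
        assert len(rec) == 1
        assert rec.iloc[0]["first_arrival_week"] == 5

    def test_never_in_zone_no_records(self):
        rec = detect_arrivals(_stationary([[150.0, 5.0]]), [TZ_A, TZ_B])
        assert len(rec) == 0

    def test_crossing_two_zones_one_record_each(self):
        lon = np.full((1, 11), 150.0)
        lon[0, 3] = 205.0
        lon[0, 7] = 225.0
        lat = np.full((1, 11), 5.0)
        rec = detect_arrivals(_trajset(lon, lat), [TZ_A, TZ_B])
        got = rec.set_index("tz_id")["first_arrival_week"].to_dict()
        assert got == {"ZA": 3, "ZB": 7}

    def test_beached_inside_zone_counts(self):
        lon = np.full((1, 11), 205.0)
        lat = np.full((1, 11), 5.0)
        status = np.full((1, 11), BEACHED, dtype=np.int8)
        rec = detect_arrivals(_trajset(lon, lat, status=status), [TZ_A])
        assert rec.iloc[0]["first_arrival_week"] == 0

    def test_exited_stops_accruing(self):
        lon = np.full((1, 11), 205.0)
        lat = np.full((1, 11), 5.0)
        status = np.zeros((1, 11), dtype=np.int8)
        status[0, :] = EXITED  # exited from the start: frozen at a TZ position
        rec = detect_arrivals(_trajset(lon, lat, status=status), [TZ_A])
        assert len(rec) == 0

    def test_duplicate_tz_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            detect_arrivals(_stationary([[150.0, 5.0]]), [TZ_A, TZ_A])


class TestConnectivity:
    def test_total_transfer_100_at_all_horizons(self):
        rec = pd.DataFrame({"particle_id": range(10),
                            "origin_zone": "A", "tz_id": "ZA",
                            "first_arrival_week": 2})
        m = connectivity(rec, pd.Series({"A": 10}))
        for h in (3.0, 12.0, 24.0):
            assert m.entry("A", "ZA", h) == 100.0
        assert m.other["A"] == 0.0

    def test_week_20_arrival_bins_after_3_months(self):
        # week 20 ≈ 4.6 months: zero at the 3-month horizon, equal
        # nonzero value at 12 and 24 months
        rec = pd.DataFrame({"particle_id": range(4),
                            "origin_zone": "A", "tz_id": "ZA",
                            "first_arrival_week": 20})
        m = connectivity(rec, pd.Series({"A": 8}))
        assert m.entry("A", "ZA", 3.0) == 0.0
        assert m.entry("A", "ZA", 12.0) == 50.0
        assert m.entry("A", "ZA", 24.0) == 50.0

    @staticmethod
    def _brute_force(rec, released, horizons, tz_ids):
        """Independent per-particle recount."""
        out = {}
        for o in released.index:
            for z in tz_ids:
                for h in horizons:
                    wmax = months_to_weeks(h)
                    n = 0
                    for _, r in rec.iterrows():
                        if (r["origin_zone"] == o and r["tz_id"] == z
                                and r["first_arrival_week"] <= wmax):
                            n += 1
                    out[(o, z, h)] = 100.0 * n / released[o]
        return out

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_recount_exactly(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(50, 1000))
        origins = [f"O{i}" for i in range(int(rng.integers(2, 5)))]
        tz_ids = [f"Z{i}" for i in range(int(rng.integers(1, 4)))]
        released = pd.Series({o: int(rng.integers(n, 2 * n)) for o in origins})
        pid = rng.integers(0, n, n)
        rec = pd.DataFrame({
            "particle_id": pid,
            "origin_zone": rng.choice(origins, n),
            "tz_id": rng.choice(tz_ids, n),
            "first_arrival_week": rng.integers(0, 105, n),
        }).drop_duplicates(subset=["particle_id", "tz_id"])
        horizons = (3.0, 12.0, 24.0)
        m = connectivity(rec, released, horizons=horizons, tz_ids=tz_ids)
        want = self._brute_force(rec, released, horizons, tz_ids)
        for (o, z, h), v in want.items():
            assert m.entry(o, z, h) == v
        assert m.is_monotone()

    def test_unknown_origin_rejected(self):
        rec = pd.DataFrame({"particle_id": [0], "origin_zone": ["X"],
                            "tz_id": ["ZA"], "first_arrival_week": [1]})
        with pytest.raises(ValueError, match="unknown origin"):
            connectivity(rec, pd.Series({"A": 5}))

    def test_other_accounts_for_unreached_particles(self):
        # 3 of 10 particles reach some TZ (one reaches two TZs)
        rec = pd.DataFrame({
            "particle_id": [0, 1, 2, 2],
            "origin_zone": "A",
            "tz_id": ["ZA", "ZA", "ZA", "ZB"],
            "first_arrival_week": [1, 2, 3, 4],
        })
        m = connectivity(rec, pd.Series({"A": 10}))
        assert m.other["A"] == 70.0
        # per-TZ sum may exceed arrived-in-≥1 share; the identity is
        # arrived-in-≥1 + other = 100
        assert (100.0 - m.other["A"]) + m.other["A"] == 100.0

    def test_csv_round_trip(self, tmp_path):
        rec = pd.DataFrame({"particle_id": [0, 1], "origin_zone": ["A", "B"],
                            "tz_id": "ZA", "first_arrival_week": [1, 60]})
        m = connectivity(rec, pd.Series({"A": 4, "B": 5}))
        back = ConnectivityMatrix.from_csv(m.to_csv(tmp_path / "m.csv"))
        assert back.horizons == m.horizons
        pd.testing.assert_frame_equal(back.table, m.table, check_names=False)
        assert back.released.tolist() == m.released.tolist()


class TestDensityMap:
    def test_single_stationary_particle_point_mass(self):
        ts = _stationary([[205.3, 5.7]])
        dm = density_map(ts, window_months=(0.0, 3.0))
        assert dm.values.sum() == 1.0
        assert dm.values.max() == 1.0

    def test_two_particles_two_cells_half_each(self):
        ts = _stationary([[205.3, 5.7], [150.2, -8.1]])
        dm = density_map(ts, window_months=(0.0, 3.0))
        vals = np.sort(dm.values.ravel())[-2:]
        np.testing.assert_allclose(vals, [0.5, 0.5])

    def test_normalization_for_any_nonempty_run(self, rng):
        lon = rng.uniform(130, 260, (50, 20))
        lat = rng.uniform(-20, 40, (50, 20))
        dm = density_map(_trajset(lon, lat), window_months=(0.0, 3.0))
        assert dm.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_window_flagged_not_division_by_zero(self):
        ts = _stationary([[205.3, 5.7]], weeks=10)
        dm = density_map(ts, window_months=(12.0, 24.0))  # beyond archive
        assert dm.empty and dm.values.sum() == 0.0

    def test_windows_partition_archive_weeks(self):
        # short[0,3) + moderate[3,12) + long[12,24] cover weeks 0..104 once
        edges = [months_to_weeks(m) for m in (0, 3, 12, 24)]
        assert edges == [0, 13, 52, 104]
        covered = sum(e - s for s, e in zip(edges[:-1], edges[1:])) + 1
        assert covered == 105  # all weekly archives of a 24-month track

    def test_exited_positions_excluded(self):
        lon = np.full((1, 11), 205.0)
        lat = np.full((1, 11), 5.0)
        status = np.zeros((1, 11), dtype=np.int8)
        status[0, 5:] = EXITED
        dm = density_map(_trajset(lon, lat, status=status),
                         window_months=(0.0, 3.0))
        assert dm.n_positions == 5


class TestPooling:
    def test_pool_with_itself_leaves_connectivity_unchanged(self):
        lon = np.full((4, 11), 150.0)
        lon[:2, 6:] = 205.0
        lat = np.full((4, 11), 5.0)
        ts = _trajset(lon, lat)
        pooled = pool_runs([ts, ts])
        assert pooled.n_particles == 8
        assert len(np.unique(pooled.particle_id)) == 8
        m1 = connectivity(detect_arrivals(ts, [TZ_A]), released_counts(ts))
        m2 = connectivity(detect_arrivals(pooled, [TZ_A]),
                          released_counts(pooled))
        pd.testing.assert_frame_equal(m1.table, m2.table)

    def test_pooling_100_and_0_gives_50(self):
        lon_hit = np.full((5, 11), 205.0)
        lon_miss = np.full((5, 11), 150.0)
        lat = np.full((5, 11), 5.0)
        a = _trajset(lon_hit, lat)
        b = _trajset(lon_miss, lat)
        pooled = pool_runs([a, b])
        m = connectivity(detect_arrivals(pooled, [TZ_A]),
                         released_counts(pooled))
        assert m.entry("A", "ZA", 3.0) == 50.0

    def test_pooled_density_of_identical_runs_equals_single(self):
        ts = _stationary([[205.3, 5.7], [150.2, -8.1]])
        one = density_map(ts, window_months=(0.0, 3.0))
        two = density_map(pool_runs([ts, ts]), window_months=(0.0, 3.0))
        np.testing.assert_allclose(one.values, two.values)

    def test_mismatched_schedules_rejected(self):
        a = _stationary([[205.3, 5.7]])
        b = _stationary([[205.3, 5.7]])
        b.meta["schedule"] = {"s": 2}
        with pytest.raises(ValueError, match="schedule"):
            pool_runs([a, b])


class TestOutputs:
    def test_write_outputs_bundle(self, tmp_path):
        rec = pd.DataFrame({"particle_id": [0], "origin_zone": ["A"],
                            "tz_id": ["ZA"], "first_arrival_week": [1]})
        m = connectivity(rec, pd.Series({"A": 4}), tz_ids=["ZA", "ZB"])
        ts = _stationary([[205.3, 5.7]])
        maps = [density_map(ts, window_months=w) for w in drift_windows()[:1]]
        paths = write_outputs(m, maps, tmp_path / "out",
                              manifest={"seed": 42})
        # CSV column count: origin + released + |TZ|×|horizons| + other
        header = (tmp_path / "out" / "connectivity.csv").read_text() \
            .splitlines()[0].split(",")
        assert len(header) == 1 + 1 + 2 * 3 + 1
        import json
        man = json.loads((tmp_path / "out" / "manifest.json").read_text())
        assert man["seed"] == 42
        import xarray as xr
        with xr.open_dataset(paths["density_0-3mo"], engine="scipy") as ds:
            assert ds["density"].values.sum() == pytest.approx(1.0)

    def test_identical_runs_identical_csv_bytes(self, tmp_path):
        rec = pd.DataFrame({"particle_id": [0, 1], "origin_zone": ["A", "A"],
                            "tz_id": "ZA", "first_arrival_week": [1, 7]})
        m1 = connectivity(rec, pd.Series({"A": 3}))
        m2 = connectivity(rec.copy(), pd.Series({"A": 3}))
        p1 = m1.to_csv(tmp_path / "a.csv")
        p2 = m2.to_csv(tmp_path / "b.csv")
        assert p1.read_bytes() == p2.read_bytes()
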