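import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deweather import preprocessing as prep
from deweather.types import ScenarioPeriod

R_EARTH = prep.EARTH_RADIUS_KM


def lon_at_km(km: float) -> float:
    """Longitude (deg) east of 0 at the equator that is exactly `km` away."""
    return np.degrees(km / R_EARTH)


class TestFilterStations:
    @staticmethod
    def _obs_with_fractions(fractions, period):
        slots = period.timestamps()
        frames = []
        for i, frac in enumerate(fractions):
            n_miss = int(round(frac * len(slots)))
            pm = np.full(len(slots), 50.0)
            pm[:n_miss] = np.nan
            frames.append(
                pd.DataFrame(
                    {
                        "station_id": f"s{i}",
                        "lat": 30.0 + i * 0.01,
                        "lon": 114.0,
                        "timestamp": slots,
                        "pm25": pm,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def test_strict_threshold_boundary(self):
        # 25 days x 4 hours = 100 slots so the fractions are exact
        period = ScenarioPeriod("P", dt.date(2020, 1, 1), dt.date(2020, 1, 25))
        obs = self._obs_with_fractions([0.0, 0.1, 0.2, 0.21, 0.5], period)
        retained, report = prep.filter_stations(obs, [period], threshold=0.2)
        kept = set(report.loc[report["retained"], "station_id"])
        # dropped iff strictly over 20%: exactly 20% stays
        assert kept == {"s0", "s1", "s2"}
        assert report.set_index("station_id")["missing_fraction"]["s3"] == pytest.approx(0.21)

    def test_idempotent(self):
        period = ScenarioPeriod("P", dt.date(2020, 1, 1), dt.date(2020, 1, 25))
        obs = self._obs_with_fractions([0.0, 0.3], period)
        once, _ = prep.filter_stations(obs, [period], threshold=0.2)
        twice, _ = prep.filter_stations(once, [period], threshold=0.2)
        pd.testing.assert_frame_equal(
            once.sort_values(["station_id", "timestamp"]).reset_index(drop=True),
            twice.sort_values(["station_id", "timestamp"]).reset_index(drop=True),
        )

    def test_empty_period_set_is_an_error(self):
        period = ScenarioPeriod("P", dt.date(2020, 1, 1), dt.date(2020, 1, 2))
        obs = self._obs_with_fractions([0.0], period)
        with pytest.raises(ValueError):
            prep.filter_stations(obs, [], threshold=0.2)


class TestTemporalInterpolation:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([10.0, np.nan, 20.0], [10.0, 15.0, 20.0]),   # linear midpoint
            ([7.2, np.nan, 7.2], [7.2, 7.2, 7.2]),        # constant case
            ([np.nan, np.nan, 20.0], [np.nan, np.nan, 20.0]),  # missing neighbour
            ([10.0, np.nan, np.nan, 20.0], [10.0, np.nan, np.nan, 20.0]),
        ],
    )
    def test_midpoint_rule(self, values, expected):
        out = prep.interpolate_temporal(pd.Series(values))
        np.testing.assert_allclose(out.to_numpy(), expected)

    def test_interpolated_values_are_not_reused_as_neighbours(self):
        # position 2 must not be filled from the freshly filled position 1
        s = pd.Series([10.0, np.nan, np.nan, 20.0, 30.0])
        out = prep.interpolate_temporal(s)
        assert out.isna().tolist() == [False, True, True, False, False]

    def test_noop_on_fully_observed(self):
        s = pd.Series([1.0, 2.0, 3.0])
        pd.testing.assert_series_equal(prep.interpolate_temporal(s), s)


class TestSpatialInterpolation:
    def test_hand_computed_idw2(self):
        # donors at exactly 1 km and 2 km: (10*1 + 40*0.25) / 1.25 = 16.0
        val = prep.interpolate_spatial(
            0.0, 0.0,
            donor_lats=np.array([0.0, 0.0]),
            donor_lons=np.array([lon_at_km(1.0), lon_at_km(2.0)]),
            donor_values=np.array([10.0, 40.0]),
        )
        assert val == pytest.approx(16.0, abs=1e-9)

    def test_single_donor_collapses_weights(self):
        val = prep.interpolate_spatial(0.0, 0.0, [0.1], [0.1], [33.0])
        assert val == pytest.approx(33.0)

    def test_equidistant_donors_average(self):
        val = prep.interpolate_spatial(
            0.0, 0.0, [0.0, 0.0], [lon_at_km(5.0), -lon_at_km(5.0)], [10.0, 30.0]
        )
        assert val == pytest.approx(20.0)

    def test_coincident_donor_takes_all_weight(self):
        val = prep.interpolate_spatial(
            0.0, 0.0, [0.0, 0.5], [0.0, 0.5], [42.0, 999.0]
        )
        assert val == pytest.approx(42.0)

    def test_no_donors_is_an_error(self):
        with pytest.raises(ValueError, match="no co-temporal donor"):
            prep.interpolate_spatial(0.0, 0.0, [], [], [])

    @settings(derandomize=True, max_examples=50)
    @given(
        values=st.lists(st.floats(0, 500), min_size=1, max_size=8),
        data=st.data(),
    )
    def test_idw_bounded_by_donor_range(self, values, data):
        lats = data.draw(
            st.lists(
                st.floats(0.01, 1.0), min_size=len(values), max_size=len(values)
            )
        )
        val = prep.interpolate_spatial(0.0, 0.0, lats, lats, values)
        assert min(values) - 1e-9 <= val <= max(values) + 1e-9


class TestInterpolationCV:
    @staticmethod
    def _linear_constant_field(n_stations=5, n_days=5):
        """Noiseless field: spatially constant, linear in slot index, so both
        the temporal midpoint and the spatial IDW reconstructions are exact."""
        period = ScenarioPeriod("P", dt.date(2020, 1, 1), dt.date(2020, 1, n_days))
        slots = period.timestamps()
        vals = 30.0 + 2.0 * np.arange(len(slots))
        frames = [
            pd.DataFrame(
                {
                    "station_id": f"s{i}",
                    "lat": 30.0 + 0.05 * i,
                    "lon": 114.0 + 0.03 * i,
                    "timestamp": slots,
                    "pm25": vals,
                }
            )
            for i in range(n_stations)
        ]
        return pd.concat(frames, ignore_index=True), period

    def test_exact_reconstruction_gives_zero_mae(self):
        obs, period = self._linear_constant_field()
        report = prep.cross_validate_interpolation(obs, [period], k=10, seed=0)
        assert report.cv_mae == pytest.approx(0.0, abs=1e-9)
        assert report.n_folds == 10

    def test_two_fold_cv_matches_scalar_oracle(self):
        """Independently reconstruct every masked value with scalar loops."""
        period = ScenarioPeriod("P", dt.date(2020, 1, 1), dt.date(2020, 1, 3))
        slots = period.timestamps()
        rng = np.random.default_rng(3)
        stations = [("s0", 30.0, 114.0), ("s1", 30.2, 114.1), ("s2", 30.4, 114.3)]
        vals = rng.uniform(20, 80, size=(len(slots), len(stations)))
        obs = pd.concat(
            [
                pd.DataFrame(
                    {"station_id": sid, "lat": la, "lon": lo,
                     "timestamp": slots, "pm25": vals[:, j]}
                )
                for j, (sid, la, lo) in enumerate(stations)
            ],
            ignore_index=True,
        )
        k, seed = 2, 11
        report = prep.cross_validate_interpolation(obs, [period], k=k, seed=seed)

        # oracle: replay the fold assignment, then reconstruct scalar-wise
        order = np.random.default_rng(seed).permutation(vals.size)
        pairs = np.argwhere(np.ones_like(vals, dtype=bool))
        fold_maes = []
        for fold in range(k):
            masked = {tuple(p) for p in pairs[order[fold::k]]}
            errs = []
            for (t, j) in sorted(masked):
                prev_ok = t > 0 and (t - 1, j) not in masked
                next_ok = t < len(slots) - 1 and (t + 1, j) not in masked
                if prev_ok and next_ok:
                    rec = (vals[t - 1, j] + vals[t + 1, j]) / 2.0
                else:
                    num = den = 0.0
                    for jj, (_, la, lo) in enumerate(stations):
                        if jj == j or (t, jj) in masked:
                            continue
                        d = prep.haversine_km(
                            stations[j][1], stations[j][2], la, lo
                        )
                        num += vals[t, jj] / d**2
                        den += 1.0 / d**2
                    if den == 0.0:
                        continue  # unreconstructable: excluded from the MAE
                    rec = num / den
                errs.append(abs(rec - vals[t, j]))
            fold_maes.append(np.mean(errs))
        assert report.cv_mae == pytest.approx(np.mean(fold_maes), abs=1e-9)

    def test_same_seed_reproduces_report(self):
        obs, period = self._linear_constant_field()
        obs.loc[obs.sample(5, random_state=1).index, "pm25"] = np.nan
        r1 = prep.cross_validate_interpolation(obs, [period], k=3, seed=5)
        r2 = prep.cross_validate_interpolation(obs, [period], k=3, seed=5)
        assert r1.cv_fold_maes == r2.cv_fold_maes

    def test_k_exceeding_observed_count_rejected(self):
        obs, period = self._linear_constant_field(n_stations=1, n_days=1)
        with pytest.raises(ValueError, match="exceeds"):
            prep.cross_validate_interpolation(obs, [period], k=50, seed=0)


class TestStandardize:
    def test_known_values(self):
        z, params = prep.standardize([1.0, 2.0, 3.0])
        np.testing.assert_allclose(z, [-1.224744871, 0.0, 1.224744871], atol=1e-8)
        assert params.std[0] == pytest.approx(0.81649658, abs=1e-8)

    def test_value_at_mean_maps_to_zero(self):
        z, _ = prep.standardize([5.0, 10.0, 15.0])
        assert z[1] == 0.0

    def test_constant_input_rejected_naming_variable(self):
        X = pd.DataFrame({"u_wind": [1.0, 2.0], "msl": [5.0, 5.0]})
        with pytest.raises(ValueError, match="msl"):
            prep.Standardizer().fit(X)

    def test_stored_params_reproduce_training_transform_bitwise(self, rng):
        X = rng.normal(size=(40, 3))
        s = prep.Standardizer().fit(X)
        z1 = s.transform(X)
        z2 = s.params_.transform(X)
        assert np.array_equal(z1, z2)
        assert abs(z1.mean()) < 1e-9 and abs(z1.std(ddof=0) - 1.0) < 1e-9

    def test_inverse_round_trip(self, rng):
        X = rng.normal(10, 3, size=(20, 2))
        s = prep.Standardizer().fit(X)
        np.testing.assert_allclose(s.inverse_transform(s.transform(X)), X, atol=1e-12)


class TestMatchGrid:
    @staticmethod
    def _meteo(lats, lons, times):
        rows = [
            dict(timestamp=pd.Timestamp(t), lat=la, lon=lo, u_wind=1.0,
                 v_wind=2.0, msl=101800.0, d2m=271.0, t2m=276.0)
            for t in times for la in lats for lo in lons
        ]
        return pd.DataFrame(rows)

    @staticmethod
    def _obs(stations, times, values):
        frames = []
        for (sid, la, lo), v in zip(stations, values):
            frames.append(
                pd.DataFrame(
                    {"station_id": sid, "lat": la, "lon": lo,
                     "timestamp": pd.to_datetime(times), "pm25": v}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def test_cell_mean_and_empty_cells(self):
        times = ["2020-01-21 02:00"]
        meteo = self._meteo([30.0, 30.1], [114.0, 114.1], times)
        # two stations near (30, 114), none in the other three cells
        obs = self._obs(
            [("a", 30.01, 114.01), ("b", 29.99, 113.99)], times, [[50.0], [70.0]]
        )
        samples, grid, cell_of = prep.match_grid(obs, meteo, spacing=0.1)
        assert len(samples) == 1
        assert samples.loc[0, "pm25_mean"] == pytest.approx(60.0)
        assert samples.loc[0, "n_stations"] == 2
        assert cell_of.nunique() == 1

    def test_single_station_value_passes_through(self):
        times = ["2020-01-21 02:00"]
        meteo = self._meteo([30.0], [114.0], times)
        obs = self._obs([("a", 30.01, 114.01)], times, [[42.0]])
        samples, _, _ = prep.match_grid(obs, meteo, spacing=0.1)
        assert samples["pm25_mean"].tolist() == [42.0]

    def test_station_outside_bbox_listed(self):
        times = ["2020-01-21 02:00"]
        meteo = self._meteo([30.0, 30.1], [114.0, 114.1], times)
        obs = self._obs([("far", 45.0, 120.0)], times, [[10.0]])
        with pytest.raises(ValueError, match="far"):
            prep.match_grid(obs, meteo, spacing=0.1)

    def test_station_count_conserved(self, tiny_world):
        obs = tiny_world.observations
        samples, grid, cell_of = prep.match_grid(
            obs, tiny_world.meteo, spacing=tiny_world.config.spacing
        )
        assert len(cell_of) == obs["station_id"].nunique()
        per_cell = cell_of.value_counts()
        assert per_cell.sum() == len(cell_of)
        # every station was matched to its generating cell (jitter < spacing/2)
        expected = tiny_world.stations.set_index("station_id")["cell_id"]
        pd.testing.assert_series_equal(
            cell_of.sort_index(), expected.sort_index(), check_names=False
        )

    def test_off_hour_samples_excluded(self):
        times = ["2020-01-21 02:00", "2020-01-21 09:00"]
        meteo = self._meteo([30.0], [114.0], times)
        obs = self._obs([("a", 30.0, 114.0)], times, [[42.0, 43.0]])
        samples, _, _ = prep.match_grid(obs, meteo, spacing=0.1)
        assert samples["hour"].tolist() == [2]


class TestStratifyHours:
    @staticmethod
    def _samples(hours):
        return pd.DataFrame(
            {
                "cell_id": "g0-0",
                "region": "R",
                "landuse": "urban",
                "date": pd.Timestamp("2020-01-21"),
                "hour": hours,
                "pm25_mean": 50.0,
            }
        )

    def test_four_groups_partition_samples(self):
        samples = self._samples([2, 2, 8, 8, 14, 14, 20, 20])
        out = prep.stratify_hours(samples, "SD")
        assert sorted(out) == [2, 8, 14, 20]
        assert all(len(ds) == 2 for ds in out.values())
        assert sum(len(ds) for ds in out.values()) == len(samples)

    def test_unexpected_hour_rejected(self):
        with pytest.raises(ValueError, match="9"):
            prep.stratify_hours(self._samples([2, 9]), "SD")

    def test_empty_input_warns_and_returns_empty_datasets(self):
        with pytest.warns(UserWarning, match="no samples"):
            out = prep.stratify_hours(self._samples([]).iloc[:0], "SD")
        assert sorted(out) == [2, 8, 14, 20]
        assert all(len(ds) == 0 for ds in out.values())


class TestGridResampling:
    def test_nearest_source_cell_assignment(self):
        # 0.2-degree source resampled to 0.1: fine cells copy nearest coarse value
        times = ["2020-01-21 02:00"]
        rows = [
            dict(timestamp=pd.Timestamp(times[0]), lat=la, lon=lo,
                 u_wind=10.0 * i + j, v_wind=0.0, msl=101800.0, d2m=271.0, t2m=276.0)
            for i, la in enumerate([30.0, 30.2])
            for j, lo in enumerate([114.0, 114.2])
        ]
        grid, fine = prep.resample_meteo(pd.DataFrame(rows), spacing=0.1)
        assert grid.shape == (3, 3)
        got = fine.set_index(["lat", "lon"])["u_wind"]
        assert got[(30.0, 114.0)] == 0.0
        assert got[(30.2, 114.2)] == 11.0
        # mid-points round to an adjacent coarse cell, never interpolate
        assert got[(30.1, 114.1)] in {0.0, 1.0, 10.0, 11.0}
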