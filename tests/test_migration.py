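import numpy as np
import pandas as pd
import pytest

from arcticphen import migration as mig
from arcticphen import track_io as tio
from arcticphen.geo import haversine_km

from geodesic_oracle import vincenty_km


def daily_frame(rows, individual="b1", year=2020, device="GPS"):
    """Daily-position frame from (doy, lat, lon) tuples; lat may be None."""
    return pd.DataFrame(
        {
            "individual_id": individual,
            "year": year,
            "doy": [r[0] for r in rows],
            "lat": [r[1] for r in rows],
            "lon": [r[2] for r in rows],
            "device": device,
        }
    )


def winter_then(rows, lat=52.0, lon=5.0):
    """Prefix a Jan-Feb residency (doys 1-59) to the given spring rows."""
    base = [(d, lat, lon) for d in range(1, 60)]
    return daily_frame(base + rows)


class TestWinterCentroid:
    def test_constant_position(self):
        cen = mig.winter_centroid(winter_then([]))
        assert (cen.lat, cen.lon) == (52.0, 5.0)

    def test_median_of_symmetric_scatter(self):
        rows = [(d, 52.0 + s, 5.0 + s) for d, s in zip(range(1, 59), [0.1, -0.1] * 29)]
        cen = mig.winter_centroid(daily_frame(rows))
        assert cen.lat == pytest.approx(52.0, abs=1e-9)
        assert cen.lon == pytest.approx(5.0, abs=1e-9)

    def test_missing_winter_raises(self):
        with pytest.raises(mig.PhenologyError, match="Jan-Feb"):
            mig.winter_centroid(daily_frame([(100, 55.0, 5.0)] * 12))

    def test_close_to_generator_truth(self, small_scenario, small_tracks):
        tracks, truth, _ = small_tracks
        daily = tio.daily_average(tracks)
        row = truth.iloc[0]
        one = daily[
            (daily["individual_id"] == row["individual_id"]) & (daily["year"] == row["year"])
        ]
        cen = mig.winter_centroid(one)
        err_km = haversine_km(cen.lat, cen.lon, *small_scenario.winter_centroid)
        assert err_km < small_scenario.winter_jitter_km


class TestDepartureGps:
    def test_last_day_inside_radius(self):
        track = winter_then([(d, 52.0, 5.0) for d in range(60, 95)] + [(95, 58.0, 5.0)])
        cen = mig.winter_centroid(track)
        assert mig.departure_date_gps(track, cen) == 94

    def test_brief_excursion_postpones_departure(self):
        # out beyond 200 km on doy 80, back on 82, final leave after 90
        rows = (
            [(d, 52.0, 5.0) for d in range(60, 80)]
            + [(80, 55.0, 5.0), (81, 55.0, 5.0)]
            + [(d, 52.0, 5.0) for d in range(82, 91)]
            + [(d, 58.0, 5.0) for d in range(91, 100)]
        )
        track = winter_then(rows)
        cen = mig.winter_centroid(track)
        assert mig.departure_date_gps(track, cen) == 90

    def test_never_leaving_gives_none(self):
        track = winter_then([(d, 52.0, 5.0) for d in range(60, 180)])
        cen = mig.winter_centroid(track)
        assert mig.departure_date_gps(track, cen) is None


class TestDepartureGls:
    def test_sustained_movement_onset(self):
        rows = [(d, 52.0 + 1.8 * max(0, d - 99), 5.0) for d in range(60, 110)]
        track = winter_then(rows)
        cen = mig.winter_centroid(track)
        # ~200 km/day northward from doy 100 -> first day >= 300 km is 102
        dd = mig.departure_date_gls(track, cen)
        assert dd == pytest.approx(102, abs=1)

    def test_single_day_jump_is_not_departure(self):
        rows = [(d, 52.0, 5.0) for d in range(60, 100)]
        rows[20] = (80, 56.0, 5.0)  # 400 km spike, then back
        track = winter_then(rows)
        cen = mig.winter_centroid(track)
        assert mig.departure_date_gls(track, cen) is None


class TestArrival:
    def test_first_day_above_arctic_circle(self):
        track = daily_frame([(140, 65.9, 20.0), (141, 66.2, 20.0), (142, 66.5, 20.0)])
        assert mig.arrival_date_gps(track) == 142

    def test_stays_south_gives_none(self):
        track = daily_frame([(d, 64.0, 20.0) for d in range(130, 160)])
        assert mig.arrival_date_gps(track) is None

    def test_monotone_in_latitude_threshold(self, small_tracks):
        tracks, _, _ = small_tracks
        daily = tio.daily_average(tracks)
        for _, g in daily.groupby(["individual_id", "year"]):
            low = mig.arrival_date_gps(g, 66.33)
            high = mig.arrival_date_gps(g, 68.0)
            if high is not None:
                assert low is not None and low <= high

    def test_gls_first_day_after_last_dark_night(self):
        rec = pd.DataFrame({"doy": range(100, 160), "dark_night": [True] * 51 + [False] * 9})
        assert mig.arrival_date_gls(rec) == 151

    def test_gls_isolated_lit_night_ignored(self):
        dark = [True] * 51 + [False] * 9
        dark[20] = False  # one lit night on doy 120 does not end the record
        rec = pd.DataFrame({"doy": range(100, 160), "dark_night": dark})
        assert mig.arrival_date_gls(rec) == 151

    def test_gls_no_dark_nights_is_malformed(self):
        rec = pd.DataFrame({"doy": range(100, 160), "dark_night": False})
        with pytest.raises(mig.PhenologyError):
            mig.arrival_date_gls(rec)


class TestDistanceAndSpeed:
    def test_stationary_segment_is_zero(self):
        track = daily_frame([(d, 52.0, 5.0) for d in range(100, 110)])
        dist, _ = mig.migration_distance(track, 100, 109)
        assert dist == 0.0

    def test_one_degree_latitude_vs_geodesic_oracle(self):
        track = daily_frame([(100, 66.33, 20.0), (101, 67.33, 20.0)])
        dist, _ = mig.migration_distance(track, 100, 101)
        assert dist == pytest.approx(111.2, abs=0.2)
        assert dist == pytest.approx(vincenty_km(66.33, 20.0, 67.33, 20.0), rel=0.005)

    def test_path_length_matches_generator(self, small_tracks):
        tracks, truth, _ = small_tracks
        daily = tio.daily_average(tracks)
        phen = mig.extract_migration_phenology(daily, population="test_pop")
        m = phen.merge(truth, on=["individual_id", "year"], suffixes=("", "_true"))
        rel = (m["migration_km"] - m["migration_km_true"]).abs() / m["migration_km_true"]
        assert rel.max() < 0.01

    def test_triangle_inequality(self, small_tracks):
        tracks, truth, _ = small_tracks
        daily = tio.daily_average(tracks)
        phen = mig.extract_migration_phenology(daily, population="test_pop")
        for r in phen.itertuples(index=False):
            one = daily[
                (daily["individual_id"] == r.individual_id) & (daily["year"] == r.year)
            ]
            start = one[one["doy"] == int(r.departure_doy)].iloc[0]
            end = one[one["doy"] == int(r.arrival_doy)].iloc[0]
            leap = haversine_km(start["lat"], start["lon"], end["lat"], end["lon"])
            assert r.migration_km >= leap - 1e-6

    def test_arrival_before_departure_rejected(self):
        track = daily_frame([(100, 52.0, 5.0)])
        with pytest.raises(mig.PhenologyError):
            mig.migration_distance(track, 120, 100)

    @pytest.mark.parametrize(
        "md,dd,da,expected", [(3000.0, 100, 110, 300.0), (0.0, 100, 110, 0.0)]
    )
    def test_travel_speed(self, md, dd, da, expected):
        assert mig.travel_speed(md, dd, da) == expected

    def test_travel_speed_zero_duration_rejected(self):
        with pytest.raises(mig.PhenologyError):
            mig.travel_speed(1000.0, 100, 100)


class TestEventRecoveryOnCleanTracks:
    def test_gps_departure_arrival_exact(self, small_tracks):
        tracks, truth, _ = small_tracks
        daily = tio.daily_average(tio.filter_speed_outliers(tracks))
        phen = mig.extract_migration_phenology(daily, population="test_pop")
        m = phen.merge(truth, on=["individual_id", "year"], suffixes=("", "_true"))
        assert (m["departure_doy"] == m["departure_doy_true"]).all()
        assert (m["arrival_doy"] == m["arrival_doy_true"]).all()

    def test_timezone_representation_invariance(self, small_tracks):
        tracks, _, _ = small_tracks
        one = tracks[tracks["individual_id"] == tracks["individual_id"].iloc[0]].copy()
        shifted = one.copy()
        shifted["timestamp"] = pd.to_datetime(shifted["timestamp"], utc=True).dt.tz_convert(
            "Asia/Yekaterinburg"
        )
        d1 = tio.daily_average(one)
        d2 = tio.daily_average(shifted)
        p1 = mig.extract_migration_phenology(d1)
        p2 = mig.extract_migration_phenology(d2)
        pd.testing.assert_frame_equal(p1, p2)
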