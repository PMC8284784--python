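"""Great-circle geometry, daily midpoints, distance summaries, filtering."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kittitrack as kt
from kittitrack.trajectories import (
    EARTH_RADIUS_KM,
    CoordinateError,
    filter_complete,
    geographic_midpoint,
)

BULDIR = (52.35, 175.933)
ST_GEORGE = (56.6, -169.55)

latitudes = st.floats(-89.0, 89.0)
longitudes = st.floats(-180.0, 180.0)


class TestGreatCircle:
    def test_identity(self):
        assert kt.great_circle_km((10.0, 20.0), (10.0, 20.0)) == 0.0

    def test_quarter_great_circle(self):
        # (0,0) to (0,90E) spans a quarter of the equator
        expected = EARTH_RADIUS_KM * math.pi / 2.0
        assert kt.great_circle_km((0.0, 0.0), (0.0, 90.0)) == pytest.approx(expected, abs=1e-9)

    def test_colony_separation_exceeds_1000_km(self):
        # the two study colonies sit more than 1000 km apart
        assert kt.great_circle_km(BULDIR, ST_GEORGE) > 1000.0

    def test_invalid_latitude_rejected(self):
        with pytest.raises(CoordinateError):
            kt.great_circle_km((95.0, 0.0), (0.0, 0.0))

    @settings(derandomize=True, max_examples=100)
    @given(latitudes, longitudes, latitudes, longitudes)
    def test_symmetry(self, lat1, lon1, lat2, lon2):
        d12 = kt.great_circle_km((lat1, lon1), (lat2, lon2))
        d21 = kt.great_circle_km((lat2, lon2), (lat1, lon1))
        assert d12 == pytest.approx(d21, abs=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(latitudes, longitudes, latitudes, longitudes, latitudes, longitudes)
    def test_triangle_inequality(self, la1, lo1, la2, lo2, la3, lo3):
        d12 = kt.great_circle_km((la1, lo1), (la2, lo2))
        d23 = kt.great_circle_km((la2, lo2), (la3, lo3))
        d13 = kt.great_circle_km((la1, lo1), (la3, lo3))
        assert d13 <= d12 + d23 + 1e-6

    @settings(derandomize=True, max_examples=100)
    @given(latitudes, longitudes, latitudes, longitudes)
    def test_longitude_wrap_invariance(self, lat1, lon1, lat2, lon2):
        base = kt.great_circle_km((lat1, lon1), (lat2, lon2))
        wrapped = kt.great_circle_km((lat1, lon1 + 360.0), (lat2, lon2))
        assert base == pytest.approx(wrapped, abs=1e-6)


class TestDailyMidpoint:
    @staticmethod
    def _track(points, date=dt.date(2016, 10, 5)):
        rows = []
        for k, (lat, lon) in enumerate(points):
            t = dt.datetime.combine(date, dt.time(6 + 12 * k), tzinfo=dt.timezone.utc)
            rows.append(("b1", "A", t, lat, lon))
        return pd.DataFrame(rows, columns=["bird_id", "colony", "timestamp", "lat", "lon"])

    def test_identical_fixes(self):
        daily = kt.daily_midpoints(self._track([(50.0, 170.0), (50.0, 170.0)]))
        assert len(daily) == 1
        assert daily.iloc[0]["lat"] == pytest.approx(50.0)
        assert daily.iloc[0]["lon"] == pytest.approx(170.0)

    def test_equatorial_symmetry(self):
        daily = kt.daily_midpoints(self._track([(0.0, -10.0), (0.0, 10.0)]))
        assert daily.iloc[0]["lat"] == pytest.approx(0.0, abs=1e-9)
        assert daily.iloc[0]["lon"] == pytest.approx(0.0, abs=1e-9)

    def test_antimeridian_midpoint(self):
        # fixes straddling the dateline must give longitude 180, not 0
        daily = kt.daily_midpoints(self._track([(50.0, 179.0), (50.0, -179.0)]))
        assert abs(daily.iloc[0]["lon"]) == pytest.approx(180.0, abs=1e-9)

    def test_single_fix_stands(self):
        daily = kt.daily_midpoints(self._track([(42.0, 155.0)]))
        assert daily.iloc[0][["lat", "lon"]].tolist() == pytest.approx([42.0, 155.0])

    def test_one_row_per_bird_day(self, small_tracks):
        daily = kt.daily_midpoints(small_tracks[0])
        assert not daily.duplicated(subset=["bird_id", "date"]).any()

    def test_antipodal_midpoint_undefined(self):
        with pytest.raises(ValueError, match="antipodal"):
            geographic_midpoint([0.0, 0.0], [0.0, 180.0])


def _line_track(lons, lat=0.0):
    rows = [
        ("b1", "A", dt.datetime(2016, 10, 1, tzinfo=dt.timezone.utc) + dt.timedelta(hours=12 * k), lat, lon)
        for k, lon in enumerate(lons)
    ]
    return pd.DataFrame(rows, columns=["bird_id", "colony", "timestamp", "lat", "lon"])


class TestDistanceSummaries:
    def test_stationary_track_zero(self):
        assert kt.cumulative_distance(_line_track([10.0, 10.0, 10.0])) == 0.0

    def test_two_fixes_single_segment(self):
        track = _line_track([0.0, 5.0])
        expected = kt.great_circle_km((0.0, 0.0), (0.0, 5.0))
        assert kt.cumulative_distance(track) == pytest.approx(expected)

    def test_out_and_back(self):
        track = _line_track([0.0, 7.0, 0.0])
        expected = 2.0 * kt.great_circle_km((0.0, 0.0), (0.0, 7.0))
        assert kt.cumulative_distance(track) == pytest.approx(expected)

    def test_additive_over_window_split(self):
        track = _line_track([0.0, 3.0, 8.0, 4.0, 12.0])
        t = pd.to_datetime(track["timestamp"])
        split = t.iloc[2]
        total = kt.cumulative_distance(track)
        first = kt.cumulative_distance(track, (t.iloc[0], split))
        second = kt.cumulative_distance(track, (split, t.iloc[-1]))
        assert total == pytest.approx(first + second, abs=1e-9)

    def test_too_few_fixes_flagged(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            kt.cumulative_distance(_line_track([0.0]))

    def test_max_distance_all_at_colony(self):
        track = _line_track([170.0, 170.0], lat=52.0)
        assert kt.max_distance_from_colony(track, (52.0, 170.0)) == 0.0

    def test_max_distance_single_fix(self):
        track = _line_track([175.0], lat=52.0)
        expected = kt.great_circle_km((52.0, 175.0), (52.0, 170.0))
        assert kt.max_distance_from_colony(track, (52.0, 170.0)) == pytest.approx(expected)

    def test_max_bounded_by_cumulative_from_colony(self, small_tracks):
        # a path starting at the colony can never exceed its own length
        tracks, _ = small_tracks
        for colony, pos in (("buldir", BULDIR), ("st_george", ST_GEORGE)):
            sub = tracks[tracks["colony"] == colony]
            for _, grp in sub.groupby("bird_id"):
                assert kt.max_distance_from_colony(grp, pos) <= kt.cumulative_distance(grp) + 1e-6


class TestFilterComplete:
    WINDOW = (dt.date(2016, 10, 1), dt.date(2016, 10, 10))

    @staticmethod
    def _bird(bird, days, colony="A"):
        rows = []
        for day in days:
            t = dt.datetime(2016, 10, day, 6, tzinfo=dt.timezone.utc)
            rows.append((bird, colony, t, 50.0, 170.0))
        return pd.DataFrame(rows, columns=["bird_id", "colony", "timestamp", "lat", "lon"])

    def test_fully_covered_bird_retained(self):
        df = self._bird("b1", range(1, 11))
        assert filter_complete(df, self.WINDOW) == ["b1"]

    def test_missing_days_excluded_strict(self):
        df = pd.concat([self._bird("b1", range(1, 11)), self._bird("b2", range(1, 9))])
        assert filter_complete(df, self.WINDOW) == ["b1"]

    def test_tolerance_threshold(self):
        df = self._bird("b1", range(1, 10))  # 9 of 10 days
        assert filter_complete(df, self.WINDOW, tolerance=0.9) == ["b1"]
        assert filter_complete(df, self.WINDOW, tolerance=0.95) == []

    def test_immersion_mode_counts_blocks(self):
        start = dt.datetime(2016, 10, 1, tzinfo=dt.timezone.utc)
        n_expected = 10 * 288
        times = [start + dt.timedelta(minutes=5 * i) for i in range(n_expected)]
        df = pd.DataFrame({"bird_id": "b1", "block_start": times, "wet_count": 0, "n_samples": 50})
        assert filter_complete(df, self.WINDOW, mode="immersion") == ["b1"]
        # drop 6% of the blocks: fails strict and 0.95, passes 0.90
        df_gappy = df.iloc[: int(n_expected * 0.94)]
        assert filter_complete(df_gappy, self.WINDOW, mode="immersion") == []
        assert filter_complete(df_gappy, self.WINDOW, mode="immersion", tolerance=0.9) == ["b1"]


class TestSummaries:
    def test_summarize_trajectories_columns(self, small_tracks):
        tracks, _ = small_tracks
        window = (dt.date(2016, 9, 1), dt.date(2017, 4, 30))
        positions = {"buldir": BULDIR, "st_george": ST_GEORGE}
        table = kt.summarize_trajectories(tracks, positions, window)
        assert len(table) == tracks["bird_id"].nunique()
        assert (table["cumulative_km"] > 0).all()
        assert (table["max_colony_km"] > 0).all()
        assert (table["max_colony_km"] <= table["cumulative_km"]).all()
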