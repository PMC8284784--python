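import datetime as dt

import numpy as np
import pandas as pd
import pytest

import kittitrack as kt


@pytest.fixture(scope="session")
def schedules():
    return kt.default_schedules(2016)


@pytest.fixture(scope="session")
def small_tracks(schedules):
    """Four birds per colony, full season, moderate geolocation-like noise."""
    cfg = kt.MovementConfig(n_birds=4, fixes_per_day=2, noise_sd_km=100.0, seed=11)
    tracks, truth = kt.simulate_tracks(schedules, cfg)
    return tracks, truth


@pytest.fixture(scope="session")
def daily_positions(small_tracks):
    return kt.daily_midpoints(small_tracks[0])


@pytest.fixture(scope="session")
def november_immersion(schedules):
    """One bird's immersion blocks over November (persistent chain)."""
    cfg = kt.MovementConfig(n_birds=1, fixes_per_day=2, noise_sd_km=50.0, seed=21)
    tracks, _ = kt.simulate_tracks(schedules, cfg)
    ts = pd.to_datetime(tracks["timestamp"])
    sub = tracks[(ts >= "2016-11-01") & (ts < "2016-12-01")]
    blocks, truth = kt.simulate_immersion(sub, kt.ImmersionSimConfig(seed=22))
    return blocks, truth


def point_colony_day(offsets_a, offsets_b, date=dt.date(2016, 10, 1)):
    """Daily-position table with two colonies at fixed (lat, lon) offsets."""
    rows = []
    for i, (lat, lon) in enumerate(offsets_a):
        rows.append((f"a{i}", "A", date, lat, lon))
    for i, (lat, lon) in enumerate(offsets_b):
        rows.append((f"b{i}", "B", date, lat, lon))
    return pd.DataFrame(rows, columns=["bird_id", "colony", "date", "lat", "lon"])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
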