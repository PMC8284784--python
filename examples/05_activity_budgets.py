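"""Immersion classification and activity budgets by solar day-phase.

Simulates a month of 5-minute immersion blocks for two birds, classifies
each block (>=98% wet = on water; all dry = flight; alternating = foraging),
assigns night / sunrise-window / day / sunset-window phases from solar
geometry at each bird's daily position, and prints the budget per phase.
"""

import pandas as pd

import kittitrack as kt
from kittitrack.activity import activity_table

schedules = kt.default_schedules(2016)
tracks, _ = kt.simulate_tracks(schedules, kt.MovementConfig(n_birds=1, noise_sd_km=50.0, seed=5))
ts = pd.to_datetime(tracks["timestamp"])
tracks = tracks[(ts >= "2016-11-01") & (ts < "2016-12-01")]

blocks, _ = kt.simulate_immersion(tracks, kt.ImmersionSimConfig(seed=6))
records = kt.assign_phases(blocks, kt.daily_midpoints(tracks))
records["colony"] = records["bird_id"].map(dict(zip(tracks["bird_id"], tracks["colony"])))

summary = kt.summarize_activity(records, by=["phase"])
print(summary.round(3).to_string(index=False))
print()
print(activity_table(records, ["colony", "phase"]).round(1).to_string(index=False))
# Night blocks are ~95% on-water (birds sit on the sea); the sunrise window
# carries the foraging peak; flight happens almost entirely in daylight.
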