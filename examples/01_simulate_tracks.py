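"""Simulate two colonies' non-breeding tracks and look at the raw material.

Builds the default seasonal schedules (one colony departing west immediately
in September, the other lingering on the Bering shelf, both converging over
the Kuril-Kamchatka Trench in late winter), simulates twice-daily position
fixes with 100 km isotropic noise, and prints where each colony sits in
mid-November — the period when the two strategies differ most.
"""

import kittitrack as kt

schedules = kt.default_schedules(start_year=2016)
tracks, truth = kt.simulate_tracks(schedules, kt.MovementConfig(n_birds=4, noise_sd_km=100.0, seed=1))
print(f"{len(tracks)} fixes for {tracks['bird_id'].nunique()} birds, "
      f"{tracks['timestamp'].min():%Y-%m-%d} to {tracks['timestamp'].max():%Y-%m-%d}")

daily = kt.daily_midpoints(tracks)
nov = daily[(daily["date"].astype(str) >= "2016-11-10") & (daily["date"].astype(str) <= "2016-11-20")]
for colony, grp in nov.groupby("colony"):
    print(f"  {colony:10s} mid-Nov centroid: {grp['lat'].mean():6.1f}°N, {grp['lon'].mean():7.1f}°E")
# The two centroids are ~2000 km apart in November: early-winter segregation
# is built into the default schedules, as observed for these colonies.
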