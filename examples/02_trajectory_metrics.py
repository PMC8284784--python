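"""Per-bird distance metrics over the non-breeding season.

Cumulative distance is the summed great-circle length of the twice-daily
track; maximum distance from the colony measures how far each bird ranged.
Only birds with a complete daily series over Sep 1 - Apr 30 are summarized.
"""

import datetime as dt

import kittitrack as kt

schedules = kt.default_schedules(2016)
tracks, _ = kt.simulate_tracks(schedules, kt.MovementConfig(n_birds=4, noise_sd_km=100.0, seed=2))

window = (dt.date(2016, 9, 1), dt.date(2017, 4, 30))
retained = kt.filter_complete(tracks, window, mode="locations")
positions = {s.colony_id: (s.colony_lat, s.colony_lon) for s in schedules}
table = kt.summarize_trajectories(tracks[tracks["bird_id"].isin(retained)], positions, window)

print(table[["bird_id", "colony", "cumulative_km", "max_colony_km"]].round(0).to_string(index=False))
means = table.groupby("colony")[["cumulative_km", "max_colony_km"]].mean().round(0)
print("\ncolony means (km):")
print(means.to_string())
# Cumulative distances are tens of thousands of km: with ~100 km noise on two
# fixes a day, noise alone contributes ~2 * 125 km/day over 242 days, so these
# values measure apparent (noise-inflated) path length, as for real
# geolocation tracks.
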