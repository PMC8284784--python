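"""The daily dispersal difference statistic with bootstrap CIs.

For each day, the mean great-circle distance over all between-colony bird
pairs minus the mean over all within-colony pairs. Zero = colonies spatially
mixed; positive = segregated. CIs resample birds within colonies (1000
resamples by default; 200 here for a quick run).
"""

import kittitrack as kt
from kittitrack.plots import plot_dispersal_series

schedules = kt.default_schedules(2016)
tracks, _ = kt.simulate_tracks(schedules, kt.MovementConfig(n_birds=4, noise_sd_km=100.0, seed=4))
daily = kt.daily_midpoints(tracks)

series = kt.dispersal_series(daily, n_boot=200, seed=4)
monthly = kt.dispersal_series(daily, n_boot=200, seed=4, scope="monthly")

print("monthly mean difference (km) with 95% bootstrap CI:")
for r in monthly.itertuples():
    print(f"  {r.month}: {r.difference_km:7.0f}  [{r.ci_low:7.0f}, {r.ci_high:7.0f}]")

ax = plot_dispersal_series(series)
ax.figure.savefig("dispersal_series.png", dpi=120, bbox_inches="tight")
print("wrote dispersal_series.png")
# Differences above ~1000 km in Oct-Nov shrink toward ~0 from January on:
# the colonies segregate in early winter and mix in late winter.
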