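# kittitrack

Analysis toolkit for the non-breeding ecology of colony-tracked seabirds —
built around the question of whether birds from geographically distant
breeding colonies (here, the two largest red-legged kittiwake colonies in
the Bering Sea, more than 1000 km apart) share wintering grounds and
behave alike at sea.

It is written for movement ecologists working with light-level geolocation
(GLS) tracks — twice-daily position estimates with errors of order
100–200 km — and leg-mounted saltwater-immersion loggers that tally wet
samples in 5-minute blocks. The package provides:

* **Trajectory metrics** — great-circle (haversine, R = 6371 km) distances,
  antimeridian-safe daily midpoints, cumulative distance and maximum
  distance from the colony, and completeness filtering so that period
  summaries only include birds with full data series.
* **Space use** — colony-level kernel utilization distributions (UDs) on an
  equal-area km grid (Lambert azimuthal projection), x% isopleths (50% =
  core distribution, 95% = overall range), and Bhattacharyya's affinity

  $$\mathrm{BA} = \sum_{\text{cells}} \sqrt{\mathrm{UD}_A \cdot \mathrm{UD}_B}\;\Delta A,$$

  computed on level-truncated, *un-renormalized* UDs so BA runs from 0
  (disjoint) to the truncation level itself (0.50 for core, 0.95 for range),
  with a bootstrap-over-birds standard error.
* **Dispersal** — the daily difference between mean between-colony and mean
  within-colony pairwise bird distances (0 = colonies mixed, positive =
  segregated), with bird-level bootstrap confidence intervals.
* **Activity** — classification of immersion blocks into on-water (≥ 98%
  wet), flight (fully dry) and active foraging (alternating wet/dry),
  solar day-phases (night / day / 1-h windows around sunrise and sunset,
  NOAA solar geometry at each bird's daily position), and budget summaries.
* **Group statistics** — James's two-sample unequal-covariance test on the
  de-degenerated (p_water, p_flight) sub-composition of per-bird budgets,
  J = (x̄₁−x̄₂)ᵀ(S₁/n₁+S₂/n₂)⁻¹(x̄₁−x̄₂), with bootstrap p-values, plus
  stage-wise breeding success (laying, hatching, fledging, overall).
* **A synthetic generator** — two-colony waypoint tracks with
  geolocation-like noise and a phase-dependent Markov behavior process whose
  emissions the classifier inverts exactly, so every stage is testable with
  known ground truth.

## Worked example

```python
import kittitrack as kt
import datetime as dt

schedules = kt.default_schedules(2016)              # two colonies, Sep 1 – Apr 30
tracks, _ = kt.simulate_tracks(schedules, kt.MovementConfig(n_birds=4, noise_sd_km=100, seed=3))
daily = kt.daily_midpoints(tracks)

for name, (w0, w1) in {"early": (dt.date(2016,10,1), dt.date(2016,12,31)),
                       "late":  (dt.date(2017,1,1),  dt.date(2017,3,31))}.items():
    sub = daily[(daily.date >= w0) & (daily.date <= w1)]
    res = kt.ba_bootstrap(sub[sub.colony=="buldir"], sub[sub.colony=="st_george"],
                          level=0.5, n_boot=50, seed=3)
    print(name, f"BA_50 = {res.ba:.3f} ± {res.ba_se:.3f}")
```

prints

```
early BA_50 = 0.000 ± 0.000
late BA_50 = 0.434 ± 0.008
```

i.e. the two colonies' 50% core distributions are disjoint in early winter
(one colony is in the Sea of Okhotsk, the other on the Bering shelf) and
overlap strongly in late winter when both converge on the shared wintering
region — BA_50 can reach at most 0.50. The `examples/` directory has one
short script per capability (simulation, trajectory metrics, UD overlap,
dispersal, activity budgets, James tests and breeding success, full
pipeline), each printing the numbers it computes and what they mean.

A thin CLI drives the same stages from the shell:

```
kittitrack simulate --seed 1 --out data
kittitrack run-all --tracks data/tracks.csv --immersion data/immersion.csv --seed 1 --out results
```

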