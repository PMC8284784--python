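# Methods

This note documents the models, estimators and numerical choices behind
kittitrack, what the synthetic generator does and does not emulate, and the
design decisions taken where the analysis admitted more than one reasonable
reading.

## Geometry

All distances are great-circle (haversine) on a sphere of radius 6371 km.
Ellipsoidal geodesics would change distances by < 0.5%, far below
light-level geolocation error (median radial errors of order 100–200 km),
so they are deliberately not used. Midpoints (daily positions, pooled
centroids) are computed as normalized 3-D Cartesian vector means, which are
exact on the sphere and continuous across the antimeridian — the study
region spans 180°, so naive longitude averaging would be wrong by up to
180°. The midpoint is undefined (raises) only for antipodal cancellation.

Daily positions collapse the twice-daily fixes to one midpoint per bird per
calendar day; a single fix stands for itself; days without fixes carry no
record rather than an interpolated one.

## Completeness filtering

Period summaries (trajectory totals, pooled UDs, activity budgets) are
biased when a bird contributes only part of the window, so birds without
complete series are excluded. "Complete" is implemented as a coverage
fraction — days with ≥ 1 fix (locations) or expected 5-minute blocks
present (immersion) — with a threshold `tolerance` defaulting to 1.0
(strict). The strict default reflects the usual practice of excluding birds
without full datasets; the tolerance is exposed because real logger series
have benign single-block dropouts.

## Utilization distributions and overlap

Positions are projected with a spherical Lambert azimuthal equal-area
projection centered on the pooled data centroid. Equal-area is essential:
the UD is a density per km², and the comparison region crosses the
antimeridian, which rules out plate carrée and any fixed-zone projection.
The UD is an isotropic bivariate Gaussian KDE evaluated on a regular grid
(default 50 km cells, covering the data padded by 3 bandwidths) and
renormalized to discrete mass 1 (tolerance 1e-6). The default bandwidth is
the reference ("href"-style) choice h = sqrt(½(var x + var y))·n^(−1/6),
the convention in kernel home-range estimation; it is deliberately
conservative (over-smooth) for clumped data, and callers can override it.
An all-identical point set has no data-driven bandwidth and raises with a
pointer to set one explicitly.

The x% isopleth is the smallest-area cell set containing x of the mass:
cells ranked by density, minimal prefix with cumulative mass ≥ x. Truncated
mass therefore lies in [x, x + max single-cell mass); with default settings
the largest cell holds ≪ 0.005, so quantization is negligible. Truncated
UDs are **not** renormalized before overlap. This is what makes
Bhattacharyya's affinity of a surface with itself equal the truncation
level (0.50 / 0.95) rather than 1, matching the convention in which those
are the printed maxima; the package treats that bound as a contract and
tests it.

Colony UDs pool all retained birds' daily positions with equal per-fix
weight (the conventional colony-level kernel practice; a per-bird-averaged
variant is a natural extension). Overlap uncertainty is a bootstrap over
birds within each colony: birds are resampled with replacement, the pooled
UD and BA recomputed, and the SE is the SD of the bootstrap distribution.
Two choices here are the package's own: (i) the resampling unit is the bird
(tracks are strongly autocorrelated within birds, so resampling fixes would
fabricate precision), and (ii) the grid and bandwidth are fixed at their
full-data values across resamples, so the bootstrap measures sampling
variability of the surfaces rather than of the smoothing parameter — this
also lets a resample be computed as a weighted sum of precomputed per-bird
kernel grids.

## Dispersal statistic

For each day, mean great-circle distance over all between-colony pairs
minus the mean over all same-colony pairs, the latter pooled across both
colonies with equal pair weight (the direct reading of "average
within-colony distance"; a mean-of-colony-means variant is available via
`within_mode`). Zero means birds were as close to the other colony's birds
as to their own; positive values mean segregation.

Confidence intervals are percentile bootstrap (default 1000 resamples,
95%) resampling birds within colonies, with the whole daily series replayed
per resample to preserve within-bird temporal dependence. Pairs formed by
two resample copies of the same bird are excluded from within-colony means:
such pairs have distance 0 by construction and would otherwise bias every
resampled difference upward. Monthly-scope CIs average daily differences
within month per resample before taking percentiles.

## Activity classification and day-phases

A 5-minute block with n samples (default 50, one per 6 s) maps to:
on-water if wet/n ≥ 0.98 (so 49/50 qualifies, 48/50 does not), flight if
wet = 0, foraging otherwise. The three regions partition {0, …, n} for any
n ≥ 2. The classifier cannot see "sit-and-wait" foraging (a floating bird
dipping its beak), which is an acknowledged blind spot of immersion data,
nor distinguish flight from dry roosting.

Day-phases come from NOAA solar geometry (Fourier expansions for the
equation of time and declination, zenith 90.833°) evaluated at the bird's
daily midpoint; accuracy is a few minutes against reference almanac values,
well inside the 5-minute block resolution. Event times are kept unwrapped
(sunrise < sunset always, possibly spilling across UTC date boundaries near
the antimeridian) and each block is checked against the events of its date
and both neighbors. Polar day/night are explicit flags mapping to all-day /
all-night. The 1-hour windows around sunrise and sunset are centered
(±30 min) by default; an uncentered post-event reading ([event, event+1h))
is supported via `window_mode="post"` because descriptions of a foraging
peak "during the hour after sunrise" suggest that alternative. A block's
phase is decided by its start time; blocks are not split at boundaries (≤ 5
min error). Days without a position borrow the nearest day within 2 days,
else the block is excluded from phase summaries and logged.

Budget tables report percent time as mean ± SD **across birds** per group
(the bird, not the block, is the sampling unit).

## Compositional inference

Per-bird budgets (p_water, p_flight, p_forage) sum to 1; their 3-D
covariance is singular. The James statistic therefore operates on the
(p_water, p_flight) sub-composition by default (an isometric log-ratio
transform is provided for strictly positive compositions). Covariances use
n−1 denominators. The bootstrap null translates each group to the pooled
mean — preserving within-group covariance while imposing equal means —
resamples birds with replacement within groups (default 1000 resamples) and
reports p = (1 + #{J* ≥ J_obs})/(n_boot + 1); the +1 keeps p > 0. James's
(1954) second-order chi-square critical-value expansion is implemented for
reference output, but the bootstrap p is the headline inference. Type-I
calibration is verified by simulation (500 null replicates of two 15-bird
groups: rejection rate within 3 binomial SEs of 0.05).

## Breeding success

Stage-wise nest proportions: laying = eggs/nests, hatching = hatched/eggs,
fledging = fledged/hatched, overall = fledged/nests. Counts must be
monotone non-increasing; a zero denominator leaves that stage NaN
(undefined) rather than 0, and overall = laying·hatching·fledging holds
identically whenever all stages are defined.

## Synthetic generator

The generator defines the conditions under which the package is tested.

**Tracks.** Each colony has a waypoint schedule spanning Sep 1 – Apr 30;
positions interpolate between waypoints along great circles proportionally
to elapsed time, sampled at 2 fixes/day (06:00/18:00 UTC). The default
schedules encode the study system's qualitative geography — one colony
(Buldir, 52.35°N 175.93°E) departing west immediately in September toward
the Kuril Islands and Sea of Okhotsk, the other (St. George, 56.6°N
169.55°W) remaining on the Bering shelf until December, both converging on
a shared late-winter centroid over the Kuril-Kamchatka Trench (47°N 158°E)
January–March and returning by April 30. Exact waypoint coordinates are
free parameters of the generator chosen once to reproduce that pattern.
Noise is isotropic Gaussian in a local tangent plane (km east/north, mapped
back through the local degree scale), SD 100 km per fix by default — a
median radial error of ~118 km, consistent with geolocation errors whose
medians reach ~185 km. Isotropy in kilometers (not degrees) is why the
noise is applied in the tangent plane.

**Immersion.** Per block, a behavior state evolves by a sticky Markov chain
P = s·I + (1−s)·1πᵀ whose stationary distribution is exactly the day-phase
occupancy target π for any persistence s ∈ [0,1) (default 0.8 — one
interpretable knob for temporal clumping). Default targets: night
(0.948, 0.022, 0.030) — anchored to observed ~95% nocturnal on-water time;
sunrise window (0.064, 0.466, 0.470) — the post-dawn foraging peak; day
(0.45, 0.40, 0.15) and sunset window (0.60, 0.30, 0.10), chosen so the
overall season budget lands near the observed ~70/18/12 water/flight/forage
split. Emissions are constructed inside the classifier's decision regions —
on-water draws uniformly from {c : c/n ≥ 0.98} (= {n−1, n} for n ≥ 50),
flight emits 0, foraging uniformly from the remaining counts — so
classification inverts the generator exactly for any n ≥ 2, making
classifier recovery an exact test rather than a statistical one.

**What the generator does not emulate.** Real geolocation error is
non-Gaussian, latitude-biased near equinoxes, and temporally correlated;
real birds have individual variation in budgets and trip structure; real
immersion series have hardware dropouts. Tests passing on this generator
validate the estimators' correctness and calibration under clean
conditions, not robustness to those artifacts.

## Numerical and degenerate-input conventions

Ties in isopleth ranking are resolved by sort order and are measure-zero
for KDE surfaces. BA requires bit-identical grids (no implicit
resampling). Windows given as bare dates are inclusive of the whole end
day. All timestamps are UTC; solar phase is the only place local time
enters and it is always computed, never read. Every stochastic routine
takes a seed and is exactly reproducible; the pipeline derives per-stage
seeds from the run seed via `SeedSequence`, and a rerun with equal inputs,
config and seed reproduces all CSV/GeoJSON outputs byte-identically.

## Problem sizes in tests and reference runs

The test suite and the acceptance script run the generator at desk scale —
typically 3–4 birds per colony over a full season (≈ 970 daily positions
per colony) and 1–2 birds over 1–2.5 months of immersion blocks (10–22k
blocks), with bootstrap counts of 25–200 in pipeline smoke tests. These
sizes were chosen to exercise every code path with comfortable
Monte-Carlo margins; all estimators accept arbitrarily larger inputs.

## Known limitations

Isopleth masks at coarse cells make BA mildly resolution-dependent
(tested: halving 50 km cells moves BA by < 0.01 on smooth surfaces). The
pooled-UD bootstrap underestimates variance for very few birds (2–3 per
colony), as any bird-level bootstrap must. The James bootstrap null assumes
exchangeable birds within groups. Geographic midpoints degrade for fix
pairs approaching antipodality (irrelevant at twice-daily sampling). The
pipeline's phase assignment is start-time based and can misphase a block by
at most one block length.
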