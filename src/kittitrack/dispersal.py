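"""Daily between/within-colony distance structure and the dispersal statistic.

For every day, the mean great-circle distance over all cross-colony bird
pairs and over all same-colony pairs (pooled across both colonies with equal
pair weight) is computed from daily positions, and their difference

    difference = mean_between − mean_within

summarizes spatial segregation: 0 means birds were equally close to birds of
either colony, positive values mean the colonies were segregated, negative
values mean birds sat closer to the other colony's birds than to their own.

Confidence intervals come from a bootstrap whose resampling unit is the
*bird* (within colony), so each resample replays the whole season for a
resampled set of individuals and within-bird temporal dependence is kept.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .trajectories import great_circle_km

__all__ = ["daily_pair_means", "dispersal_difference", "dispersal_series", "dispersal_bootstrap"]


def _pair_distance_matrix(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    return great_circle_km((lat[:, None], lon[:, None]), (lat[None, :], lon[None, :]))


def _pair_means(D: np.ndarray, is_a: np.ndarray, within_mode: str = "pooled"):
    """Mean cross-colony and same-colony pair distances from a distance matrix
    and a boolean colony indicator. within_mode "pooled" averages all
    same-colony pairs together; "colony_mean" averages the two per-colony
    means."""
    ia = np.where(is_a)[0]
    ib = np.where(~is_a)[0]
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("no cross-colony pairs that day")
    between = float(D[np.ix_(ia, ib)].mean())

    def colony_pairs(idx):
        if len(idx) < 2:
            return None, 0
        sub = D[np.ix_(idx, idx)]
        m = len(idx)
        return float(sub.sum() / 2.0), m * (m - 1) // 2

    sum_a, n_a = colony_pairs(ia)
    sum_b, n_b = colony_pairs(ib)
    if n_a + n_b == 0:
        raise ValueError("no within-colony pairs that day")
    if n_a == 0 or n_b == 0:
        warnings.warn("a colony has <2 birds; within-colony mean uses remaining pairs")
    if within_mode == "pooled":
        within = ((sum_a or 0.0) + (sum_b or 0.0)) / (n_a + n_b)
    elif within_mode == "colony_mean":
        means = [s / n for s, n in ((sum_a, n_a), (sum_b, n_b)) if n > 0]
        within = float(np.mean(means))
    else:
        raise ValueError(f"unknown within_mode {within_mode!r}")
    return between, within


def daily_pair_means(daily_positions: pd.DataFrame, date, within_mode: str = "pooled"):
    """(mean_between_km, mean_within_km) over all bird pairs on one day.

    ``daily_positions`` has columns bird_id, colony, date, lat, lon with at
    most one row per bird per day.
    """
    day = daily_positions[daily_positions["date"] == date]
    if len(day) < 2:
        raise ValueError("need at least 2 birds with a position that day")
    colonies = sorted(day["colony"].unique())
    if len(colonies) != 2:
        raise ValueError("daily pair means are defined for exactly 2 colonies")
    D = _pair_distance_matrix(day["lat"].to_numpy(), day["lon"].to_numpy())
    is_a = (day["colony"] == colonies[0]).to_numpy()
    return _pair_means(D, is_a, within_mode)


def dispersal_difference(daily_positions: pd.DataFrame, date, within_mode: str = "pooled") -> float:
    """mean_between − mean_within for one day (km)."""
    between, within = daily_pair_means(daily_positions, date, within_mode)
    return between - within


def _series_for_birds(day_tables, order_a, order_b, within_mode):
    """Daily (between, within) for a fixed multiset of birds per colony.

    ``day_tables`` maps date -> (D, index_of_bird) where index_of_bird maps a
    bird id to its row in the day's distance matrix (absent if no position).
    Duplicate birds (bootstrap resamples) are allowed: pairs of a bird with
    its own copy carry zero distance and are excluded, otherwise resampled
    within-colony means would be biased toward zero.
    """
    out = {}
    for date, (D, idx) in day_tables.items():
        rows_a = np.array([idx[b] for b in order_a if b in idx], dtype=int)
        rows_b = np.array([idx[b] for b in order_b if b in idx], dtype=int)
        if len(rows_a) == 0 or len(rows_b) == 0 or len(rows_a) + len(rows_b) < 3:
            continue
        between = float(D[np.ix_(rows_a, rows_b)].mean())

        def colony_pairs(rows):
            # pair sum/count over distinct-bird slot pairs
            if len(rows) < 2:
                return 0.0, 0
            sub = D[np.ix_(rows, rows)]
            distinct = rows[:, None] != rows[None, :]
            return float(sub[distinct].sum() / 2.0), int(distinct.sum() // 2)

        sum_a, n_a = colony_pairs(rows_a)
        sum_b, n_b = colony_pairs(rows_b)
        if n_a + n_b == 0:
            continue
        if within_mode == "pooled":
            within = (sum_a + sum_b) / (n_a + n_b)
        else:
            means = [s / n for s, n in ((sum_a, n_a), (sum_b, n_b)) if n > 0]
            within = float(np.mean(means))
        out[date] = (between, within)
    return out


def dispersal_series(
    daily_positions: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    scope: str = "daily",
    within_mode: str = "pooled",
    ci: float = 0.95,
) -> pd.DataFrame:
    """Full dispersal series with bootstrap percentile confidence intervals.

    scope="daily" gives one record per day; scope="monthly" averages the
    daily differences within each calendar month before taking bootstrap
    percentiles. Deterministic given ``seed``.
    """
    if scope not in ("daily", "monthly"):
        raise ValueError(f"unknown scope {scope!r}")
    colonies = sorted(daily_positions["colony"].unique())
    if len(colonies) != 2:
        raise ValueError("dispersal series needs exactly 2 colonies")
    birds_a = sorted(daily_positions.loc[daily_positions["colony"] == colonies[0], "bird_id"].unique())
    birds_b = sorted(daily_positions.loc[daily_positions["colony"] == colonies[1], "bird_id"].unique())
    if len(birds_a) < 2 or len(birds_b) < 2:
        raise ValueError("bootstrap needs at least 2 birds per colony")

    day_tables = {}
    for date, day in daily_positions.groupby("date", sort=True):
        D = _pair_distance_matrix(day["lat"].to_numpy(), day["lon"].to_numpy())
        idx = {b: i for i, b in enumerate(day["bird_id"])}
        day_tables[date] = (D, idx)

    point = _series_for_birds(day_tables, birds_a, birds_b, within_mode)
    dates = sorted(point)

    rng = np.random.default_rng(seed)
    # bird-level bootstrap: one resampled bird set replayed over all days
    boot_diffs = np.full((n_boot, len(dates)), np.nan)
    date_pos = {d: j for j, d in enumerate(dates)}
    for r in range(n_boot):
        sa = [birds_a[i] for i in rng.integers(0, len(birds_a), len(birds_a))]
        sb = [birds_b[i] for i in rng.integers(0, len(birds_b), len(birds_b))]
        for date, (between, within) in _series_for_birds(day_tables, sa, sb, within_mode).items():
            if date in date_pos:
                boot_diffs[r, date_pos[date]] = between - within

    lo_q, hi_q = (1 - ci) / 2 * 100, (1 + ci) / 2 * 100
    n_a = {d: sum(1 for b in birds_a if b in day_tables[d][1]) for d in dates}
    n_b = {d: sum(1 for b in birds_b if b in day_tables[d][1]) for d in dates}

    if scope == "daily":
        rows = []
        for j, d in enumerate(dates):
            between, within = point[d]
            col = boot_diffs[:, j]
            col = col[np.isfinite(col)]
            lo, hi = np.percentile(col, [lo_q, hi_q]) if len(col) else (np.nan, np.nan)
            rows.append(
                {
                    "date": d,
                    "mean_between_km": between,
                    "mean_within_km": within,
                    "difference_km": between - within,
                    "ci_low": lo,
                    "ci_high": hi,
                    f"n_{colonies[0]}": n_a[d],
                    f"n_{colonies[1]}": n_b[d],
                }
            )
        return pd.DataFrame(rows)

    # monthly: average daily differences within month, percentile over resamples
    months = pd.PeriodIndex([pd.Timestamp(d) for d in dates], freq="M")
    rows = []
    for month in months.unique():
        jj = np.where(months == month)[0]
        diffs = np.array([point[dates[j]][0] - point[dates[j]][1] for j in jj])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            boot_month = np.nanmean(boot_diffs[:, jj], axis=1)
        boot_month = boot_month[np.isfinite(boot_month)]
        lo, hi = np.percentile(boot_month, [lo_q, hi_q]) if len(boot_month) else (np.nan, np.nan)
        rows.append(
            {
                "month": str(month),
                "difference_km": float(diffs.mean()),
                "ci_low": lo,
                "ci_high": hi,
                "n_days": len(jj),
            }
        )
    return pd.DataFrame(rows)


def dispersal_bootstrap(
    daily_positions: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    scope: str = "daily",
    **kwargs,
) -> pd.DataFrame:
    """Alias for :func:`dispersal_series` emphasizing the CI computation."""
    return dispersal_series(daily_positions, n_boot=n_boot, seed=seed, scope=scope, **kwargs)
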