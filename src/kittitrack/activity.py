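"""Immersion-based behavior classification and solar day-phase budgets.

Leg-mounted geolocators sense saltwater immersion every 6 s and tally the wet
samples per 5-minute block (50 samples by default). Each block maps to one of
three behaviors:

* ``on_water``  — wet for ≥ 98% of the block (occasional dry reads come from
  bathing/preening while sitting on the sea surface);
* ``flight``    — dry for the entire block (surface-feeding gulls do not stay
  dry at sea any other way, though roosting on flotsam is indistinguishable);
* ``foraging``  — alternating wet/dry reads, the signature of repeated short
  plunges and surface-splashing.

Blocks are also assigned a solar day-phase — night, day, or 1-hour windows
around sunrise and sunset — from solar geometry at the bird's daily position,
and activity budgets are summarized per colony/month/phase.
"""

from __future__ import annotations

import datetime as _dt
import logging

import numpy as np
import pandas as pd

from .solar import SolarEvents, solar_events

logger = logging.getLogger(__name__)

BEHAVIORS = ("on_water", "flight", "foraging")
PHASES = ("night", "sunrise_window", "day", "sunset_window")

WET_FRACTION_ON_WATER = 0.98


def classify_block(wet_count: int, n_samples: int = 50) -> str:
    """Behavior of one immersion block from its wet-sample tally."""
    if not (0 <= wet_count <= n_samples):
        raise ValueError(f"wet_count {wet_count} outside [0, {n_samples}]")
    if wet_count == 0:
        return "flight"
    if wet_count / n_samples >= WET_FRACTION_ON_WATER:
        return "on_water"
    return "foraging"


def classify_blocks(blocks: pd.DataFrame) -> pd.Series:
    """Vectorized behavior for a block table (columns wet_count, n_samples)."""
    wet = blocks["wet_count"].to_numpy()
    n = blocks["n_samples"].to_numpy()
    if np.any(wet < 0) or np.any(wet > n):
        raise ValueError("wet_count outside [0, n_samples]")
    out = np.where(
        wet == 0, "flight", np.where(wet / n >= WET_FRACTION_ON_WATER, "on_water", "foraging")
    )
    return pd.Series(out, index=blocks.index, name="behavior")


def assign_phase(
    block_start: _dt.datetime,
    events_by_date: dict[_dt.date, SolarEvents],
    half_width_min: float = 30.0,
    window_mode: str = "centered",
) -> str:
    """Solar day-phase of one block start time.

    ``events_by_date`` must contain the block's UTC date and ideally its
    neighbors (event times at longitudes near the antimeridian spill across
    UTC date boundaries). Windows around sunrise/sunset are 1 h wide:
    centered (±30 min, the default) or starting at the event
    (``window_mode="post"``). Polar days are all "day", polar nights all
    "night".
    """
    if window_mode not in ("centered", "post"):
        raise ValueError(f"unknown window_mode {window_mode!r}")
    t = block_start
    d0 = t.date()
    lo = -half_width_min if window_mode == "centered" else 0.0
    hi = half_width_min if window_mode == "centered" else 2.0 * half_width_min
    in_day = False
    polar_votes = []
    for dd in (-1, 0, 1):
        ev = events_by_date.get(d0 + _dt.timedelta(days=dd))
        if ev is None:
            continue
        if ev.polar is not None:
            if dd == 0:
                polar_votes.append(ev.polar)
            continue
        for event, name in ((ev.sunrise, "sunrise_window"), (ev.sunset, "sunset_window")):
            delta = (t - event).total_seconds() / 60.0
            if lo <= delta < hi:
                return name
        if ev.sunrise + _dt.timedelta(minutes=hi) <= t < ev.sunset + _dt.timedelta(minutes=lo):
            in_day = True
    if polar_votes:
        return "day" if polar_votes[0] == "day" else "night"
    return "day" if in_day else "night"


def assign_phases(
    blocks: pd.DataFrame,
    daily_positions: pd.DataFrame,
    half_width_min: float = 30.0,
    window_mode: str = "centered",
    max_gap_days: int = 2,
) -> pd.DataFrame:
    """Add behavior and phase columns to an immersion block table.

    Solar geometry uses each bird's daily position; days with no position
    borrow the nearest available day within ``max_gap_days``, else the
    block's phase is left missing (excluded from phase summaries, logged).
    """
    blocks = blocks.copy()
    blocks["behavior"] = classify_blocks(blocks)
    pos = {
        (r.bird_id, r.date): (r.lat, r.lon)
        for r in daily_positions.itertuples()
    }
    dates_by_bird: dict = {}
    for bird, grp in daily_positions.groupby("bird_id"):
        dates_by_bird[bird] = sorted(grp["date"])

    def position_for(bird, date):
        if (bird, date) in pos:
            return pos[(bird, date)]
        dates = dates_by_bird.get(bird)
        if not dates:
            return None
        nearest = min(dates, key=lambda d: abs((d - date).days))
        if abs((nearest - date).days) <= max_gap_days:
            return pos[(bird, nearest)]
        return None

    phases = np.empty(len(blocks), dtype=object)
    ts = pd.to_datetime(blocks["block_start"])
    py_times = [t.to_pydatetime() for t in ts]
    block_dates = ts.dt.date.to_numpy()
    birds = blocks["bird_id"].to_numpy()
    events_cache: dict = {}
    n_missing = 0
    for i in range(len(blocks)):
        key = (birds[i], block_dates[i])
        if key not in events_cache:
            p = position_for(*key)
            if p is None:
                events_cache[key] = None
            else:
                events_cache[key] = {
                    d: solar_events(p[0], p[1], d)
                    for d in (
                        key[1] - _dt.timedelta(days=1),
                        key[1],
                        key[1] + _dt.timedelta(days=1),
                    )
                }
        ev = events_cache[key]
        if ev is None:
            phases[i] = None
            n_missing += 1
        else:
            phases[i] = assign_phase(py_times[i], ev, half_width_min, window_mode)
    if n_missing:
        logger.warning("%d blocks had no usable daily position; phase left missing", n_missing)
    blocks["phase"] = phases
    return blocks


def summarize_activity(records: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Behavior-budget proportions per group.

    ``records`` is a classified block table (behavior column present; phase
    and colony columns as needed); ``by`` lists grouping columns drawn from
    {colony, month, phase, bird_id} (month is derived from block_start).
    Proportions are block counts over total blocks in the group and sum to 1.
    """
    df = records.copy()
    if by and "month" in by and "month" not in df.columns:
        df["month"] = pd.to_datetime(df["block_start"]).dt.month
    if by and "phase" in by:
        df = df[df["phase"].notna()]
    group_iter = df.groupby(by, sort=True) if by else [((), df)]
    rows = []
    for keys, grp in group_iter:
        if not isinstance(keys, tuple):
            keys = (keys,)
        counts = grp["behavior"].value_counts()
        total = int(counts.sum())
        if total == 0:
            continue
        row = dict(zip(by or [], keys))
        row.update(
            {
                "p_water": counts.get("on_water", 0) / total,
                "p_flight": counts.get("flight", 0) / total,
                "p_forage": counts.get("foraging", 0) / total,
                "n_blocks": total,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def bird_compositions(records: pd.DataFrame, group_cols: list[str] | None = None) -> pd.DataFrame:
    """Per-bird (p_water, p_flight, p_forage) time-budget compositions.

    One row per bird (and optional extra grouping columns, e.g. colony or a
    winter period); the unit of inference for between-group composition
    tests. Components sum to 1 for every bird.
    """
    by = ["bird_id"] + [c for c in (group_cols or []) if c != "bird_id"]
    return summarize_activity(records, by=by)


def activity_table(records: pd.DataFrame, group_cols: list[str]) -> pd.DataFrame:
    """Mean ± SD (across birds) percent time per behavior, per group — the
    conventional activity-budget summary layout."""
    comp = bird_compositions(records, group_cols)
    rows = []
    for keys, grp in comp.groupby(group_cols, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(group_cols, keys))
        for col, name in (("p_water", "water"), ("p_flight", "flight"), ("p_forage", "forage")):
            row[f"pct_{name}_mean"] = 100.0 * grp[col].mean()
            row[f"pct_{name}_sd"] = 100.0 * grp[col].std(ddof=1)
        row["n_birds"] = len(grp)
        rows.append(row)
    return pd.DataFrame(rows)
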