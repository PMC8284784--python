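"""Distance metrics on estimated position tracks.

All geometry is spherical (mean Earth radius 6371 km). Geolocation error is
of order 100–200 km, so ellipsoidal corrections (< 0.5%) are irrelevant here.
Midpoints are computed through 3-D Cartesian vector means, which keeps every
operation well behaved across the antimeridian — the study region spans 180°.

Tracks are plain pandas DataFrames with columns
``bird_id, colony, timestamp, lat, lon`` (timestamps UTC); daily positions use
``bird_id, colony, date, lat, lon``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: Default analysis windows: the non-breeding period runs September–April and
#: immersion-based activity analyses are restricted to October–March.
NON_BREEDING_WINDOW = ((9, 1), (4, 30))
ACTIVITY_WINDOW = ((10, 1), (3, 31))


class CoordinateError(ValueError):
    """Raised for latitudes/longitudes outside their valid ranges."""


def _check_coords(lat, lon) -> tuple[np.ndarray, np.ndarray]:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise CoordinateError("non-finite coordinate")
    if np.any(np.abs(lat) > 90.0):
        raise CoordinateError("latitude outside [-90, 90]")
    # Longitudes are wrapped, not rejected: 0–360 and unwrapped inputs are
    # equivalent directions on the sphere.
    lon = wrap_lon(lon)
    return lat, lon


def wrap_lon(lon):
    """Wrap longitudes into (-180, 180]."""
    lon = np.asarray(lon, dtype=float)
    wrapped = ((lon + 180.0) % 360.0) - 180.0
    return np.where(wrapped == -180.0, 180.0, wrapped)


def great_circle_km(p1, p2) -> float | np.ndarray:
    """Haversine great-circle distance in km between (lat, lon) points.

    Accepts scalars or broadcastable arrays of degrees. Symmetric,
    non-negative and zero only for coincident points.
    """
    lat1, lon1 = _check_coords(*p1)
    lat2, lon2 = _check_coords(*p2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def to_unit_vectors(lat, lon) -> np.ndarray:
    """Degrees -> unit vectors on the sphere, shape (..., 3)."""
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    return np.stack(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)], axis=-1
    )


def from_unit_vectors(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors -> (lat, lon) in degrees."""
    v = np.asarray(v, dtype=float)
    lat = np.degrees(np.arctan2(v[..., 2], np.hypot(v[..., 0], v[..., 1])))
    lon = np.degrees(np.arctan2(v[..., 1], v[..., 0]))
    return lat, lon


def geographic_midpoint(lats, lons) -> tuple[float, float]:
    """Antimeridian-safe midpoint of a set of points via the normalized
    3-D vector mean. Undefined (raises) for antipodal cancellation."""
    lats, lons = _check_coords(lats, lons)
    v = to_unit_vectors(lats, lons).reshape(-1, 3).mean(axis=0)
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ValueError("midpoint undefined: points cancel (antipodal configuration)")
    lat, lon = from_unit_vectors(v / norm)
    return float(lat), float(lon)


def daily_midpoints(tracks: pd.DataFrame) -> pd.DataFrame:
    """Collapse fixes to one position per bird per calendar day.

    With two fixes the result is their great-circle midpoint; a single fix
    stands for itself. Days without fixes simply have no record. Returns a
    DataFrame with columns ``bird_id, colony, date, lat, lon``.
    """
    tracks = tracks.copy()
    tracks["date"] = pd.to_datetime(tracks["timestamp"]).dt.date
    rows = []
    for (bird, date), grp in tracks.groupby(["bird_id", "date"], sort=True):
        lat, lon = geographic_midpoint(grp["lat"].to_numpy(), grp["lon"].to_numpy())
        rows.append((bird, grp["colony"].iloc[0], date, lat, lon))
    return pd.DataFrame(rows, columns=["bird_id", "colony", "date", "lat", "lon"])


def _as_bound(value, ts: pd.Series) -> pd.Timestamp:
    """A window bound coerced to the tz-awareness of the timestamp series."""
    bound = pd.Timestamp(value)
    if ts.dt.tz is not None and bound.tz is None:
        bound = bound.tz_localize("UTC")
    elif ts.dt.tz is None and bound.tz is not None:
        bound = bound.tz_localize(None)
    return bound


def _window_mask(timestamps: pd.Series, window) -> pd.Series:
    if window is None:
        return pd.Series(True, index=timestamps.index)
    ts = pd.to_datetime(timestamps)
    start = _as_bound(window[0], ts)
    # a bare date as the end bound means "through that whole day"
    end = _as_bound(window[1], ts)
    if isinstance(window[1], _dt.date) and not isinstance(window[1], _dt.datetime):
        end = end + pd.Timedelta(days=1) - pd.Timedelta(nanoseconds=1)
    return (ts >= start) & (ts <= end)


def cumulative_distance(track: pd.DataFrame, window=None) -> float:
    """Total great-circle path length (km) over consecutive fixes of one bird.

    ``window`` is an optional (start, end) pair of timestamps/dates bounding
    the fixes used (inclusive). Raises if fewer than two fixes remain.
    """
    t = track.sort_values("timestamp")
    t = t[_window_mask(t["timestamp"], window).to_numpy()]
    if len(t) < 2:
        raise ValueError("cumulative distance undefined: fewer than 2 fixes in window")
    lat = t["lat"].to_numpy()
    lon = t["lon"].to_numpy()
    seg = great_circle_km((lat[:-1], lon[:-1]), (lat[1:], lon[1:]))
    return float(np.sum(seg))


def max_distance_from_colony(track: pd.DataFrame, colony: tuple[float, float], window=None) -> float:
    """Maximum great-circle distance (km) of any fix from the colony position."""
    t = track[_window_mask(track["timestamp"], window).to_numpy()]
    if len(t) == 0:
        raise ValueError("max distance undefined: no fixes in window")
    d = great_circle_km((t["lat"].to_numpy(), t["lon"].to_numpy()), colony)
    return float(np.max(d))


@dataclass(frozen=True)
class TrajectorySummary:
    bird_id: str
    colony: str
    cumulative_km: float
    max_colony_km: float
    window: tuple[_dt.date, _dt.date]


def summarize_trajectories(
    tracks: pd.DataFrame,
    colony_positions: dict[str, tuple[float, float]],
    window,
) -> pd.DataFrame:
    """Per-bird cumulative distance and maximum colony distance over a window.

    Returns a table with one row per bird, mirroring the conventional
    "cumulative distance / max distance from colony" summary.
    """
    rows = []
    for bird, grp in tracks.groupby("bird_id", sort=True):
        colony = grp["colony"].iloc[0]
        rows.append(
            {
                "bird_id": bird,
                "colony": colony,
                "cumulative_km": cumulative_distance(grp, window),
                "max_colony_km": max_distance_from_colony(grp, colony_positions[colony], window),
                "window_start": window[0],
                "window_end": window[1],
            }
        )
    return pd.DataFrame(rows)


def _date_range(start: _dt.date, end: _dt.date) -> list[_dt.date]:
    n = (end - start).days + 1
    return [start + _dt.timedelta(days=d) for d in range(n)]


def filter_complete(
    df: pd.DataFrame,
    window: tuple[_dt.date, _dt.date],
    mode: str = "locations",
    tolerance: float = 1.0,
    block_minutes: int = 5,
) -> list:
    """Birds whose data cover a window completely enough to be retained.

    Period summaries are biased if a bird contributes only part of the window,
    so birds without (near-)complete series are excluded.

    mode="locations": coverage is the fraction of calendar days in the window
    with at least one fix. mode="immersion": the fraction of expected
    ``block_minutes`` blocks present. A bird is retained when coverage >=
    ``tolerance`` (default 1.0, strict).
    """
    if mode not in ("locations", "immersion"):
        raise ValueError(f"unknown mode {mode!r}")
    retained = []
    time_col = "timestamp" if mode == "locations" else "block_start"
    for bird, grp in df.groupby("bird_id", sort=True):
        ts = pd.to_datetime(grp[time_col])
        start = _as_bound(window[0], ts)
        end = _as_bound(window[1], ts) + pd.Timedelta(days=1)  # end date inclusive
        inside = grp[((ts >= start) & (ts < end)).to_numpy()]
        if mode == "locations":
            n_days = (end - start).days
            covered = pd.to_datetime(inside["timestamp"]).dt.date.nunique()
            coverage = covered / n_days
        else:
            expected = (end - start) / pd.Timedelta(minutes=block_minutes)
            coverage = inside["block_start"].nunique() / expected
        if coverage >= tolerance:
            retained.append(bird)
    return retained
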