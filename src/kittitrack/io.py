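"""CSV/GeoJSON/YAML input-output for the pipeline's tabular schemas.

Track CSV:      bird_id,colony,timestamp_utc,lat,lon (ISO-8601 UTC)
Immersion CSV:  bird_id,block_start_utc,wet_count,n_samples
Nests CSV:      colony,year,n_nests,n_with_eggs,n_hatched,n_fledged

All timestamps are UTC everywhere; coordinates are decimal degrees WGS84 with
longitudes normalized to (-180, 180]. Isopleth regions are exported as RFC
7946 GeoJSON with polygons split at the antimeridian.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging

import numpy as np
import pandas as pd
from shapely.geometry import box as _box
from shapely.geometry import mapping as _mapping
from shapely.ops import unary_union

from .space_use import IsoplethUD, unproject_points
from .trajectories import wrap_lon

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["bird_id", "colony", "timestamp_utc", "lat", "lon"]
IMMERSION_COLUMNS = ["bird_id", "block_start_utc", "wet_count", "n_samples"]
NEST_COLUMNS = ["colony", "year", "n_nests", "n_with_eggs", "n_hatched", "n_fledged"]


class SchemaError(ValueError):
    """Raised when an input file violates its declared schema."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_tracks(path) -> pd.DataFrame:
    """Read and validate a track CSV into the in-memory track schema
    (bird_id, colony, timestamp, lat, lon), sorted per bird by time.

    Latitude outside [-90, 90] and duplicate (bird, timestamp) rows are
    rejected with the offending CSV line number; 0–360 longitudes are
    normalized to (-180, 180].
    """
    df = pd.read_csv(path)
    _require_columns(df, TRACK_COLUMNS, path)
    if len(df) == 0:
        return pd.DataFrame(columns=["bird_id", "colony", "timestamp", "lat", "lon"])
    ts = pd.to_datetime(df["timestamp_utc"], utc=True, errors="coerce")
    for name, bad in (
        ("timestamp", ts.isna()),
        ("latitude", (df["lat"] < -90) | (df["lat"] > 90) | df["lat"].isna()),
        ("longitude", (df["lon"] < -360) | (df["lon"] > 360) | df["lon"].isna()),
    ):
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise SchemaError(f"{path}: malformed {name} at line {line}")
    dup = df.duplicated(subset=["bird_id", "timestamp_utc"])
    if dup.any():
        raise SchemaError(f"{path}: duplicate (bird_id, timestamp) at line {int(dup.idxmax()) + 2}")
    out = pd.DataFrame(
        {
            "bird_id": df["bird_id"].astype(str),
            "colony": df["colony"].astype(str),
            "timestamp": ts,
            "lat": df["lat"].astype(float),
            "lon": wrap_lon(df["lon"].astype(float)),
        }
    )
    return out.sort_values(["bird_id", "timestamp"]).reset_index(drop=True)


def write_tracks(tracks: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "bird_id": tracks["bird_id"],
            "colony": tracks["colony"],
            "timestamp_utc": pd.to_datetime(tracks["timestamp"], utc=True).dt.strftime(
                "%Y-%m-%dT%H:%M:%SZ"
            ),
            "lat": tracks["lat"].map(lambda v: f"{v:.6f}"),
            "lon": tracks["lon"].map(lambda v: f"{v:.6f}"),
        }
    )
    out.to_csv(path, index=False)


def read_immersion(path, block_minutes: int = 5) -> pd.DataFrame:
    """Read and validate an immersion CSV into (bird_id, block_start,
    wet_count, n_samples); gaps in each bird's block series are logged."""
    df = pd.read_csv(path)
    _require_columns(df, IMMERSION_COLUMNS, path)
    if len(df) == 0:
        return pd.DataFrame(columns=["bird_id", "block_start", "wet_count", "n_samples"])
    ts = pd.to_datetime(df["block_start_utc"], utc=True, errors="coerce")
    if ts.isna().any():
        raise SchemaError(f"{path}: malformed timestamp at line {int(ts.isna().idxmax()) + 2}")
    bad = (df["wet_count"] < 0) | (df["wet_count"] > df["n_samples"])
    if bad.any():
        raise SchemaError(f"{path}: wet_count outside [0, n_samples] at line {int(bad.idxmax()) + 2}")
    out = pd.DataFrame(
        {
            "bird_id": df["bird_id"].astype(str),
            "block_start": ts,
            "wet_count": df["wet_count"].astype(int),
            "n_samples": df["n_samples"].astype(int),
        }
    ).sort_values(["bird_id", "block_start"]).reset_index(drop=True)
    step = pd.Timedelta(minutes=block_minutes)
    for bird, grp in out.groupby("bird_id"):
        gaps = grp["block_start"].diff()
        big = gaps[gaps > step]
        for idx, gap in big.items():
            logger.warning(
                "%s: gap of %s before block %s", bird, gap, grp.loc[idx, "block_start"]
            )
    return out


def write_immersion(blocks: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "bird_id": blocks["bird_id"],
            "block_start_utc": pd.to_datetime(blocks["block_start"], utc=True).dt.strftime(
                "%Y-%m-%dT%H:%M:%SZ"
            ),
            "wet_count": blocks["wet_count"],
            "n_samples": blocks["n_samples"],
        }
    )
    out.to_csv(path, index=False)


def read_nests(path) -> pd.DataFrame:
    """Read nest-monitoring counts; stage counts must be monotone
    non-increasing within each row."""
    df = pd.read_csv(path)
    _require_columns(df, NEST_COLUMNS, path)
    bad = ~(
        (df["n_nests"] >= df["n_with_eggs"])
        & (df["n_with_eggs"] >= df["n_hatched"])
        & (df["n_hatched"] >= df["n_fledged"])
        & (df["n_fledged"] >= 0)
    )
    if bad.any():
        raise SchemaError(f"{path}: non-monotone nest counts at line {int(bad.idxmax()) + 2}")
    return df


# ---------------------------------------------------------------------------
# GeoJSON isopleth export


def _split_antimeridian(poly, lon_center: float):
    """Split a polygon built in an unwrapped longitude frame (continuous
    around ``lon_center``) at the ±180° meridians, per RFC 7946."""
    parts = []
    for lo, hi, shift in ((-540.0, -180.0, 360.0), (-180.0, 180.0, 0.0), (180.0, 540.0, -360.0)):
        clipped = poly.intersection(_box(lo, -90.0, hi, 90.0))
        if clipped.is_empty:
            continue
        geoms = getattr(clipped, "geoms", [clipped])
        for g in geoms:
            if g.area <= 0:
                continue
            xs, ys = np.asarray(g.exterior.coords).T
            parts.append(list(zip((xs + shift).round(6), ys.round(6))))
    return parts


def isopleth_to_geojson_features(iso: IsoplethUD, properties: dict | None = None) -> list[dict]:
    """GeoJSON polygon features (WGS84) outlining an isopleth's cell mask.

    Cell rectangles are unioned in the projected plane, unprojected vertex by
    vertex, and split at the antimeridian.
    """
    ud = iso.parent
    half = ud.cell_size_km / 2.0
    boxes = [
        _box(ud.x[j] - half, ud.y[i] - half, ud.x[j] + half, ud.y[i] + half)
        for i, j in zip(*np.nonzero(iso.mask))
    ]
    if not boxes:
        return []
    merged = unary_union(boxes)
    geoms = getattr(merged, "geoms", [merged])
    lon_c = ud.center[1]
    features = []
    for geom in geoms:
        xs, ys = np.asarray(geom.exterior.coords).T
        lat, lon = unproject_points(xs, ys, ud.center)
        # unwrap around the projection center so rings are continuous
        lon_unwrapped = lon_c + (np.asarray(lon) - lon_c + 180.0) % 360.0 - 180.0
        from shapely.geometry import Polygon

        ring = Polygon(zip(lon_unwrapped, lat))
        for part in _split_antimeridian(ring, lon_c):
            features.append(
                {
                    "type": "Feature",
                    "properties": {"level": iso.level, **(properties or {})},
                    "geometry": {"type": "Polygon", "coordinates": [part]},
                }
            )
    return features


def write_isopleth_geojson(isopleths: list[tuple[IsoplethUD, dict]], path) -> None:
    features = []
    for iso, props in isopleths:
        features.extend(isopleth_to_geojson_features(iso, props))
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (_dt.date, _dt.datetime)):
            return o.isoformat()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=default)
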