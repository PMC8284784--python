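"""NOAA solar-geometry sunrise/sunset computation.

Implements the standard NOAA solar position equations (fractional-year
Fourier expansions for the equation of time and solar declination, hour-angle
solution at zenith 90.833° — the conventional sunrise/sunset zenith including
refraction and the solar disc). Accuracy is a few minutes, far inside the
5-minute block resolution of the immersion data that consumes it.

At high latitudes a day may have no sunrise/sunset; those days carry an
explicit polar-day or polar-night flag rather than event times.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

SUNRISE_SUNSET_ZENITH_DEG = 90.833


@dataclass(frozen=True)
class SolarEvents:
    """Sunrise/sunset (UTC) for one position and calendar date.

    ``polar`` is None on ordinary days, "day" under midnight sun (sun never
    sets; no events) and "night" during polar night (sun never rises). Event
    times may fall outside the calendar date's 00:00–24:00 UTC range at
    longitudes far from Greenwich; they always satisfy sunrise < sunset.
    """

    date: _dt.date
    sunrise: _dt.datetime | None
    sunset: _dt.datetime | None
    polar: str | None = None


def _solar_terms(date: _dt.date):
    doy = date.timetuple().tm_yday
    year_len = 366.0 if date.year % 4 == 0 and (date.year % 100 != 0 or date.year % 400 == 0) else 365.0
    gamma = 2.0 * np.pi / year_len * (doy - 1 + 0.5)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )
    return eqtime, decl


def solar_events(lat: float, lon: float, date: _dt.date) -> SolarEvents:
    """Sunrise and sunset (UTC datetimes) at a position on a calendar date."""
    if not (-90.0 <= lat <= 90.0):
        raise ValueError("latitude outside [-90, 90]")
    eqtime, decl = _solar_terms(date)
    phi = np.radians(lat)
    zen = np.radians(SUNRISE_SUNSET_ZENITH_DEG)
    cos_ha = (np.cos(zen) - np.sin(phi) * np.sin(decl)) / (np.cos(phi) * np.cos(decl))
    if cos_ha > 1.0:
        return SolarEvents(date=date, sunrise=None, sunset=None, polar="night")
    if cos_ha < -1.0:
        return SolarEvents(date=date, sunrise=None, sunset=None, polar="day")
    ha_deg = np.degrees(np.arccos(cos_ha))
    # minutes past 00:00 UTC; deliberately NOT wrapped into [0, 1440) so that
    # sunrise < sunset always holds (events can spill into adjacent UTC days
    # at longitudes near the antimeridian)
    sunrise_min = 720.0 - 4.0 * (lon + ha_deg) - eqtime
    sunset_min = 720.0 - 4.0 * (lon - ha_deg) - eqtime
    midnight = _dt.datetime.combine(date, _dt.time(), tzinfo=_dt.timezone.utc)
    return SolarEvents(
        date=date,
        sunrise=midnight + _dt.timedelta(minutes=float(sunrise_min)),
        sunset=midnight + _dt.timedelta(minutes=float(sunset_min)),
        polar=None,
    )


def day_length_hours(events: SolarEvents) -> float:
    if events.polar == "day":
        return 24.0
    if events.polar == "night":
        return 0.0
    return (events.sunset - events.sunrise).total_seconds() / 3600.0
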