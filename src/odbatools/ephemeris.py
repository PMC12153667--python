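"""Solar events, noon-to-noon nights, and night-window weather summaries.

For a nocturnal animal the natural analysis unit is the *night*: the 24 h
running from local noon to the following local noon, so that a single
activity period is never split across records.  Within each night the
sunset-to-sunrise interval defines which weather hours the animal could
plausibly have experienced above ground; night-level covariates are the
means (rainfall: the sum) of hourly values over that interval.

Sunset/sunrise come from the standard NOAA solar-position equations
(fractional-year form of the equation of time and solar declination),
accurate to a few minutes at temperate latitudes — well within the +/-5 min
contract this module advertises.  Polar latitudes (|lat| > 66.5 deg), where
sunset may not exist, are rejected rather than approximated.

All timestamps are treated as local clock time at a single fixed UTC offset
(``tz_offset_hours``); deployments of a week or two inside one season never
straddle a daylight-saving change, so no DST arithmetic is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .weather import WEATHER_COVARIATES, WeatherSeries

__all__ = ["NightWindow", "solar_events", "build_night_windows", "assign_nights", "night_weather_average"]

_ZENITH_DEG = 90.833  # official sunrise/sunset: solar center 50 arcmin below horizon


@dataclass(frozen=True)
class NightWindow:
    """One noon-to-noon night with its sunset and sunrise."""

    night_id: Date          # calendar date of the starting noon
    start: pd.Timestamp     # local noon
    end: pd.Timestamp       # next local noon
    sunset: pd.Timestamp
    sunrise: pd.Timestamp

    def __post_init__(self):
        if not (self.start < self.sunset < self.sunrise < self.end):
            raise ValueError("night window ordering violated: need start < sunset < sunrise < end")


def _fractional_year(day_of_year: int, hour: float = 12.0) -> float:
    return 2.0 * math.pi / 365.0 * (day_of_year - 1 + (hour - 12.0) / 24.0)

def _equation_of_time_min(gamma: float) -> float:
    return 229.18 * (
        0.000075
        + 0.001868 * math.cos(gamma)
        - 0.032077 * math.sin(gamma)
        - 0.014615 * math.cos(2 * gamma)
        - 0.040849 * math.sin(2 * gamma)
    )

def _solar_declination_rad(gamma: float) -> float:
    return (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )


def _event_minutes_utc(latitude: float, longitude: float, day: Date, rising: bool) -> float:
    """Minutes after 00:00 UTC of sunrise (rising) or sunset on ``day``."""
    gamma = _fractional_year(day.timetuple().tm_yday)
    eqtime = _equation_of_time_min(gamma)
    decl = _solar_declination_rad(gamma)
    lat = math.radians(latitude)
    cos_ha = (
        math.cos(math.radians(_ZENITH_DEG)) / (math.cos(lat) * math.cos(decl))
        - math.tan(lat) * math.tan(decl)
    )
    if not -1.0 < cos_ha < 1.0:
        raise ValueError("sun does not rise/set on this date at this latitude")
    ha_deg = math.degrees(math.acos(cos_ha))
    if not rising:
        ha_deg = -ha_deg
    return 720.0 - 4.0 * (longitude + ha_deg) - eqtime


def solar_events(
    latitude: float,
    longitude: float,
    date: Date | str,
    tz_offset_hours: float = 0.0,
) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Sunset on ``date`` and sunrise of the following morning, local time.

    Longitude is positive east.  Raises for |latitude| > 66.5 deg, where
    polar day/night would need special handling.
    """
    if abs(latitude) > 66.5:
        raise ValueError("polar latitudes (|lat| > 66.5 deg) are not supported")
    day = pd.Timestamp(date).date()
    next_day = (pd.Timestamp(day) + pd.Timedelta(days=1)).date()
    sunset_min = _event_minutes_utc(latitude, longitude, day, rising=False)
    sunrise_min = _event_minutes_utc(latitude, longitude, next_day, rising=True)
    offset = pd.Timedelta(hours=tz_offset_hours)
    sunset = pd.Timestamp(day) + pd.Timedelta(minutes=sunset_min) + offset
    sunrise = pd.Timestamp(next_day) + pd.Timedelta(minutes=sunrise_min) + offset
    return sunset, sunrise


def build_night_windows(
    latitude: float,
    longitude: float,
    start_date: Date | str,
    n_nights: int,
    tz_offset_hours: float = 0.0,
) -> list[NightWindow]:
    """Consecutive noon-to-noon nights starting at noon of ``start_date``."""
    if n_nights < 1:
        raise ValueError("n_nights must be >= 1")
    windows = []
    d0 = pd.Timestamp(start_date).normalize()
    for k in range(n_nights):
        day = d0 + pd.Timedelta(days=k)
        sunset, sunrise = solar_events(latitude, longitude, day.date(), tz_offset_hours)
        windows.append(
            NightWindow(
                night_id=day.date(),
                start=day + pd.Timedelta(hours=12),
                end=day + pd.Timedelta(hours=36),
                sunset=sunset,
                sunrise=sunrise,
            )
        )
    return windows


def assign_nights(timestamps: pd.Series | pd.DatetimeIndex) -> pd.Series:
    """Map each timestamp to its night_id (date of the noon starting it).

    Every instant belongs to exactly one noon-to-noon window, so this is a
    partition of the timeline.
    """
    ts = pd.Series(pd.to_datetime(np.asarray(timestamps)))
    return (ts - pd.Timedelta(hours=12)).dt.date


def night_weather_average(weather: WeatherSeries, window: NightWindow) -> dict:
    """Night-level covariates: hourly means (rainfall summed) over [sunset, sunrise).

    An hour belongs to the night when its hour-start falls in the half-open
    sunset-to-sunrise interval.  If any expected hour is missing from the
    series the record is flagged ``incomplete``.
    """
    f = weather.frame
    sel = f[(f["hour_start"] >= window.sunset) & (f["hour_start"] < window.sunrise)]
    expected = pd.date_range(window.sunset.ceil("h"), window.sunrise, freq="h", inclusive="left")
    record: dict = {"night_id": window.night_id, "n_hours": int(len(sel)),
                    "incomplete": len(sel) < len(expected)}
    for name in WEATHER_COVARIATES:
        if len(sel) == 0:
            record[name] = np.nan
        elif name == "Rain":
            record[name] = float(sel[name].sum())
        else:
            record[name] = float(sel[name].mean())
    return record
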