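"""Sunrise/sunset computation and the twilight/day/night partition of the diel cycle.

The diel cycle is partitioned into three periods anchored to the sun rather than
the clock: *twilight* is the hour before and after both sunrise and sunset
(4 h in total), *day* runs from one hour after sunrise to one hour before
sunset, and *night* from one hour after sunset to one hour before the next
sunrise.  Sunrise and sunset are computed with the NOAA solar-position
algorithm (Julian-century ephemeris for declination and the equation of
time, re-evaluated at the event time) at the official zenith of 90.833 deg,
i.e. refraction-corrected upper-limb rise/set.  Times are reported in local
civil time for a fixed UTC offset; daylight-saving shifts are not modelled.

Seasons follow calendar quarters: winter = January--March, spring =
April--June, summer = July--September, autumn = October--December.
"""

from __future__ import annotations

import csv
import datetime as dt
import math
from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "SolarDay",
    "DielPeriods",
    "SolarCalendar",
    "solar_times",
    "diel_period_of",
    "season_of",
    "mean_day_length",
    "SEASONS",
    "PERIODS",
]

SEASONS = ("winter", "spring", "summer", "autumn")
PERIODS = ("twilight", "day", "night")

#: official zenith: 90 deg 50' -- geometric horizon plus standard refraction
#: and the solar semi-diameter
OFFICIAL_ZENITH_DEG = 90.833

#: latitudes beyond this may have dates with no sunrise/sunset at the
#: official zenith; the partition below is undefined there
MAX_SUPPORTED_LATITUDE = 66.0

_TWILIGHT_HALF_WIDTH = dt.timedelta(hours=1)


class PolarLatitudeError(ValueError):
    """Raised for sites where the sun may not rise or set on some dates."""


@dataclass(frozen=True)
class SolarDay:
    """Sunrise, sunset and day length for one civil date at one site."""

    date: dt.date
    sunrise: dt.datetime  # local civil time
    sunset: dt.datetime
    day_length: float  # minutes, sunset - sunrise

    def __post_init__(self) -> None:
        if self.sunrise >= self.sunset:
            raise ValueError(f"sunrise must precede sunset on {self.date}")
        if not 0.0 < self.day_length < 1440.0:
            raise ValueError(f"day length {self.day_length} min out of range on {self.date}")


@dataclass(frozen=True)
class DielPeriods:
    """The twilight/day/night partition of one civil date (midnight to midnight).

    ``hours`` gives the duration of each period *within the civil date*; the
    three always sum to 24 h with twilight exactly 4 h (the twilight windows
    at this package's supported latitudes never cross midnight).
    """

    date: dt.date
    twilight_intervals: tuple[tuple[dt.datetime, dt.datetime], ...]
    day_interval: tuple[dt.datetime, dt.datetime]
    hours: dict[str, float]


def _ephemeris(date: dt.date, minutes_local: float, utc_offset: float) -> tuple[float, float]:
    """Solar declination (degrees) and equation of time (minutes) at an instant.

    NOAA solar-calculator formulation: Julian centuries from J2000, mean
    solar elements with the equation of center, apparent longitude corrected
    for nutation, and the obliquity-based equation of time.  Accurate to a
    few seconds of time over the twentieth/twenty-first centuries, which
    keeps computed rise/set within ~1 minute of almanac values.
    """
    jd = (date.toordinal() + 1721424.5) + minutes_local / 1440.0 - utc_offset / 24.0
    T = (jd - 2451545.0) / 36525.0
    L0 = (280.46646 + T * (36000.76983 + 0.0003032 * T)) % 360.0
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    m_r = math.radians(M)
    center = (
        math.sin(m_r) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + math.sin(2 * m_r) * (0.019993 - 0.000101 * T)
        + math.sin(3 * m_r) * 0.000289
    )
    true_long = L0 + center
    omega = math.radians(125.04 - 1934.136 * T)
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    eps = math.radians(eps0 + 0.00256 * math.cos(omega))
    decl = math.degrees(math.asin(math.sin(eps) * math.sin(math.radians(app_long))))
    y = math.tan(eps / 2.0) ** 2
    l0_r = math.radians(L0)
    eqtime = 4.0 * math.degrees(
        y * math.sin(2 * l0_r)
        - 2.0 * e * math.sin(m_r)
        + 4.0 * e * y * math.sin(m_r) * math.cos(2 * l0_r)
        - 0.5 * y * y * math.sin(4 * l0_r)
        - 1.25 * e * e * math.sin(2 * m_r)
    )
    return decl, eqtime


def _hour_angle_deg(latitude: float, decl_deg: float) -> float:
    lat_r, decl_r = math.radians(latitude), math.radians(decl_deg)
    cos_ha = math.cos(math.radians(OFFICIAL_ZENITH_DEG)) / (
        math.cos(lat_r) * math.cos(decl_r)
    ) - math.tan(lat_r) * math.tan(decl_r)
    # |latitude| < 66 guarantees |cos_ha| < 1 at this zenith
    return math.degrees(math.acos(cos_ha))


def solar_times(
    date: dt.date,
    latitude: float,
    longitude: float,
    utc_offset: float,
) -> SolarDay:
    """Sunrise and sunset on ``date`` at a site, in local civil time.

    Parameters
    ----------
    date : datetime.date
    latitude, longitude : float
        Degrees; north and east positive.
    utc_offset : float
        Hours ahead of UTC of the local civil clock (no DST).

    Raises
    ------
    PolarLatitudeError
        If ``abs(latitude) >= 66`` deg, where the sun may not cross the
        official zenith on every date.
    """
    if abs(latitude) >= MAX_SUPPORTED_LATITUDE:
        raise PolarLatitudeError(
            f"latitude {latitude} deg unsupported: polar day/night possible above "
            f"{MAX_SUPPORTED_LATITUDE} deg"
        )
    # first pass at local solar noon, then refine the ephemeris at the
    # event times themselves (declination moves ~0.4 deg/day near equinox,
    # worth ~2 min of rise/set time)
    decl, eqtime = _ephemeris(date, 720.0, utc_offset)
    ha = _hour_angle_deg(latitude, decl)
    noon = 720.0 - 4.0 * longitude - eqtime + utc_offset * 60.0
    sunrise_min, sunset_min = noon - 4.0 * ha, noon + 4.0 * ha
    for _ in range(2):
        d1, e1 = _ephemeris(date, sunrise_min, utc_offset)
        d2, e2 = _ephemeris(date, sunset_min, utc_offset)
        sunrise_min = (720.0 - 4.0 * longitude - e1 + utc_offset * 60.0
                       - 4.0 * _hour_angle_deg(latitude, d1))
        sunset_min = (720.0 - 4.0 * longitude - e2 + utc_offset * 60.0
                      + 4.0 * _hour_angle_deg(latitude, d2))
    midnight = dt.datetime.combine(date, dt.time())
    sunrise = midnight + dt.timedelta(minutes=sunrise_min)
    sunset = midnight + dt.timedelta(minutes=sunset_min)
    return SolarDay(date=date, sunrise=sunrise, sunset=sunset,
                    day_length=(sunset - sunrise).total_seconds() / 60.0)


def season_of(date: dt.date) -> str:
    """Season by calendar month: Jan-Mar winter, Apr-Jun spring, Jul-Sep summer, Oct-Dec autumn."""
    return SEASONS[(date.month - 1) // 3]


class SolarCalendar:
    """Per-date solar table for one site, with period assignment and durations.

    A calendar computes (and caches) one :class:`SolarDay` per civil date.
    Published sunrise/sunset tables can be injected bit-exactly from a CSV
    with columns ``date, sunrise, sunset`` (ISO times, local civil clock),
    overriding the ephemeris for the listed dates.
    """

    def __init__(self, latitude: float, longitude: float, utc_offset: float,
                 override_csv: str | None = None) -> None:
        if abs(latitude) >= MAX_SUPPORTED_LATITUDE:
            raise PolarLatitudeError(
                f"latitude {latitude} deg unsupported above {MAX_SUPPORTED_LATITUDE} deg"
            )
        self.latitude = latitude
        self.longitude = longitude
        self.utc_offset = utc_offset
        self._cache: dict[dt.date, SolarDay] = {}
        if override_csv is not None:
            self._load_override(override_csv)

    def _load_override(self, path: str) -> None:
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                date = dt.date.fromisoformat(row["date"].strip())
                sunrise = dt.datetime.combine(date, dt.time.fromisoformat(row["sunrise"].strip()))
                sunset = dt.datetime.combine(date, dt.time.fromisoformat(row["sunset"].strip()))
                self._cache[date] = SolarDay(
                    date=date, sunrise=sunrise, sunset=sunset,
                    day_length=(sunset - sunrise).total_seconds() / 60.0,
                )

    def solar_day(self, date: dt.date) -> SolarDay:
        day = self._cache.get(date)
        if day is None:
            day = solar_times(date, self.latitude, self.longitude, self.utc_offset)
            self._cache[date] = day
        return day

    def twilight_windows(self, date: dt.date) -> tuple[tuple[dt.datetime, dt.datetime], ...]:
        """The two closed twilight windows anchored to this date's sunrise and sunset."""
        sd = self.solar_day(date)
        return (
            (sd.sunrise - _TWILIGHT_HALF_WIDTH, sd.sunrise + _TWILIGHT_HALF_WIDTH),
            (sd.sunset - _TWILIGHT_HALF_WIDTH, sd.sunset + _TWILIGHT_HALF_WIDTH),
        )

    def diel_periods(self, date: dt.date) -> DielPeriods:
        """Partition of the civil date ``date`` (midnight to midnight).

        Day runs (sunrise+1h, sunset-1h); twilight windows are closed; night
        is the open remainder, split across midnight and accounted against
        whichever civil date each piece falls in.  Durations are exact
        interval measures clipped to the civil date (twilight windows of the
        neighbouring dates are consulted in case one crosses midnight), so
        twilight + day + night = 24 h always and twilight = 4 h whenever both
        windows fall inside the date -- which they do at mid latitudes.
        """
        sd = self.solar_day(date)
        tw = self.twilight_windows(date)
        day_start = dt.datetime.combine(date, dt.time())
        day_end = day_start + dt.timedelta(days=1)
        clipped: list[tuple[dt.datetime, dt.datetime]] = []
        for nb in (date - dt.timedelta(days=1), date, date + dt.timedelta(days=1)):
            for lo, hi in self.twilight_windows(nb):
                lo, hi = max(lo, day_start), min(hi, day_end)
                if lo < hi:
                    clipped.append((lo, hi))
        clipped.sort()
        # union measure (windows are disjoint at supported latitudes, but be exact)
        twilight_s = 0.0
        cur_end = day_start
        for lo, hi in clipped:
            lo = max(lo, cur_end)
            if lo < hi:
                twilight_s += (hi - lo).total_seconds()
                cur_end = hi
        twilight_h = twilight_s / 3600.0
        day_iv = (sd.sunrise + _TWILIGHT_HALF_WIDTH, sd.sunset - _TWILIGHT_HALF_WIDTH)
        day_h = max((min(day_iv[1], day_end) - max(day_iv[0], day_start)).total_seconds(), 0.0) / 3600.0
        night_h = 24.0 - twilight_h - day_h
        return DielPeriods(
            date=date,
            twilight_intervals=tw,
            day_interval=day_iv,
            hours={"twilight": twilight_h, "day": day_h, "night": night_h},
        )

    def period_of(self, timestamp: dt.datetime) -> str:
        """Diel period containing ``timestamp``.

        Twilight windows are closed at both ends; between them day and night
        take the open remainder.  Because night spans midnight, the windows of
        the previous and next civil dates are consulted as well (the hour
        before a post-midnight sunrise belongs to the previous night, the
        window around a pre-midnight sunset can spill past midnight at other
        sites).
        """
        for date in (timestamp.date() - dt.timedelta(days=1),
                     timestamp.date(),
                     timestamp.date() + dt.timedelta(days=1)):
            for lo, hi in self.twilight_windows(date):
                if lo <= timestamp <= hi:
                    return "twilight"
        sd = self.solar_day(timestamp.date())
        if sd.sunrise + _TWILIGHT_HALF_WIDTH < timestamp < sd.sunset - _TWILIGHT_HALF_WIDTH:
            return "day"
        return "night"


def diel_period_of(timestamp: dt.datetime, calendar: SolarCalendar) -> str:
    """Functional form of :meth:`SolarCalendar.period_of`."""
    return calendar.period_of(timestamp)


def mean_day_length(dates: Iterable[dt.date], calendar: SolarCalendar) -> float:
    """Arithmetic mean day length over ``dates``, in minutes.

    Raises ``ValueError`` on an empty range.
    """
    lengths = [calendar.solar_day(d).day_length for d in dates]
    if not lengths:
        raise ValueError("mean_day_length requires a non-empty date range")
    return sum(lengths) / len(lengths)


def date_range(start: dt.date, end: dt.date) -> list[dt.date]:
    """All dates from ``start`` to ``end`` inclusive."""
    if end < start:
        raise ValueError("end date precedes start date")
    return [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]
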