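"""Sunrise/sunset from NOAA solar geometry.

Implements the NOAA solar-calculator equations (Meeus-derived) for local
sunrise and sunset at a fixed UTC offset.  The study site is the
Bakgalagadi Schwelle in the south-western Kalahari; the default centroid
is S 24.35°, E 20.62° with clocks at UTC+2 (Botswana, no DST).

Accuracy is a few minutes near the tropics, which is ample for deciding
whether an hourly logger record falls in daylight.
"""

from __future__ import annotations

import datetime as dt
import math

__all__ = ["daylight_window", "daylight_hours", "STUDY_LAT", "STUDY_LON", "UTC_OFFSET_HOURS"]

# Study-area centroid (decimal degrees, south/east sign convention: S negative)
STUDY_LAT = -24.35
STUDY_LON = 20.62
UTC_OFFSET_HOURS = 2.0

# Standard refraction-corrected zenith for rise/set
_ZENITH_DEG = 90.833


def _julian_day(date: dt.date) -> float:
    y, m, d = date.year, date.month, date.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def _solar_params(jc: float) -> tuple[float, float]:
    """Return (equation of time [min], solar declination [deg]) at Julian century jc."""
    gml = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    gma = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    ctr = (
        math.sin(math.radians(gma)) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(math.radians(2 * gma)) * (0.019993 - 0.000101 * jc)
        + math.sin(math.radians(3 * gma)) * 0.000289
    )
    true_long = gml + ctr
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(125.04 - 1934.136 * jc))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(math.radians(125.04 - 1934.136 * jc))
    decl = math.degrees(
        math.asin(math.sin(math.radians(obliq)) * math.sin(math.radians(app_long)))
    )
    var_y = math.tan(math.radians(obliq / 2.0)) ** 2
    eot = 4.0 * math.degrees(
        var_y * math.sin(2.0 * math.radians(gml))
        - 2.0 * ecc * math.sin(math.radians(gma))
        + 4.0 * ecc * var_y * math.sin(math.radians(gma)) * math.cos(2.0 * math.radians(gml))
        - 0.5 * var_y * var_y * math.sin(4.0 * math.radians(gml))
        - 1.25 * ecc * ecc * math.sin(2.0 * math.radians(gma))
    )
    return eot, decl


def daylight_window(
    date: dt.date,
    latitude: float = STUDY_LAT,
    longitude: float = STUDY_LON,
    utc_offset_hours: float = UTC_OFFSET_HOURS,
) -> tuple[dt.datetime, dt.datetime]:
    """Local (sunrise, sunset) naive datetimes for ``date`` at the given site.

    Raises ``ValueError`` for polar latitudes (|lat| >= 66.5°) where the sun
    may not rise or set.
    """
    if abs(latitude) >= 66.5:
        raise ValueError("polar latitudes are unsupported (no guaranteed sunrise/sunset)")

    jd = _julian_day(date) + 0.5 - utc_offset_hours / 24.0  # local noon-ish UTC
    jc = (jd - 2451545.0) / 36525.0
    eot, decl = _solar_params(jc)

    lat_r = math.radians(latitude)
    decl_r = math.radians(decl)
    cos_ha = (
        math.cos(math.radians(_ZENITH_DEG)) / (math.cos(lat_r) * math.cos(decl_r))
        - math.tan(lat_r) * math.tan(decl_r)
    )
    if not -1.0 <= cos_ha <= 1.0:  # pragma: no cover - excluded by latitude guard
        raise ValueError(f"sun does not rise/set on {date} at latitude {latitude}")
    ha_deg = math.degrees(math.acos(cos_ha))

    # Local solar noon in local-clock minutes
    noon_min = 720.0 - 4.0 * longitude - eot + utc_offset_hours * 60.0
    rise_min = noon_min - 4.0 * ha_deg
    set_min = noon_min + 4.0 * ha_deg

    midnight = dt.datetime.combine(date, dt.time())
    return (
        midnight + dt.timedelta(minutes=rise_min),
        midnight + dt.timedelta(minutes=set_min),
    )


def daylight_hours(
    date: dt.date,
    latitude: float = STUDY_LAT,
    longitude: float = STUDY_LON,
    utc_offset_hours: float = UTC_OFFSET_HOURS,
) -> float:
    """Daylight duration in hours (sunset minus sunrise)."""
    rise, sset = daylight_window(date, latitude, longitude, utc_offset_hours)
    return (sset - rise).total_seconds() / 3600.0
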