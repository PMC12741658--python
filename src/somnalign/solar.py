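"""Sunrise-to-sunset day length from a NOAA-style solar position algorithm.

Day length enters the agreement models as the seasonal covariate: at high
latitudes (the default coordinates are Helsinki, 60.17 N) daylight swings
from under 6 h at the December solstice to almost 19 h in June, and sleep
timing tracks it.  The routine below follows the NOAA solar calculator
chain (Julian century -> solar geometry -> declination -> sunrise hour
angle) and is accurate to well under a minute at temperate latitudes.
"""

from __future__ import annotations

import datetime as dt
import math

__all__ = ["day_length", "solar_declination"]

#: Solar zenith at sunrise/sunset including refraction and solar radius.
_SUNRISE_ZENITH_DEG = 90.833


def _julian_day(date: dt.date) -> float:
    """Julian day number at 12:00 UT for a calendar date."""
    y, m, d = date.year, date.month, date.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5 + 0.5


def solar_declination(date: dt.date, longitude: float = 0.0) -> float:
    """Apparent solar declination in degrees, evaluated near local solar noon.

    The longitude only nudges the evaluation instant (solar noon shifts by
    4 min per degree); its effect on day length is far below a minute.
    """
    # Fraction of day to local solar noon in UT.
    noon_frac = 0.5 - longitude / 360.0
    t = (_julian_day(date) + noon_frac - 0.5 - 2451545.0) / 36525.0

    geom_mean_long = (280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360.0
    geom_mean_anom = 357.52911 + t * (35999.05029 - 0.0001537 * t)

    eq_center = (
        math.sin(math.radians(geom_mean_anom)) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + math.sin(math.radians(2 * geom_mean_anom)) * (0.019993 - 0.000101 * t)
        + math.sin(math.radians(3 * geom_mean_anom)) * 0.000289
    )
    true_long = geom_mean_long + eq_center
    apparent_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(125.04 - 1934.136 * t))

    mean_obliq = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    obliq_corr = mean_obliq + 0.00256 * math.cos(math.radians(125.04 - 1934.136 * t))

    decl = math.degrees(
        math.asin(math.sin(math.radians(obliq_corr)) * math.sin(math.radians(apparent_long)))
    )
    return decl


def day_length(date: dt.date, latitude: float = 60.17, longitude: float = 24.94) -> float:
    """Sunrise-to-sunset duration in minutes for ``date`` at the given site.

    Polar day and polar night clamp to 1440 and 0 respectively.

    Parameters
    ----------
    date:
        Calendar date (the civil date at the site).
    latitude, longitude:
        Site coordinates in degrees; default Helsinki (60.17 N, 24.94 E).
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude out of range: {latitude}")
    decl = solar_declination(date, longitude)
    lat_r = math.radians(latitude)
    decl_r = math.radians(decl)
    cos_ha = (
        math.cos(math.radians(_SUNRISE_ZENITH_DEG)) - math.sin(lat_r) * math.sin(decl_r)
    ) / (math.cos(lat_r) * math.cos(decl_r))
    if cos_ha >= 1.0:
        return 0.0  # polar night
    if cos_ha <= -1.0:
        return 1440.0  # polar day
    ha_deg = math.degrees(math.acos(cos_ha))
    # Hour angle sweeps 15 deg/h; sunrise-to-sunset spans 2*ha -> 8*ha minutes.
    return 8.0 * ha_deg
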