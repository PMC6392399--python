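"""Sunrise/sunset from the NOAA solar position algorithm.

Legal waterfowl shooting time brackets the day by civil sunrise/sunset; the
NOAA general solar calculations reproduce published shooting-time tables to
within about a minute at mid latitudes, which is far finer than the 30-min
margins applied around them.
"""

from __future__ import annotations

import math
from datetime import date, datetime, timedelta, timezone

_ZENITH_OFFICIAL = 90.833  # degrees: sun center at -50 arcmin (refraction + radius)


def _julian_day(d: date) -> float:
    y, m = d.year, d.month
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d.day + b - 1524.5


def _solar_quantities(jc: float) -> tuple[float, float]:
    """(equation of time [min], solar declination [deg]) at Julian century jc."""
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
    mean_obliq = 23 + (26 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60) / 60
    obliq = mean_obliq + 0.00256 * math.cos(math.radians(125.04 - 1934.136 * jc))
    decl = math.degrees(math.asin(math.sin(math.radians(obliq)) * math.sin(math.radians(app_long))))
    var_y = math.tan(math.radians(obliq / 2)) ** 2
    eot = 4 * math.degrees(
        var_y * math.sin(2 * math.radians(gml))
        - 2 * ecc * math.sin(math.radians(gma))
        + 4 * ecc * var_y * math.sin(math.radians(gma)) * math.cos(2 * math.radians(gml))
        - 0.5 * var_y**2 * math.sin(4 * math.radians(gml))
        - 1.25 * ecc**2 * math.sin(2 * math.radians(gma))
    )
    return eot, decl


def sunrise_sunset(d: date, lat: float, lon: float) -> tuple[datetime, datetime]:
    """Official sunrise and sunset (UTC) for a date at lat/lon in degrees.

    Raises ValueError under polar day/night (the sun never crosses the
    official zenith), which cannot occur at mid-latitude study areas.
    """
    jd = _julian_day(d)
    jc = (jd - 2451545.0) / 36525.0
    eot, decl = _solar_quantities(jc)
    cos_ha = (
        math.cos(math.radians(_ZENITH_OFFICIAL))
        / (math.cos(math.radians(lat)) * math.cos(math.radians(decl)))
        - math.tan(math.radians(lat)) * math.tan(math.radians(decl))
    )
    if not -1.0 <= cos_ha <= 1.0:
        raise ValueError(f"no sunrise/sunset at lat={lat} on {d} (polar day or night)")
    ha = math.degrees(math.acos(cos_ha))
    solar_noon_min = 720 - 4 * lon - eot  # minutes from UTC midnight
    rise_min = solar_noon_min - 4 * ha
    set_min = solar_noon_min + 4 * ha
    midnight = datetime(d.year, d.month, d.day, tzinfo=timezone.utc)
    return midnight + timedelta(minutes=rise_min), midnight + timedelta(minutes=set_min)


class NoaaSolar:
    """Sunrise/sunset provider anchored at one reference point.

    The analysis assumes a single projected study area (no CRS engine), so
    diel classification uses one reference latitude/longitude for all fixes.
    """

    def __init__(self, lat: float, lon: float):
        self.lat = lat
        self.lon = lon
        self._cache: dict[date, tuple[datetime, datetime]] = {}

    def __call__(self, t: datetime) -> tuple[datetime, datetime]:
        d = t.astimezone(timezone.utc).date() if t.tzinfo else t.date()
        if d not in self._cache:
            self._cache[d] = sunrise_sunset(d, self.lat, self.lon)
        return self._cache[d]
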