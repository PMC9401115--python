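"""Apparent solar elevation and civil day/night classification.

Implements the NOAA solar position equations (the algorithm behind the
NOAA Solar Calculator): Julian-century polynomials for the sun's geometric
mean longitude, anomaly and orbital eccentricity, the equation of centre,
apparent longitude with nutation/aberration corrections, corrected
obliquity, declination, the equation of time, and finally the local hour
angle. Accuracy is a few hundredths of a degree over +/-2 centuries of
J2000 — far inside the 0.2 deg needed to classify civil twilight.

Day is defined as the sun's centre at or above -6 deg apparent elevation
(between civil dawn and civil dusk). Working from the elevation predicate
directly, rather than dawn/dusk event times, makes polar dates with no
civil dusk well-defined for free.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: sun-centre elevation (degrees) at the civil dawn/dusk boundary
CIVIL_TWILIGHT_ELEVATION = -6.0

_J2000_JD = 2451545.0


def _julian_day(timestamps) -> np.ndarray:
    ts = pd.to_datetime(timestamps, utc=True)
    if isinstance(ts, pd.Timestamp):
        ts = pd.DatetimeIndex([ts])
    else:
        ts = pd.DatetimeIndex(ts)
    # days since unix epoch -> Julian day (epoch 1970-01-01 00:00 UTC = JD 2440587.5)
    seconds = ts.asi8 / 1e9
    return seconds / 86400.0 + 2440587.5


def _refraction(elev_deg: np.ndarray) -> np.ndarray:
    """Standard NOAA atmospheric refraction correction, degrees."""
    e = elev_deg
    te = np.tan(np.radians(np.where(np.abs(e) > 1e-9, e, 1e-9)))
    corr = np.where(
        e > 85.0,
        0.0,
        np.where(
            e > 5.0,
            (58.1 / te - 0.07 / te**3 + 0.000086 / te**5) / 3600.0,
            np.where(
                e > -0.575,
                (1735.0 + e * (-518.2 + e * (103.4 + e * (-12.79 + e * 0.711)))) / 3600.0,
                (-20.772 / te) / 3600.0,
            ),
        ),
    )
    return corr


def solar_elevation(lat, lon, timestamp) -> np.ndarray | float:
    """Apparent solar elevation (degrees) at a site and UTC time.

    Vectorised over equal-length ``lat``/``lon``/``timestamp`` inputs.
    """
    jd = _julian_day(timestamp)
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    jc = (jd - _J2000_JD) / 36525.0

    l0 = np.mod(280.46646 + jc * (36000.76983 + jc * 0.0003032), 360.0)
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mrad = np.radians(m)
    eq_centre = (
        np.sin(mrad) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(2 * mrad) * (0.019993 - 0.000101 * jc)
        + np.sin(3 * mrad) * 0.000289
    )
    true_long = l0 + eq_centre
    omega = np.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * np.sin(omega)

    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * np.cos(omega)
    obliq_rad = np.radians(obliq)

    decl = np.arcsin(np.sin(obliq_rad) * np.sin(np.radians(app_long)))

    var_y = np.tan(obliq_rad / 2.0) ** 2
    l0r = np.radians(l0)
    eq_time_min = 4.0 * np.degrees(
        var_y * np.sin(2 * l0r)
        - 2.0 * ecc * np.sin(mrad)
        + 4.0 * ecc * var_y * np.sin(mrad) * np.cos(2 * l0r)
        - 0.5 * var_y**2 * np.sin(4 * l0r)
        - 1.25 * ecc**2 * np.sin(2 * mrad)
    )

    minutes_utc = np.mod(jd - 0.5, 1.0) * 1440.0
    tst = np.mod(minutes_utc + eq_time_min + 4.0 * lon, 1440.0)
    ha = np.radians(tst / 4.0 - 180.0)

    lat_rad = np.radians(lat)
    cos_zenith = np.sin(lat_rad) * np.sin(decl) + np.cos(lat_rad) * np.cos(decl) * np.cos(ha)
    zenith = np.degrees(np.arccos(np.clip(cos_zenith, -1.0, 1.0)))
    elev = 90.0 - zenith
    elev = elev + _refraction(elev)
    return float(elev[0]) if elev.size == 1 else elev


def classify_daynight(lat, lon, timestamp) -> np.ndarray | bool:
    """True for civil day (sun-centre elevation >= -6 deg), False for night."""
    elev = solar_elevation(lat, lon, timestamp)
    out = np.asarray(elev) >= CIVIL_TWILIGHT_ELEVATION
    return bool(out) if out.ndim == 0 else out


def label_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Add a ``day`` column classified at each interval's start position/time."""
    out = intervals.copy()
    out["day"] = classify_daynight(
        out["lat"].to_numpy(float), out["lon"].to_numpy(float), out["timestamp"]
    )
    return out
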