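"""Solar position, extraterrestrial irradiance, clearness index and
diffuse fraction.

Solar position uses the Astronomical Almanac low-precision algorithm
(Michalsky 1988), accurate to about 0.01 deg over 1950-2050 -- ample for
half-hourly flux work, where the published requirement is agreement better
than 0.2 deg with a high-accuracy reference.  No atmospheric refraction is
applied; day/night decisions use true (geometric) elevation.

For radiation work each half-hourly record is evaluated at the interval
midpoint (TIMESTAMP_END - 900 s); use :func:`midpoint_times`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import SOLAR_CONSTANT

TWO_PI = 2.0 * np.pi


@dataclass
class SolarState:
    """Per-interval solar geometry and clear-sky reference irradiance."""

    zenith: np.ndarray        # rad, [0, pi]
    azimuth: np.ndarray       # rad, 0 = N, clockwise
    elevation: np.ndarray     # rad, pi/2 - zenith
    g0h: np.ndarray           # extraterrestrial horizontal irradiance, W m-2
    kt: np.ndarray            # clearness index, NaN where g0h <= 0


def midpoint_times(index: pd.DatetimeIndex) -> pd.DatetimeIndex:
    """Midpoints of half-hourly intervals stamped end-of-interval."""
    return index - pd.Timedelta(seconds=900)


def solar_position(times: pd.DatetimeIndex, lat: float, lon: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Solar zenith and azimuth (radians) at the given UTC instants.

    Azimuth is measured from north, clockwise (east = pi/2).  Longitude is
    degrees east-positive.
    """
    times = pd.DatetimeIndex(times)
    # days (with fraction) since J2000.0
    t = times.to_julian_date().to_numpy() - 2451545.0
    hour_ut = (t + 0.5) % 1.0 * 24.0

    mnlong = np.deg2rad((280.460 + 0.9856474 * t) % 360.0)
    mnanom = np.deg2rad((357.528 + 0.9856003 * t) % 360.0)
    eclong = mnlong + np.deg2rad(1.915) * np.sin(mnanom) \
        + np.deg2rad(0.020) * np.sin(2.0 * mnanom)
    oblqec = np.deg2rad(23.439 - 4.0e-7 * t)

    ra = np.arctan2(np.cos(oblqec) * np.sin(eclong), np.cos(eclong)) % TWO_PI
    dec = np.arcsin(np.sin(oblqec) * np.sin(eclong))

    gmst = (6.697375 + 0.0657098242 * t + hour_ut) % 24.0
    lmst = np.deg2rad(((gmst + lon / 15.0) % 24.0) * 15.0)
    ha = (lmst - ra + np.pi) % TWO_PI - np.pi      # rad, + after solar noon

    phi = np.deg2rad(lat)
    sin_el = np.sin(dec) * np.sin(phi) + np.cos(dec) * np.cos(phi) * np.cos(ha)
    el = np.arcsin(np.clip(sin_el, -1.0, 1.0))
    zenith = np.pi / 2.0 - el
    # azimuth from south (westward +), shifted to from-north clockwise
    az_s = np.arctan2(np.sin(ha), np.cos(ha) * np.sin(phi) - np.tan(dec) * np.cos(phi))
    azimuth = (az_s + np.pi) % TWO_PI
    return zenith, azimuth


def eccentricity_factor(doy: np.ndarray) -> np.ndarray:
    """Sun-earth distance correction E0 via the standard day-angle cosine."""
    return 1.0 + 0.033 * np.cos(TWO_PI * np.asarray(doy, dtype=float) / 365.0)


def extraterrestrial_horizontal(times: pd.DatetimeIndex, lat: float, lon: float
                                ) -> np.ndarray:
    """Extraterrestrial irradiance on a horizontal plane, G0h = S0 E0 cos(zen).

    Zero whenever the sun is at or below the horizon.
    """
    times = pd.DatetimeIndex(times)
    zenith, _ = solar_position(times, lat, lon)
    e0 = eccentricity_factor(times.dayofyear.to_numpy())
    return np.clip(SOLAR_CONSTANT * e0 * np.cos(zenith), 0.0, None)


def clearness_index(sw_in: np.ndarray, g0h: np.ndarray) -> np.ndarray:
    """k_t = SW_IN / G0h clamped to [0, 1]; NaN (undefined) where G0h <= 0."""
    sw_in = np.asarray(sw_in, dtype=float)
    g0h = np.asarray(g0h, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        kt = np.where(g0h > 0, sw_in / g0h, np.nan)
    return np.clip(kt, 0.0, 1.0)


# Reindl two-predictor diffuse-fraction correlation (clearness index and
# solar elevation).  Piecewise in k_t; each branch carries its published
# constraint interval; continuity at branch edges is NOT guaranteed.
_REINDL_KT_CLAMP = (0.05, 0.98)


def diffuse_fraction(kt: np.ndarray, elevation: np.ndarray,
                     sw_in: np.ndarray | None = None,
                     g0h: np.ndarray | None = None) -> np.ndarray:
    """Diffuse fraction of global shortwave from k_t and solar elevation.

    Defined only where extraterrestrial irradiance is positive and SW_IN
    exceeds 5 W m-2; NaN elsewhere.  If ``sw_in``/``g0h`` are omitted the
    validity window reduces to k_t being finite and elevation > 0.
    """
    kt = np.asarray(kt, dtype=float)
    elevation = np.asarray(elevation, dtype=float)
    valid = np.isfinite(kt) & (elevation > 0)
    if g0h is not None:
        valid &= np.asarray(g0h, dtype=float) > 0
    if sw_in is not None:
        valid &= np.asarray(sw_in, dtype=float) > 5.0

    k = np.clip(kt, *_REINDL_KT_CLAMP)
    sin_el = np.sin(elevation)
    fd = np.where(
        k <= 0.3,
        np.minimum(1.02 - 0.254 * k + 0.0123 * sin_el, 1.0),
        np.where(
            k < 0.78,
            np.clip(1.400 - 1.749 * k + 0.177 * sin_el, 0.1, 0.97),
            np.maximum(0.486 * k - 0.182 * sin_el, 0.1),
        ),
    )
    fd = np.clip(fd, 0.0, 1.0)
    return np.where(valid, fd, np.nan)


def solar_state(times: pd.DatetimeIndex, lat: float, lon: float,
                sw_in: np.ndarray | None = None) -> SolarState:
    """Bundle zenith/azimuth/G0h/k_t at interval midpoints of ``times``."""
    mid = midpoint_times(times)
    zenith, azimuth = solar_position(mid, lat, lon)
    e0 = eccentricity_factor(mid.dayofyear.to_numpy())
    g0h = np.clip(SOLAR_CONSTANT * e0 * np.cos(zenith), 0.0, None)
    kt = clearness_index(sw_in, g0h) if sw_in is not None else np.full(len(mid), np.nan)
    return SolarState(zenith, azimuth, np.pi / 2 - zenith, g0h, kt)
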