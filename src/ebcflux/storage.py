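"""Calorimetric storage and sink terms of the surface energy budget.

Implements every storage term that separates net radiation from the energy
actually available for turbulent exchange at a flux tower:

* ``S_G``  -- heat storage in the soil layer above the heat-flux plates,
  from soil temperature/moisture profiles (plates at 0.05 m by default);
* ``S_H``, ``S_LE`` -- sensible and latent heat storage in the air column
  below the eddy-covariance measurement height, from temperature and
  water-vapour mole-fraction profiles (plus one-point approximations that
  assume no vertical gradient below z_m);
* ``S_PHO`` -- biochemical energy fixed by photosynthesis, from GPP;
* ``S_BIO`` -- heat storage in above-ground biomass, with air temperature
  as a proxy for biomass temperature.

Sign convention: positive = energy leaving the surface control volume, so
every term is *subtracted* from net radiation when assembling available
energy.  All terms are exactly linear in their driving temperature or
moisture increments.

Layer attribution: each profile level represents the slab from the midpoint
below to the midpoint above, with the surface and the column top (plate
depth or z_m) as outer bounds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import constants as k
from .core import FluxTable, SiteMeta, FluxTableError


def layer_thicknesses(coords: np.ndarray, total: float) -> np.ndarray:
    """Slab thicknesses for ordered level coordinates bounded by [0, total].

    Levels must be strictly increasing and inside (0, total]; thicknesses
    sum to ``total`` exactly.
    """
    c = np.asarray(coords, dtype=float)
    if c.ndim != 1 or len(c) == 0:
        raise ValueError("need at least one level")
    if (np.diff(c) <= 0).any():
        raise ValueError("level coordinates must be strictly increasing")
    if c[0] <= 0 or c[-1] > total + 1e-12:
        raise ValueError("levels must lie in (0, total]")
    bounds = np.concatenate(([0.0], (c[:-1] + c[1:]) / 2.0, [total]))
    return np.diff(bounds)


def soil_heat_capacity(theta: np.ndarray, c_dry: float = k.C_SOIL_DRY_DEFAULT
                       ) -> np.ndarray:
    """Volumetric soil heat capacity c_s = c_dry + theta * c_water.

    A de Vries-type mixing rule: the dry matrix contributes a constant
    ``c_dry`` (J m-3 K-1) and soil water adds its own volumetric heat
    capacity in proportion to the volumetric water content ``theta``.
    """
    theta = np.asarray(theta, dtype=float)
    if np.nanmin(theta, initial=0.0) < 0 or np.nanmax(theta, initial=0.0) > 1:
        raise ValueError("theta outside [0, 1]")
    return c_dry + theta * k.C_WATER_VOL


def soil_storage_flux(temp_layers: np.ndarray, theta_layers: np.ndarray,
                      thicknesses: np.ndarray, dt: float = k.HALF_HOUR_S,
                      c_dry: float = k.C_SOIL_DRY_DEFAULT) -> np.ndarray:
    """Soil-layer heat storage S_G = sum_i c_s,i dT_s,i / dt * dz_i (W m-2).

    ``temp_layers``/``theta_layers``: arrays (n_time, n_layers) of soil
    temperature (degC) and volumetric moisture; the temporal increment is
    taken between consecutive rows, so the first interval is NaN.
    """
    temp = np.atleast_2d(np.asarray(temp_layers, dtype=float))
    theta = np.atleast_2d(np.asarray(theta_layers, dtype=float))
    dz = np.asarray(thicknesses, dtype=float)
    if temp.shape != theta.shape or temp.shape[1] != len(dz):
        raise FluxTableError("mismatched soil layering")
    c_s = soil_heat_capacity(theta, c_dry)
    d_temp = np.diff(temp, axis=0)
    per_layer = c_s[1:] * d_temp / dt * dz
    out = np.full(temp.shape[0], np.nan)
    out[1:] = per_layer.sum(axis=1)
    return out


def aggregate_soil_plates(g_plates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spatial mean of replicate soil heat-flux plates.

    Returns (mean, n_available) per interval; intervals where every plate
    is missing stay missing.
    """
    g = np.atleast_2d(np.asarray(g_plates, dtype=float))
    finite = np.isfinite(g)
    n = finite.sum(axis=1)
    total = np.where(finite, g, 0.0).sum(axis=1)
    mean = np.divide(total, n, out=np.full(len(n), np.nan), where=n > 0)
    return mean, n


def air_density(ta_c: np.ndarray, pa_kpa: np.ndarray) -> np.ndarray:
    """Moist-air mass density from the ideal-gas law (kg m-3)."""
    return np.asarray(pa_kpa, float) * 1000.0 / (k.R_DRY * (np.asarray(ta_c, float) + 273.15))


def dry_air_molar_density(ta_c: np.ndarray, pa_kpa: np.ndarray,
                          e_kpa: np.ndarray | float = 0.0) -> np.ndarray:
    """Dry-air molar density rho_d = (PA - e) / (R T) in mol m-3."""
    p_d = (np.asarray(pa_kpa, float) - np.asarray(e_kpa, float)) * 1000.0
    return p_d / (k.R_GAS * (np.asarray(ta_c, float) + 273.15))


def saturation_vapor_pressure(ta_c: np.ndarray) -> np.ndarray:
    """Saturation vapour pressure over water, Magnus form (kPa)."""
    ta_c = np.asarray(ta_c, dtype=float)
    return 0.61078 * np.exp(17.27 * ta_c / (ta_c + 237.3))


def air_heat_storage(ta_layers: np.ndarray, thicknesses: np.ndarray,
                     rho_a: np.ndarray, dt: float = k.HALF_HOUR_S) -> np.ndarray:
    """Air-column sensible heat storage S_H = rho_a c_p sum dTA_i/dt dz_i."""
    ta = np.atleast_2d(np.asarray(ta_layers, dtype=float))
    dz = np.asarray(thicknesses, dtype=float)
    if ta.shape[1] != len(dz):
        raise FluxTableError("mismatched air-column levels")
    rho = np.broadcast_to(np.asarray(rho_a, dtype=float), (ta.shape[0],))
    d_ta = np.diff(ta, axis=0)
    out = np.full(ta.shape[0], np.nan)
    out[1:] = rho[1:] * k.CP_AIR * (d_ta * dz).sum(axis=1) / dt
    return out


def air_moisture_storage(xw_layers: np.ndarray, thicknesses: np.ndarray,
                         rho_d: np.ndarray, dt: float = k.HALF_HOUR_S,
                         lam: float = k.LAMBDA_VAP) -> np.ndarray:
    """Latent heat storage S_LE = rho_d lambda M_w sum dX_w,i/dt dz_i.

    ``xw_layers`` is the water-vapour mole fraction relative to dry air
    (mol mol-1) at each level.
    """
    xw = np.atleast_2d(np.asarray(xw_layers, dtype=float))
    dz = np.asarray(thicknesses, dtype=float)
    if xw.shape[1] != len(dz):
        raise FluxTableError("mismatched air-column levels")
    rho = np.broadcast_to(np.asarray(rho_d, dtype=float), (xw.shape[0],))
    d_xw = np.diff(xw, axis=0)
    out = np.full(xw.shape[0], np.nan)
    out[1:] = rho[1:] * lam * k.M_WATER * (d_xw * dz).sum(axis=1) / dt
    return out


def one_point_storage(ta_top: np.ndarray, xw_top: np.ndarray, z_m: float,
                      rho_a: np.ndarray, rho_d: np.ndarray,
                      dt: float = k.HALF_HOUR_S) -> tuple[np.ndarray, np.ndarray]:
    """One-point S_H and S_LE: a single slab of thickness z_m holding the
    top-of-column temperature and moisture (no vertical gradient below z_m)."""
    if z_m <= 0:
        raise ValueError("z_m must be positive")
    dz = np.array([z_m])
    s_h = air_heat_storage(np.asarray(ta_top, float)[:, None], dz, rho_a, dt)
    s_le = air_moisture_storage(np.asarray(xw_top, float)[:, None], dz, rho_d, dt)
    return s_h, s_le


def photosynthesis_storage(gpp: np.ndarray, clamp_negative: bool = False
                           ) -> np.ndarray:
    """Photosynthetic energy sink S_pho = -mu * GPP (W m-2).

    GPP in umol CO2 m-2 s-1 is converted to kg CO2 m-2 s-1 via the CO2
    molar mass; the sink is negative (energy entering the ecosystem as
    fixed carbon leaves the thermal budget).  Negative GPP values
    (partitioning artifacts) pass through unless ``clamp_negative``.
    """
    gpp = np.asarray(gpp, dtype=float)
    if clamp_negative:
        gpp = np.clip(gpp, 0.0, None)
    return -k.MU_PHOTOSYNTHESIS * gpp * 1e-6 * k.M_CO2


def biomass_storage(m_v: float, dt_v: np.ndarray, dt: float = k.HALF_HOUR_S
                    ) -> np.ndarray:
    """Biomass heat storage S_bio = m_v c_v dT_v / dt (W m-2).

    ``m_v`` is the wet (fresh) above-ground biomass in kg m-2; dry
    inventory values convert with :func:`wet_biomass_from_dry`.  ``dt_v``
    is the per-interval biomass temperature change (K), proxied by the
    layer-weighted air-temperature change.
    """
    if m_v < 0:
        raise ValueError("biomass must be >= 0")
    return m_v * k.C_BIOMASS * np.asarray(dt_v, dtype=float) / dt


def wet_biomass_from_dry(dry_mass: float) -> float:
    """Fresh biomass from dry inventory via the dry-to-fresh factor of 2."""
    return dry_mass * k.DRY_TO_FRESH


def layer_weighted_mean(layers: np.ndarray, thicknesses: np.ndarray) -> np.ndarray:
    """Thickness-weighted column mean of a (n_time, n_layers) array."""
    dz = np.asarray(thicknesses, dtype=float)
    return (np.atleast_2d(layers) * dz).sum(axis=1) / dz.sum()


# ---------------------------------------------------------------------------
# FluxTable-level driver
# ---------------------------------------------------------------------------

def add_storage_columns(table: FluxTable, meta: SiteMeta,
                        c_dry: float = k.C_SOIL_DRY_DEFAULT,
                        clamp_negative_gpp: bool = False) -> FluxTable:
    """Compute G, S_G, S_H, S_LE, one-point variants, S_PHO and S_BIO.

    Reads the profile column groups (``TS_i``/``SWC_i`` at depths,
    ``TA_i``/``H2O_i`` at heights, ``G_i`` replicate plates) declared in
    ``table.profiles`` and appends the storage columns in place of any
    existing ones.  Terms whose inputs are absent stay absent (all-NaN
    columns are not created).
    """
    t = table.copy()
    df = t.data

    if "PA" in df:
        pa = df["PA"].to_numpy(float)
    else:  # barometric fallback from site elevation
        pa = np.full(len(df), 101.325 * (1 - 2.25577e-5 * meta.elevation) ** 5.25588)
    ta = df["TA"].to_numpy(float) if "TA" in df else np.full(len(df), np.nan)
    rho_a = air_density(ta, pa)
    e_kpa = np.zeros(len(df))
    if "RH" in df and "TA" in df:
        e_kpa = df["RH"].to_numpy(float) / 100.0 * saturation_vapor_pressure(ta)
    rho_d = dry_air_molar_density(ta, pa, e_kpa)

    # soil plates -> G
    g_cols = t.profile_columns("G")
    if g_cols:
        g_mean, g_n = aggregate_soil_plates(df[g_cols].to_numpy(float))
        df["G"] = g_mean
        df["G_N"] = g_n

    # soil profile -> S_G
    ts_cols, swc_cols = t.profile_columns("TS"), t.profile_columns("SWC")
    if ts_cols and swc_cols:
        dz_soil = layer_thicknesses(np.asarray(t.profiles["TS"]), meta.soil_plate_depth)
        df["S_G"] = soil_storage_flux(df[ts_cols].to_numpy(float),
                                      df[swc_cols].to_numpy(float),
                                      dz_soil, c_dry=c_dry)

    # air profile -> S_H, S_LE
    ta_cols, h2o_cols = t.profile_columns("TA"), t.profile_columns("H2O")
    if meta.has_profile and ta_cols and h2o_cols:
        heights = np.asarray(t.profiles["TA"])
        dz_air = layer_thicknesses(heights, meta.ec_height)
        ta_prof = df[ta_cols].to_numpy(float)
        df["S_H"] = air_heat_storage(ta_prof, dz_air, rho_a)
        df["S_LE"] = air_moisture_storage(df[h2o_cols].to_numpy(float), dz_air, rho_d)
        ta_col_mean = layer_weighted_mean(ta_prof, dz_air)
    else:
        ta_col_mean = ta

    # one-point approximations from top-of-column (EC height) values
    ta_top = df[ta_cols[-1]].to_numpy(float) if ta_cols else ta
    if h2o_cols:
        xw_top = df[h2o_cols[-1]].to_numpy(float)
    elif "RH" in df and "TA" in df:
        xw_top = e_kpa / (pa - e_kpa)
    else:
        xw_top = np.full(len(df), np.nan)
    s_h_1p, s_le_1p = one_point_storage(ta_top, xw_top, meta.ec_height, rho_a, rho_d)
    df["S_H_1P"], df["S_LE_1P"] = s_h_1p, s_le_1p
    if not (meta.has_profile and ta_cols and h2o_cols):
        df["S_H"], df["S_LE"] = s_h_1p, s_le_1p

    if "GPP" in df:
        # column convention: positive = energy leaving the available pool,
        # so the (negative) photosynthetic sink enters with flipped sign
        df["S_PHO"] = -photosynthesis_storage(df["GPP"].to_numpy(float),
                                              clamp_negative_gpp)

    if meta.wet_biomass > 0:
        dtv = np.full(len(df), np.nan)
        dtv[1:] = np.diff(np.asarray(ta_col_mean, float))
        df["S_BIO"] = biomass_storage(meta.wet_biomass, dtv)
    else:
        df["S_BIO"] = 0.0
    return t
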