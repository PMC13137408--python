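"""Net-radiation corrections: terrain slope, topographic shadowing, tower
field-of-view interference, and radiometer/footprint field-of-view mismatch.

Each correction returns its own corrected NETRAD variant computed from the
*measured* baseline components -- corrections are evaluated independently,
never chained, so their individual effect on closure can be compared.

Conventions: angles in radians inside the math, degrees at the metadata /
horizon-profile surface; corrections that cannot be evaluated at an
interval (night, undefined albedo, non-physical inversion) pass the
measured value through and raise a per-interval flag rather than clipping
silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import STEFAN_BOLTZMANN
from .core import FluxTable, SiteMeta, Grid
from . import solar


# ---------------------------------------------------------------------------
# Terrain slope
# ---------------------------------------------------------------------------

def incidence_angle(zenith: np.ndarray, azimuth: np.ndarray,
                    slope_deg: float, aspect_deg: float) -> np.ndarray:
    """Angle psi between the slope normal and the sun direction (rad).

    cos psi = cos(zen) cos(beta) + sin(zen) sin(beta) cos(az_sun - aspect);
    reduces to the zenith angle exactly on flat terrain.
    """
    beta = np.deg2rad(slope_deg)
    aspect = np.deg2rad(aspect_deg)
    cos_psi = (np.cos(zenith) * np.cos(beta)
               + np.sin(zenith) * np.sin(beta) * np.cos(azimuth - aspect))
    return np.arccos(np.clip(cos_psi, -1.0, 1.0))


def slope_correct_sw(sw_in: np.ndarray, kt: np.ndarray, zenith: np.ndarray,
                     psi: np.ndarray, albedo: np.ndarray,
                     albedo_term: str = "multiply") -> np.ndarray:
    """Incoming shortwave on the inclined surface, SW_IN(psi).

    SW_IN(psi) = SW_IN exp(-k_t (psi^2 - zen^2)) * (1 - ALB sin^2(psi/2)),
    all angles in radians.  The albedo factor is applied as a multiplier by
    default; ``albedo_term="divide"`` selects the divisor reading of the
    same expression (the published rendering is typographically ambiguous).
    Night or undefined-k_t intervals pass through unchanged.
    """
    sw_in = np.asarray(sw_in, dtype=float)
    kt = np.asarray(kt, dtype=float)
    ok = np.isfinite(kt) & np.isfinite(psi) & (np.cos(zenith) > 0) & np.isfinite(sw_in)
    expo = np.exp(-kt * (np.square(psi) - np.square(zenith)))
    alb_fac = 1.0 - np.asarray(albedo, dtype=float) * np.square(np.sin(psi / 2.0))
    if albedo_term == "multiply":
        corr = expo * alb_fac
    elif albedo_term == "divide":
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = expo / alb_fac
    else:
        raise ValueError("albedo_term must be 'multiply' or 'divide'")
    return np.where(ok, sw_in * corr, sw_in)


def interval_albedo(sw_in: np.ndarray, sw_out: np.ndarray,
                    index: pd.DatetimeIndex | None = None,
                    low_sun_floor: float = 50.0,
                    clamp: tuple[float, float] = (0.01, 0.99)) -> np.ndarray:
    """Per-interval surface albedo SW_OUT/SW_IN with a low-sun guard.

    Where SW_IN < ``low_sun_floor`` W m-2 the ratio blows up; those
    intervals fall back to the daily median of the well-lit ratios (when an
    ``index`` is given) or to the overall median.
    """
    sw_in = np.asarray(sw_in, dtype=float)
    sw_out = np.asarray(sw_out, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        alb = np.clip(sw_out / sw_in, *clamp)
    lit = sw_in >= low_sun_floor
    if index is not None and len(index):
        s = pd.Series(np.where(lit, alb, np.nan), index=index)
        daily = s.groupby(index.date).transform("median").to_numpy()
        alb = np.where(lit, alb, daily)
    overall = np.nanmedian(np.where(lit, alb, np.nan))
    if not np.isfinite(overall):
        overall = 0.2
    return np.where(np.isfinite(alb), alb, overall)


# ---------------------------------------------------------------------------
# Topographic shadowing
# ---------------------------------------------------------------------------

@dataclass
class HorizonProfile:
    """Horizon elevation angle (deg) on a regular azimuth grid (deg from N)."""

    azimuths: np.ndarray
    elevations: np.ndarray

    def __post_init__(self) -> None:
        if (self.elevations < 0).any() or (self.elevations >= 90).any():
            raise ValueError("horizon elevations outside [0, 90)")

    def elevation_at(self, azimuth_deg: np.ndarray) -> np.ndarray:
        """Periodic linear interpolation of horizon elevation."""
        az = np.asarray(azimuth_deg, dtype=float) % 360.0
        grid = np.concatenate([self.azimuths, [self.azimuths[0] + 360.0]])
        elev = np.concatenate([self.elevations, [self.elevations[0]]])
        return np.interp(az, grid, elev)


def horizon_from_dem(dem: Grid, site_xy: tuple[float, float] | None = None,
                     radius: float | None = None,
                     azimuth_step: float = 1.0) -> HorizonProfile:
    """Horizon elevation per azimuth bin from a DEM around the site.

    For each azimuth the ray from the site is sampled at half-cell steps
    out to ``radius`` (default: largest inscribed distance) and the maximum
    elevation angle atan((z_cell - z_site) / d) is recorded (floored at 0).
    Planar geometry -- adequate for frames up to ~20 km.
    """
    nrows, ncols = dem.shape
    if site_xy is None:
        site_xy = (dem.xll + ncols * dem.cellsize / 2.0,
                   dem.yll + nrows * dem.cellsize / 2.0)
    x0, y0 = site_xy
    if not (dem.xll <= x0 <= dem.xll + ncols * dem.cellsize
            and dem.yll <= y0 <= dem.yll + nrows * dem.cellsize):
        raise ValueError("site outside DEM grid")
    z0 = dem.value_at(x0, y0)
    if radius is None:
        radius = min(x0 - dem.xll, dem.xll + ncols * dem.cellsize - x0,
                     y0 - dem.yll, dem.yll + nrows * dem.cellsize - y0)
    dists = np.arange(dem.cellsize, radius, dem.cellsize / 2.0)
    azimuths = np.arange(0.0, 360.0, azimuth_step)
    elevations = np.zeros_like(azimuths)
    az_rad = np.deg2rad(azimuths)
    # azimuth from north clockwise: dx = sin(az), dy = cos(az)
    for j, a in enumerate(az_rad):
        xs = x0 + dists * np.sin(a)
        ys = y0 + dists * np.cos(a)
        cols = np.floor((xs - dem.xll) / dem.cellsize).astype(int)
        rows = np.floor(nrows - (ys - dem.yll) / dem.cellsize).astype(int)
        ok = (rows >= 0) & (rows < nrows) & (cols >= 0) & (cols < ncols)
        if not ok.any():
            continue
        z = dem.data[rows[ok], cols[ok]]
        ang = np.arctan2(z - z0, dists[ok])
        elevations[j] = max(0.0, np.rad2deg(np.nanmax(ang)))
    return HorizonProfile(azimuths, elevations)


def shadow_correct_sw(sw_in: np.ndarray, diffuse_frac: np.ndarray,
                      elevation: np.ndarray, azimuth: np.ndarray,
                      horizon: HorizonProfile) -> np.ndarray:
    """Shortwave with the direct beam removed where terrain blocks the sun.

    When the solar elevation is below the horizon elevation at the solar
    azimuth, SW_IN is reduced to its diffuse component (the reflected
    component is neglected); otherwise it is unchanged.  Intervals where
    the diffuse fraction is undefined pass through.
    """
    sw_in = np.asarray(sw_in, dtype=float)
    fd = np.asarray(diffuse_frac, dtype=float)
    elev_deg = np.rad2deg(np.asarray(elevation, dtype=float))
    hor = horizon.elevation_at(np.rad2deg(np.asarray(azimuth, dtype=float)))
    shadowed = (elev_deg > 0) & (elev_deg < hor) & np.isfinite(fd)
    return np.where(shadowed, fd * sw_in, sw_in)


# ---------------------------------------------------------------------------
# Mounting-tower interference
# ---------------------------------------------------------------------------

@dataclass
class TowerGeometry:
    """Tower seen from a downward radiometer, modelled as a vertical
    rectangle: effective width (after lattice void reduction), visible
    height (mount height minus canopy height), horizontal distance, and
    the radiometer's total FoV angle (deg)."""

    effective_width: float
    visible_height: float
    horizontal_distance: float
    fov_angle: float

    def __post_init__(self) -> None:
        for v in (self.effective_width, self.visible_height,
                  self.horizontal_distance, self.fov_angle):
            if v <= 0:
                raise ValueError("tower geometry values must be positive")


def rectangle_solid_angle(width: float, height: float, distance: float) -> float:
    """Solid angle of a vertical rectangle whose top edge is at sensor level.

    The sensor sits on the normal through the rectangle's top-centre at
    perpendicular distance ``distance``.  By the pyramid (corner-
    decomposition) formula, Omega = 2 atan(w/2 * h / (D sqrt((w/2)^2 + h^2
    + D^2))).
    """
    u, v, d = width / 2.0, height, distance
    return 2.0 * np.arctan(u * v / (d * np.sqrt(u * u + v * v + d * d)))


def tower_disturbance_fraction(geom: TowerGeometry) -> float:
    """Fraction of the radiometer FoV solid angle occupied by the tower."""
    omega_rect = rectangle_solid_angle(geom.effective_width,
                                       geom.visible_height,
                                       geom.horizontal_distance)
    omega_fov = 2.0 * np.pi * (1.0 - np.cos(np.deg2rad(geom.fov_angle) / 2.0))
    return float(omega_rect / omega_fov)


def tower_geometry_from_meta(meta: SiteMeta, band: str = "sw") -> TowerGeometry:
    fov = meta.radiometer.sw_fov_angle if band == "sw" else meta.radiometer.lw_fov_angle
    return TowerGeometry(
        effective_width=meta.tower.effective_width,
        visible_height=max(meta.radiometer.mount_height - meta.canopy_height, 1e-6),
        horizontal_distance=meta.radiometer.horizontal_distance_to_tower,
        fov_angle=fov,
    )


def tower_correct_sw(sw_out: np.ndarray, sw_in: np.ndarray, delta_frac: float,
                     alb_tower: float = 0.2
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Outgoing shortwave with the tower's reflectance share removed.

    The measured FoV albedo mixes ground and tower, ALB_FoV =
    (1 - delta) ALB_g + delta ALB_t; inverting for ALB_g and rescaling
    SW_OUT by ALB_g/ALB_FoV removes the tower share.  Returns the
    corrected series and a boolean flag of intervals passed through
    (SW_IN <= 0 or non-physical inversion ALB_FoV <= delta*ALB_t).
    """
    sw_out = np.asarray(sw_out, dtype=float)
    sw_in = np.asarray(sw_in, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        alb_fov = sw_out / sw_in
        alb_g = (alb_fov - delta_frac * alb_tower) / (1.0 - delta_frac)
        corrected = sw_out * alb_g / alb_fov
    bad = ~np.isfinite(corrected) | (sw_in <= 0) | (alb_fov <= delta_frac * alb_tower)
    return np.where(bad, sw_out, corrected), bad


def tower_correct_lw(lw_out: np.ndarray, lw_in: np.ndarray, ta_c: np.ndarray,
                     delta_frac: float, eps_tower: float = 0.3,
                     day: np.ndarray | None = None,
                     denominator: str = "literal", tau: float = 1.0,
                     lw_atm: float = 0.0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Outgoing longwave with the tower's emission share removed.

    The FoV emissivity is retrieved radiometrically with surface
    temperature approximated as TA + 4 K (day) / + 2 K (night):

    * ``denominator="literal"``:  eps = (LW_OUT - tau (LW_IN - LW_ATM))
      / (tau sigma T^4 - LW_OUT);
    * ``denominator="standard"``: the Jin-Liang-style form with
      (sigma T^4 - LW_IN) in the denominator.

    Ground emissivity follows from the linear FoV mixing rule, and LW_OUT
    is rescaled by eps_g/eps_FoV.  Non-physical retrievals (denominator
    <= 0, eps outside (0, 1.5]) pass through flagged.
    """
    lw_out = np.asarray(lw_out, dtype=float)
    lw_in = np.asarray(lw_in, dtype=float)
    ta_k = np.asarray(ta_c, dtype=float) + 273.15
    if day is None:
        day = np.ones_like(lw_out, dtype=bool)
    t_surf = ta_k + np.where(day, 4.0, 2.0)
    sig_t4 = STEFAN_BOLTZMANN * t_surf ** 4
    if denominator == "literal":
        den = tau * sig_t4 - lw_out
    elif denominator == "standard":
        den = sig_t4 - lw_in
    else:
        raise ValueError("denominator must be 'literal' or 'standard'")
    with np.errstate(divide="ignore", invalid="ignore"):
        eps_fov = (lw_out - tau * (lw_in - lw_atm)) / den
        eps_g = (eps_fov - delta_frac * eps_tower) / (1.0 - delta_frac)
        corrected = lw_out * eps_g / eps_fov
    bad = (~np.isfinite(corrected) | (den <= 0)
           | (eps_fov <= 0) | (eps_fov > 1.5) | (eps_g <= 0))
    return np.where(bad, lw_out, corrected), bad


# ---------------------------------------------------------------------------
# Radiometer / footprint FoV mismatch
# ---------------------------------------------------------------------------

@dataclass
class FovWeights:
    """Footprint weights (sum 1 over the 70 % cumulative-contribution clip)
    and the radiometer's projected circular FoV (equal weights, sum 1)."""

    footprint: Grid
    radiometer_disc: Grid

    def __post_init__(self) -> None:
        for g in (self.footprint, self.radiometer_disc):
            w = np.nan_to_num(g.data)
            if (w < 0).any():
                raise ValueError("negative FoV weights")
            if abs(w.sum() - 1.0) > 1e-6:
                raise ValueError("FoV weights must sum to 1")


def _weighted_mean(values: Grid, weights: Grid, min_valid: float
                   ) -> float:
    v = values.data
    w = np.nan_to_num(weights.data)
    region = w > 0
    valid = region & np.isfinite(v)
    if region.sum() == 0 or valid.sum() / region.sum() < min_valid:
        return np.nan
    wv = w[valid]
    return float((v[valid] * wv).sum() / wv.sum())


def fov_mismatch_ratios(weights: FovWeights, sr: Grid, lst: Grid,
                        min_valid: float = 0.5) -> tuple[float, float]:
    """Correction ratios for SW_OUT and LW_OUT from co-registered rasters.

    delta_FoV|SW = SR_rad / SR_EC and delta_FoV|LW = LST_rad / LST_EC,
    each a footprint- / disc-weighted mean over the surface-reflectance and
    land-surface-temperature rasters.  A ratio is NaN (undefined) when
    fewer than ``min_valid`` of the pixels in either region are valid.
    """
    for g in (sr, lst):
        if g.shape != weights.footprint.shape:
            raise ValueError("rasters not co-registered with weights")
    sr_ec = _weighted_mean(sr, weights.footprint, min_valid)
    sr_rad = _weighted_mean(sr, weights.radiometer_disc, min_valid)
    lst_ec = _weighted_mean(lst, weights.footprint, min_valid)
    lst_rad = _weighted_mean(lst, weights.radiometer_disc, min_valid)
    with np.errstate(divide="ignore", invalid="ignore"):
        return sr_rad / sr_ec, lst_rad / lst_ec


def fov_overlap_fraction(weights: FovWeights) -> float:
    """Area overlap between footprint and radiometer-FoV supports, as a
    fraction of the larger of the two areas."""
    a = np.nan_to_num(weights.footprint.data) > 0
    b = np.nan_to_num(weights.radiometer_disc.data) > 0
    larger = max(a.sum(), b.sum())
    return float((a & b).sum() / larger) if larger else np.nan


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass
class CorrectedRadiation:
    """Per-correction NETRAD variants plus intermediate components."""

    variants: pd.DataFrame
    delta_frac_sw: float | None = None
    delta_frac_lw: float | None = None
    fov_ratio_sw: float | None = None
    fov_ratio_lw: float | None = None
    flags: dict[str, np.ndarray] = field(default_factory=dict)


def assemble_netrad(table: FluxTable, meta: SiteMeta,
                    corrections: tuple[str, ...] = (),
                    horizon: HorizonProfile | None = None,
                    fov_weights: FovWeights | None = None,
                    sr: Grid | None = None, lst: Grid | None = None,
                    min_slope_deg: float = 2.0,
                    overlap_threshold: float = 0.6,
                    albedo_term: str = "multiply",
                    lw_denominator: str = "literal") -> CorrectedRadiation:
    """Baseline NETRAD plus one independently-corrected variant per item of
    ``corrections`` (subset of {"slope", "shadow", "tower", "fov"}).

    The slope correction is applied only when the site slope reaches
    ``min_slope_deg``; the FoV-mismatch correction only when the
    footprint/radiometer overlap is below ``overlap_threshold`` of the
    larger area.  Each variant is built from the measured components; they
    are never chained.
    """
    df = table.data
    sw_in = df["SW_IN"].to_numpy(float)
    sw_out = df["SW_OUT"].to_numpy(float)
    lw_in = df["LW_IN"].to_numpy(float)
    lw_out = df["LW_OUT"].to_numpy(float)
    base = sw_in + lw_in - sw_out - lw_out
    out = pd.DataFrame({"NETRAD": base}, index=df.index)
    result = CorrectedRadiation(out)

    need_sun = {"slope", "shadow"} & set(corrections)
    if need_sun:
        state = solar.solar_state(df.index, meta.latitude, meta.longitude, sw_in)

    if "slope" in corrections:
        if meta.slope >= min_slope_deg:
            psi = incidence_angle(state.zenith, state.azimuth, meta.slope, meta.aspect)
            alb = interval_albedo(sw_in, sw_out, df.index)
            sw_slope = slope_correct_sw(sw_in, state.kt, state.zenith, psi,
                                        alb, albedo_term)
            out["SW_IN_SLOPE"] = sw_slope
            out["NETRAD_SLOPE"] = sw_slope + lw_in - sw_out - lw_out
        else:
            out["NETRAD_SLOPE"] = base

    if "shadow" in corrections:
        if horizon is None:
            raise ValueError("shadow correction requires a horizon profile")
        fd = solar.diffuse_fraction(state.kt, state.elevation, sw_in, state.g0h)
        sw_sh = shadow_correct_sw(sw_in, fd, state.elevation, state.azimuth, horizon)
        out["SW_IN_SHADOW"] = sw_sh
        out["NETRAD_SHADOW"] = sw_sh + lw_in - sw_out - lw_out

    if "tower" in corrections:
        d_sw = tower_disturbance_fraction(tower_geometry_from_meta(meta, "sw"))
        d_lw = tower_disturbance_fraction(tower_geometry_from_meta(meta, "lw"))
        result.delta_frac_sw, result.delta_frac_lw = d_sw, d_lw
        sw_t, sw_bad = tower_correct_sw(sw_out, sw_in, d_sw, meta.tower.albedo)
        if need_sun:
            day = state.elevation > 0
        else:
            day = solar.solar_state(df.index, meta.latitude, meta.longitude).elevation > 0
        ta = df["TA"].to_numpy(float) if "TA" in df else np.full(len(df), np.nan)
        lw_t, lw_bad = tower_correct_lw(lw_out, lw_in, ta, d_lw,
                                        meta.tower.emissivity, day,
                                        lw_denominator)
        out["SW_OUT_TOWER"], out["LW_OUT_TOWER"] = sw_t, lw_t
        out["NETRAD_TOWER"] = sw_in + lw_in - sw_t - lw_t
        result.flags["tower_sw"] = sw_bad
        result.flags["tower_lw"] = lw_bad

    if "fov" in corrections:
        if fov_weights is None or sr is None or lst is None:
            raise ValueError("fov correction requires weights, SR and LST rasters")
        overlap = fov_overlap_fraction(fov_weights)
        if overlap < overlap_threshold:
            r_sw, r_lw = fov_mismatch_ratios(fov_weights, sr, lst)
            result.fov_ratio_sw, result.fov_ratio_lw = r_sw, r_lw
            sw_f = sw_out * r_sw if np.isfinite(r_sw) else sw_out
            lw_f = lw_out * r_lw if np.isfinite(r_lw) else lw_out
            out["SW_OUT_FOV"], out["LW_OUT_FOV"] = sw_f, lw_f
            out["NETRAD_FOV"] = sw_in + lw_in - sw_f - lw_f
        else:
            out["NETRAD_FOV"] = base
    return result
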