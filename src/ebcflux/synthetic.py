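"""Synthetic half-hourly flux-tower generator with known ground truth.

Emulates the variable structure of network flux archives (radiation
components, meteorology, soil/air profiles, turbulent fluxes, quality
flags, gaps) so the whole accounting pipeline is testable by parameter
recovery: the generator imposes a closure fraction ``f`` with
TE = f * AE at every interval *before* noise, where AE is assembled by the
package's own storage accounting on the generated profiles -- energy
conservation holds by construction and the imposed ``f`` is the quantity
every closure metric should recover.

The defaults describe a temperate mid-latitude site: AR(1) clearness with
mean 0.6 and lag-1 correlation 0.8, a 0.5-2 seasonal Bowen-ratio swing, a
2-layer soil profile above a 0.05 m plate, 3 air-profile levels to the EC
height, gap runs with geometric lengths, and nocturnal low-u* flux
suppression.  They are fixture choices, not field measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import solar, storage
from .constants import STEFAN_BOLTZMANN
from .core import FluxTable, SiteMeta, Grid


@dataclass
class TruthRecord:
    """Ground-truth parameters of one synthetic site."""

    closure_fraction: float = 0.85
    soil_temp_amplitude: float = 4.0       # K diurnal swing at top soil layer
    air_temp_amplitude: float = 5.0        # K diurnal swing of TA
    biomass_dry: float = 10.0              # kg m-2 dry inventory
    bowen_range: tuple[float, float] = (0.5, 2.0)
    noise_mult: float = 0.0                # multiplicative SD per flux
    noise_add: float = 0.0                 # additive SD (W m-2) per flux
    gap_fraction: float = 0.0
    gap_mean_run: int = 4                  # mean gap run length (intervals)
    flag2_fraction: float = 0.02
    ustar_threshold: float | None = None   # m s-1; None = no suppression
    ustar_suppression: float = 0.4         # TE multiplier below threshold
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.closure_fraction <= 1.2:
            raise ValueError("closure_fraction outside (0, 1.2]")
        if min(self.noise_mult, self.noise_add, self.gap_fraction) < 0:
            raise ValueError("noise/gap parameters must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def default_site_meta(**overrides) -> SiteMeta:
    """A plausible temperate grass/cropland tower used by the fixtures."""
    base = dict(latitude=48.0, longitude=8.0, elevation=300.0,
                ec_height=30.0, canopy_height=12.0, slope=0.0, aspect=180.0,
                wet_biomass=20.0, has_profile=True)
    base.update(overrides)
    return SiteMeta(**base)


def _ar1(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    eps = rng.normal(0.0, sd, n)
    out = np.empty(n)
    out[0] = eps[0] / np.sqrt(max(1.0 - phi * phi, 1e-9))
    for i in range(1, n):
        out[i] = phi * out[i - 1] + eps[i]
    return out


def _gap_mask(n: int, fraction: float, mean_run: int,
              rng: np.random.Generator) -> np.ndarray:
    """Boolean gap mask with geometric run lengths totalling ~fraction."""
    mask = np.zeros(n, dtype=bool)
    if fraction <= 0:
        return mask
    target = int(round(fraction * n))
    placed = 0
    while placed < target:
        run = min(rng.geometric(1.0 / mean_run), target - placed)
        start = rng.integers(0, n - run + 1)
        newly = run - mask[start:start + run].sum()
        mask[start:start + run] = True
        placed += int(newly)
    return mask


def generate_site(meta: SiteMeta | None = None,
                  truth: TruthRecord | None = None,
                  start: str = "2023-01-01", days: int = 365,
                  ) -> tuple[FluxTable, TruthRecord]:
    """Generate one synthetic site; deterministic given ``truth.seed``.

    Returns the flux table (with AE_TRUE and TE_TRUE ledger columns for
    test introspection) and the echoed truth record.
    """
    meta = meta or default_site_meta()
    truth = truth or TruthRecord()
    rng = np.random.default_rng(truth.seed)
    n = days * 48
    index = pd.date_range(pd.Timestamp(start) + pd.Timedelta(minutes=30),
                          periods=n, freq="30min", name="TIMESTAMP_END")
    doy = index.dayofyear.to_numpy()
    hfrac = index.hour.to_numpy() + index.minute.to_numpy() / 60.0

    # --- radiation drivers -------------------------------------------------
    state = solar.solar_state(index, meta.latitude, meta.longitude)
    kt = np.clip(0.6 + _ar1(n, 0.8, 0.12, rng), 0.05, 0.95)
    sw_in = state.g0h * kt
    albedo = 0.22
    sw_out = albedo * sw_in

    # --- temperature and humidity -----------------------------------------
    seasonal = 10.0 + 9.0 * np.sin(2 * np.pi * (doy - 110) / 365.0)
    diurnal = truth.air_temp_amplitude * np.sin(2 * np.pi * (hfrac - 9.0) / 24.0)
    ta = seasonal + diurnal + _ar1(n, 0.95, 0.25, rng)
    rh = np.clip(82.0 - 1.2 * (ta - seasonal) - 0.5 * (ta - 10.0)
                 + rng.normal(0, 3.0, n), 20.0, 100.0)
    pa = np.full(n, 101.325 * (1 - 2.25577e-5 * meta.elevation) ** 5.25588)

    ta_k = ta + 273.15
    t_srf = ta + 1.0 + 5.0 * sw_in / 800.0
    lw_out = 0.98 * STEFAN_BOLTZMANN * (t_srf + 273.15) ** 4
    eps_atm = 0.70 + 0.22 * (1.0 - (kt - 0.05) / 0.90)
    lw_in = eps_atm * STEFAN_BOLTZMANN * ta_k ** 4
    netrad = sw_in + lw_in - sw_out - lw_out

    # --- soil profile and plates -------------------------------------------
    # first-order damped/lagged response of each soil layer to the surface
    depths = [0.02, 0.04]
    alphas = [0.10, 0.04]
    ts_layers = np.empty((n, len(depths)))
    for j, a in enumerate(alphas):
        s = np.empty(n)
        s[0] = t_srf[0]
        for i in range(1, n):
            s[i] = s[i - 1] + a * (t_srf[i] - s[i - 1])
        ts_layers[:, j] = s
    swc = 0.25 + 0.08 * np.sin(2 * np.pi * (doy - 30) / 365.0)
    g_base = np.empty(n)
    g_base[0] = 0.0
    for i in range(1, n):  # lagged fraction of net radiation into the soil
        g_base[i] = g_base[i - 1] + 0.15 * (0.12 * netrad[i] - g_base[i - 1])
    plate_scale = np.array([0.9, 1.0, 1.1])
    g_plates = g_base[:, None] * plate_scale[None, :]

    # --- air profile ---------------------------------------------------------
    heights = np.array([2.0, meta.ec_height / 2.0, meta.ec_height])
    damp = np.array([1.0, 0.85, 0.7])
    ta_prof = seasonal[:, None] + diurnal[:, None] * damp[None, :] \
        + (ta - seasonal - diurnal)[:, None]
    e_kpa = rh / 100.0 * storage.saturation_vapor_pressure(ta)
    xw_top = e_kpa / (pa - e_kpa)
    xw_prof = xw_top[:, None] * np.array([1.05, 1.0, 0.95])[None, :]

    # --- biological drivers --------------------------------------------------
    season_fac = 0.35 + 0.65 * np.clip(np.sin(np.pi * (doy - 90) / 200.0), 0, 1)
    gpp = 25.0 * season_fac * sw_in / (sw_in + 250.0)

    df = pd.DataFrame({
        "SW_IN": sw_in, "SW_OUT": sw_out, "LW_IN": lw_in, "LW_OUT": lw_out,
        "NETRAD": netrad, "TA": ta, "RH": rh, "PA": pa, "GPP": gpp,
    }, index=index)
    for j in range(len(depths)):
        df[f"TS_{j+1}"] = ts_layers[:, j]
        df[f"SWC_{j+1}"] = swc
    for j in range(3):
        df[f"G_{j+1}"] = g_plates[:, j]
    for j in range(len(heights)):
        df[f"TA_{j+1}"] = ta_prof[:, j]
        df[f"H2O_{j+1}"] = xw_prof[:, j]

    profiles = {"TS": depths, "SWC": depths, "G": [0.05] * 3,
                "TA": list(heights), "H2O": list(heights)}
    table = FluxTable(df, profiles)

    # --- storage accounting defines AE_true ---------------------------------
    table = storage.add_storage_columns(table, meta)
    d = table.data
    ae_true = (d["NETRAD"] - d["G"] - d["S_G"] - d["S_H"] - d["S_LE"]
               - d["S_PHO"] - d["S_BIO"])
    te_true = truth.closure_fraction * ae_true
    d["AE_TRUE"], d["TE_TRUE"] = ae_true, te_true

    bow_lo, bow_hi = truth.bowen_range
    bowen = (bow_lo + bow_hi) / 2.0 + (bow_hi - bow_lo) / 2.0 \
        * np.sin(2 * np.pi * (doy - 200) / 365.0)
    h_true = te_true * bowen / (1.0 + bowen)
    le_true = te_true / (1.0 + bowen)

    # --- friction velocity and nocturnal suppression -------------------------
    night = state.elevation <= 0
    u_day = 0.30 + 0.30 * sw_in / 800.0 + np.abs(rng.normal(0, 0.06, n))
    u_night = rng.lognormal(np.log(0.28), 0.5, n)   # median 0.28 m s-1
    ustar = np.clip(np.where(night, u_night, u_day), 0.01, None)
    h_obs, le_obs = h_true.to_numpy().copy(), le_true.to_numpy().copy()
    if truth.ustar_threshold is not None:
        supp = night & (ustar < truth.ustar_threshold)
        h_obs[supp] *= truth.ustar_suppression
        le_obs[supp] *= truth.ustar_suppression

    # --- noise, flags, gaps ---------------------------------------------------
    if truth.noise_mult > 0:
        h_obs *= 1.0 + rng.normal(0, truth.noise_mult, n)
        le_obs *= 1.0 + rng.normal(0, truth.noise_mult, n)
    if truth.noise_add > 0:
        h_obs += rng.normal(0, truth.noise_add, n)
        le_obs += rng.normal(0, truth.noise_add, n)

    flags = np.zeros(n)
    u = rng.random(n)
    flags[u < 0.05] = 1.0
    flags[u < truth.flag2_fraction] = 2.0
    d["H"], d["LE"] = h_obs, le_obs
    d["H_FLAG"] = flags
    d["LE_FLAG"] = np.roll(flags, 7)   # flags differ per flux but same rate
    d["USTAR"] = ustar

    for var in ("H", "LE"):
        gaps = _gap_mask(n, truth.gap_fraction, truth.gap_mean_run, rng)
        d.loc[gaps, var] = np.nan
        d[f"{var}_GAP"] = gaps.astype(int)
    return table, truth


# ---------------------------------------------------------------------------
# Raster fixtures
# ---------------------------------------------------------------------------

def generate_dem(kind: str = "flat", size: int = 201, cellsize: float = 30.0,
                 base: float = 500.0, peak_height: float = 100.0,
                 peak_distance: float = 1000.0, peak_azimuth: float = 90.0,
                 sigma: float = 60.0, ridge_azimuth: float = 0.0) -> Grid:
    """Analytic DEM fixtures with known horizon profiles.

    ``flat``: constant elevation; ``single_peak``: Gaussian peak of height
    ``peak_height`` at ``peak_distance`` along ``peak_azimuth`` from the
    grid centre; ``ridge``: Gaussian ridge through the off-centre point,
    oriented along ``ridge_azimuth``.
    """
    half = size * cellsize / 2.0
    grid = Grid(np.full((size, size), base), cellsize, xll=-half, yll=-half)
    if kind == "flat":
        return grid
    x, y = grid.xy_mesh()
    az = np.deg2rad(peak_azimuth)
    xc, yc = peak_distance * np.sin(az), peak_distance * np.cos(az)
    if kind == "single_peak":
        r2 = (x - xc) ** 2 + (y - yc) ** 2
        grid.data = base + peak_height * np.exp(-r2 / (2 * sigma ** 2))
    elif kind == "ridge":
        ar = np.deg2rad(ridge_azimuth)
        # perpendicular distance to the ridge line through (xc, yc)
        dist = np.abs((x - xc) * np.cos(ar) - (y - yc) * np.sin(ar))
        grid.data = base + peak_height * np.exp(-dist ** 2 / (2 * sigma ** 2))
    else:
        raise ValueError("kind must be flat | single_peak | ridge")
    return grid


def generate_rasters(pattern: str = "homogeneous", size: int = 101,
                     cellsize: float = 30.0, values: tuple[float, float] = (1.0, 2.0),
                     disc_center: tuple[float, float] = (0.0, 0.0),
                     disc_radius: float = 300.0,
                     fp_center: tuple[float, float] = (0.0, 0.0),
                     fp_sigma: float = 400.0, fp_clip: float = 0.70,
                     ) -> tuple[Grid, Grid, Grid, Grid]:
    """Co-registered (SR, LST, footprint-weight, radiometer-disc) fixtures.

    ``homogeneous``: both value rasters constant; ``two_patch``: west half
    ``values[0]``, east half ``values[1]``; ``gradient``: linear in x.  The
    footprint is a Gaussian clipped at ``fp_clip`` cumulative contribution
    and renormalized to 1; the disc has equal weights within
    ``disc_radius`` of ``disc_center``.  LST mirrors SR scaled into a
    temperature-like range (290 + 10 * SR).
    """
    half = size * cellsize / 2.0
    make = lambda a: Grid(a, cellsize, xll=-half, yll=-half)
    x, y = make(np.zeros((size, size))).xy_mesh()
    if pattern == "homogeneous":
        sr = np.full((size, size), values[0])
    elif pattern == "two_patch":
        sr = np.where(x < 0, values[0], values[1]).astype(float)
    elif pattern == "gradient":
        sr = values[0] + (values[1] - values[0]) * (x - x.min()) / (x.max() - x.min())
    else:
        raise ValueError("pattern must be homogeneous | two_patch | gradient")
    lst = 290.0 + 10.0 * sr

    w = np.exp(-((x - fp_center[0]) ** 2 + (y - fp_center[1]) ** 2)
               / (2 * fp_sigma ** 2))
    w /= w.sum()
    flat = np.sort(w.ravel())[::-1]
    cum = np.cumsum(flat)
    cutoff = flat[np.searchsorted(cum, fp_clip)]
    w = np.where(w >= cutoff, w, 0.0)
    w /= w.sum()

    disc = ((x - disc_center[0]) ** 2 + (y - disc_center[1]) ** 2
            <= disc_radius ** 2).astype(float)
    disc /= disc.sum()
    return make(sr), make(lst), make(w), make(disc)
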