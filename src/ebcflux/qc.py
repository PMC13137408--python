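"""Turbulent-flux quality tiers, friction-velocity threshold estimation and
MDS-like gap filling.

Three nested tiers of H/LE screening are produced:

``uncorrected``
    only physically implausible values removed (range check);
``fullQC``
    additionally drops intervals whose network quality flag equals 2
    (flags are consumed, never recomputed here);
``ustar_filter``
    additionally drops intervals with friction velocity below a
    site-specific threshold estimated with a moving-point change detection
    in temperature/u* classes (Papale-style).

Mask nesting kept(ustar_filter) <= kept(fullQC) <= kept(uncorrected) is
guaranteed by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FluxTable
from .storage import saturation_vapor_pressure

logger = logging.getLogger("ebcflux")

#: Default plausible physical ranges (W m-2), closed intervals.
DEFAULT_RANGES = {"H": (-250.0, 800.0), "LE": (-100.0, 800.0)}

TIERS = ("uncorrected", "fullQC", "ustar_filter")


def plausibility_filter(table: FluxTable,
                        ranges: dict[str, tuple[float, float]] | None = None
                        ) -> pd.DataFrame:
    """Keep-mask per flux: True where the value is inside its plausible
    range (boundaries included) or missing."""
    ranges = ranges or DEFAULT_RANGES
    masks = {}
    for var, (lo, hi) in ranges.items():
        if var not in table.data:
            continue
        s = table.data[var]
        masks[var] = ~((s < lo) | (s > hi))
    return pd.DataFrame(masks, index=table.data.index)


def fullqc_filter(table: FluxTable, fluxes: tuple[str, ...] = ("H", "LE")
                  ) -> pd.DataFrame:
    """Keep-mask per flux: drop intervals with severe quality flag (= 2).

    A missing ``<VAR>_FLAG`` column is treated as all-zero flags with a
    warning (nothing is dropped for that flux).
    """
    masks = {}
    for var in fluxes:
        if var not in table.data:
            continue
        flag_col = f"{var}_FLAG"
        if flag_col in table.data:
            masks[var] = table.data[flag_col].fillna(0) != 2
        else:
            logger.warning("no %s column; treating flags as 0", flag_col)
            masks[var] = pd.Series(True, index=table.data.index)
    return pd.DataFrame(masks, index=table.data.index)


@dataclass
class QcTier:
    """Keep/drop masks of one stringency tier with drop provenance."""

    name: str
    keep: pd.DataFrame                       # columns = fluxes, True = kept
    provenance: pd.DataFrame | None = None   # 'range' | 'flag' | 'ustar' | ''


def build_tiers(table: FluxTable, ustar_threshold: float | None = None,
                ranges: dict | None = None, fluxes: tuple[str, ...] = ("H", "LE"),
                night_only: bool = False) -> dict[str, QcTier]:
    """The three nested tiers for the given table.

    ``ustar_threshold`` may be None, in which case the u* tier equals
    fullQC.  ``night_only`` restricts the u* removal to nighttime
    intervals (sun below the horizon proxied by SW_IN < 12 W m-2).
    """
    plaus = plausibility_filter(table, ranges)
    plaus = plaus.reindex(columns=[f for f in fluxes if f in table.data], fill_value=True)
    flagged = fullqc_filter(table, fluxes)
    full = plaus & flagged
    ustar_keep = full.copy()
    if ustar_threshold is not None and "USTAR" in table.data:
        low = table.data["USTAR"] < ustar_threshold
        if night_only and "SW_IN" in table.data:
            low &= table.data["SW_IN"].fillna(0) < 12.0
        for c in ustar_keep.columns:
            ustar_keep[c] &= ~low
    prov = {}
    for c in full.columns:
        p = pd.Series("", index=full.index)
        p[~plaus[c]] = "range"
        p[plaus[c] & ~flagged[c]] = "flag"
        p[full[c] & ~ustar_keep[c]] = "ustar"
        prov[c] = p
    prov_df = pd.DataFrame(prov)
    return {
        "uncorrected": QcTier("uncorrected", plaus, prov_df.where(prov_df == "range", "")),
        "fullQC": QcTier("fullQC", full, prov_df.where(prov_df.isin(["range", "flag"]), "")),
        "ustar_filter": QcTier("ustar_filter", ustar_keep, prov_df),
    }


# ---------------------------------------------------------------------------
# Friction-velocity threshold (moving-point detection)
# ---------------------------------------------------------------------------

@dataclass
class UstarThreshold:
    """Seasonal and site-aggregate u* thresholds with class diagnostics."""

    site: float
    seasonal: dict[str, float] = field(default_factory=dict)
    diagnostics: list[dict] = field(default_factory=list)


def _season_label(months: pd.Series) -> pd.Series:
    # 3-month blocks anchored to the calendar year
    return pd.cut(months, bins=[0, 3, 6, 9, 12],
                  labels=["JFM", "AMJ", "JAS", "OND"]).astype(str)


def estimate_ustar_threshold(flux: pd.Series, ta: pd.Series, ustar: pd.Series,
                             night: pd.Series,
                             n_ta_classes: int = 6, n_ustar_classes: int = 20,
                             ratio: float = 0.99, corr_guard: float = 0.4,
                             min_records: int = 100) -> UstarThreshold:
    """Site u* threshold by moving-point detection in nocturnal data.

    Per season (calendar quarters) and per temperature class (quantiles),
    u* quantile classes are scanned from the lowest upward; the threshold
    is the mean u* of the first class whose mean flux reaches ``ratio``
    (99 %) of the mean over the following up-to-10 classes.  Temperature
    classes where |corr(TA, u*)| exceeds ``corr_guard`` are excluded
    (temperature-driven flux variation would masquerade as a u* effect).
    Season value: median over temperature-class thresholds; site value:
    max over seasons (conservative: keeps the strictest season).
    Undefined (NaN) when no season yields a threshold.
    """
    df = pd.DataFrame({"flux": flux, "ta": ta, "ustar": ustar}).loc[night.values]
    df = df.dropna()
    # work on a positively-signed flux so the saturation test reads upward
    if len(df) and df["flux"].mean() < 0:
        df = df.assign(flux=-df["flux"])
    seasonal: dict[str, float] = {}
    diagnostics: list[dict] = []
    months = pd.Series(df.index.month, index=df.index)
    for season, sdf in df.groupby(_season_label(months)):
        if len(sdf) < min_records:
            continue
        try:
            ta_class = pd.qcut(sdf["ta"], n_ta_classes, labels=False, duplicates="drop")
        except ValueError:
            continue
        class_thresholds = []
        for ci, cdf in sdf.groupby(ta_class):
            if len(cdf) < n_ustar_classes:
                continue
            r = cdf["ta"].corr(cdf["ustar"])
            if np.isfinite(r) and abs(r) > corr_guard:
                diagnostics.append({"season": season, "ta_class": int(ci),
                                    "excluded": "ta_ustar_corr", "corr": float(r)})
                continue
            u_class = pd.qcut(cdf["ustar"], n_ustar_classes, labels=False,
                              duplicates="drop")
            g = cdf.groupby(u_class).agg(u_mean=("ustar", "mean"),
                                         f_mean=("flux", "mean"))
            g = g.sort_index()
            thr = np.nan
            means = g["f_mean"].to_numpy()
            u_means = g["u_mean"].to_numpy()
            for i in range(len(g) - 1):
                higher = means[i + 1: i + 11]
                ref = higher.mean()
                if ref == 0:
                    continue
                if means[i] >= ratio * ref:
                    thr = u_means[i]
                    break
            if np.isfinite(thr):
                class_thresholds.append(thr)
                diagnostics.append({"season": season, "ta_class": int(ci),
                                    "threshold": float(thr)})
        if class_thresholds:
            seasonal[season] = float(np.median(class_thresholds))
    site = float(np.max(list(seasonal.values()))) if seasonal else np.nan
    return UstarThreshold(site=site, seasonal=seasonal, diagnostics=diagnostics)


def apply_ustar_filter(table: FluxTable, threshold: float,
                       fluxes: tuple[str, ...] = ("H", "LE"),
                       night_only: bool = False) -> pd.DataFrame:
    """Keep-mask per flux dropping intervals with u* below ``threshold``."""
    keep = pd.Series(True, index=table.data.index)
    if "USTAR" in table.data:
        low = table.data["USTAR"] < threshold
        if night_only and "SW_IN" in table.data:
            low &= table.data["SW_IN"].fillna(0) < 12.0
        keep = ~low
    return pd.DataFrame({f: keep for f in fluxes if f in table.data})


# ---------------------------------------------------------------------------
# MDS-like gap filling
# ---------------------------------------------------------------------------

def vpd_from_ta_rh(ta_c: np.ndarray, rh: np.ndarray) -> np.ndarray:
    """Vapour pressure deficit (hPa) from TA (degC) and RH (%), Magnus form."""
    es_hpa = saturation_vapor_pressure(np.asarray(ta_c, float)) * 10.0
    return es_hpa * (1.0 - np.asarray(rh, float) / 100.0)


def mds_gapfill(series: pd.Series, sw_in: pd.Series, ta: pd.Series,
                vpd: pd.Series,
                tolerances: tuple[float, float, float] = (50.0, 2.5, 5.0),
                windows_days: tuple[int, ...] = (7, 14),
                min_matches: int = 1) -> tuple[pd.Series, pd.Series]:
    """Fill gaps by averaging records under similar meteorological conditions.

    Reduced marginal-distribution-sampling scheme: for each gap, records
    within +-``windows_days[0]`` days whose SW_IN, TA and VPD lie within
    ``tolerances`` (W m-2, degC, hPa) of the gap's conditions are averaged;
    failing that the window expands, and as a last resort the mean diurnal
    course (same time of day +-1 h, +-7 then +-14 days) is used.

    Returns the filled series and a quality class: 0 = observed, 1/2 =
    similarity fill at the two window sizes, 3 = mean-diurnal-course fill,
    NaN = unfillable.  Observed values are never altered.
    """
    vals = series.to_numpy(float).copy()
    qc = np.zeros(len(vals))
    sw = sw_in.to_numpy(float)
    ta_v = ta.to_numpy(float)
    vpd_v = vpd.to_numpy(float)
    finite = np.isfinite(vals)
    gaps = np.flatnonzero(~finite)
    qc[~finite] = np.nan
    per_day = 48
    tol_sw, tol_ta, tol_vpd = tolerances

    for i in gaps:
        filled = False
        drivers_ok = np.isfinite(sw[i]) and np.isfinite(ta_v[i]) and np.isfinite(vpd_v[i])
        if drivers_ok:
            for wi, wdays in enumerate(windows_days, start=1):
                lo, hi = max(0, i - wdays * per_day), min(len(vals), i + wdays * per_day + 1)
                sl = slice(lo, hi)
                cand = (finite[sl]
                        & (np.abs(sw[sl] - sw[i]) <= tol_sw)
                        & (np.abs(ta_v[sl] - ta_v[i]) <= tol_ta)
                        & (np.abs(vpd_v[sl] - vpd_v[i]) <= tol_vpd))
                if cand.sum() >= min_matches:
                    vals[i] = vals[sl][cand].mean()
                    qc[i] = wi
                    filled = True
                    break
        if not filled:
            for wdays in (7, 14):
                offsets = np.arange(-wdays * per_day, wdays * per_day + 1, per_day)
                idx = np.concatenate([i + offsets + d for d in (-2, -1, 0, 1, 2)])
                idx = idx[(idx >= 0) & (idx < len(vals))]
                ok = finite[idx]
                if ok.sum() >= min_matches:
                    vals[i] = vals[idx][ok].mean()
                    qc[i] = 3
                    break
    return (pd.Series(vals, index=series.index),
            pd.Series(qc, index=series.index))


def gapfill_table(table: FluxTable, variables: tuple[str, ...] = ("H", "LE"),
                  mask: pd.DataFrame | None = None) -> FluxTable:
    """Gap-fill ``variables`` in a copy of ``table`` (columns ``VAR_F`` and
    ``VAR_FQC`` appended).  An optional keep-mask marks additional records
    as gaps (e.g. u*-filtered intervals) before filling."""
    t = table.copy()
    df = t.data
    ta, rh = df["TA"], df["RH"]
    vpd = pd.Series(vpd_from_ta_rh(ta.to_numpy(float), rh.to_numpy(float)), df.index)
    for var in variables:
        if var not in df:
            continue
        s = df[var].copy()
        if mask is not None and var in mask:
            s[~mask[var]] = np.nan
        filled, fqc = mds_gapfill(s, df["SW_IN"], ta, vpd)
        df[f"{var}_F"], df[f"{var}_FQC"] = filled, fqc
    return t
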