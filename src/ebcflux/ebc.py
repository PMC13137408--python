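"""Energy-balance-closure metrics: the AE formulation ladder, OLS/RMA
regressions, bulk ratios over aggregation windows, group tests and
imbalance diagnostics.

The closure statistic of record is the reduced-major-axis (RMA) slope of
turbulent energy TE = H + LE against available energy AE: RMA treats both
variables as error-laden, with slope sign(r) * s_TE / s_AE, whereas OLS of
TE on AE attenuates whenever AE carries noise.  The energy balance bulk
ratio EBR = sum(TE) / sum(AE) complements the regressions at daily to
annual aggregation (computed from gap-filled series so the sums cover the
same intervals).

Available-energy ladder (progressively more complete accounting):

====  ================================================
AE1   NETRAD
AE2   NETRAD - G
AE3   NETRAD - G - S_G
AE4   NETRAD - G - S_G - S_H - S_LE
AE5   AE4 - S_PHO
AE6   AE5 - S_BIO
====  ================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import FluxTable, SiteMeta
from .constants import HALF_HOUR_S

AE_FORMULATIONS = ("AE1", "AE2", "AE3", "AE4", "AE5", "AE6")

#: storage columns subtracted at each ladder step beyond the previous one
_AE_STEPS: dict[str, list[str]] = {
    "AE1": [],
    "AE2": ["G"],
    "AE3": ["G", "S_G"],
    "AE4": ["G", "S_G", "S_H", "S_LE"],
    "AE5": ["G", "S_G", "S_H", "S_LE", "S_PHO"],
    "AE6": ["G", "S_G", "S_H", "S_LE", "S_PHO", "S_BIO"],
}

WINDOW_FREQ = {"daily": "D", "weekly": "W", "monthly": "MS",
               "seasonal": "QS-JAN", "annual": "YS"}


@dataclass
class EBCResult:
    """One closure estimate: a regression slope or a bulk ratio."""

    method: str                      # "OLS" | "RMA" | "EBR"
    slope: float                     # slope or ratio (dimensionless)
    intercept: float                 # W m-2 (NaN for EBR)
    ci_low: float
    ci_high: float
    n: int
    ae_formulation: str = ""
    te_tier: str = ""
    window: str = "halfhourly"

    def __post_init__(self) -> None:
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            if self.ci_low > self.ci_high:
                raise ValueError("ci_low > ci_high")


def build_ae(table: FluxTable, formulation: str, meta: SiteMeta | None = None,
             use_profile: bool = True) -> pd.Series:
    """Available-energy series for one ladder formulation.

    Missing component values propagate to a missing AE at that interval.
    When the site lacks air profiles (``meta.has_profile`` False) or
    ``use_profile`` is False, the one-point storage columns substitute for
    S_H / S_LE.
    """
    if formulation not in _AE_STEPS:
        raise ValueError(f"unknown formulation {formulation!r}")
    df = table.data
    if "NETRAD" in df:
        ae = df["NETRAD"].astype(float).copy()
    else:
        ae = (df["SW_IN"] + df["LW_IN"] - df["SW_OUT"] - df["LW_OUT"]).astype(float)
    one_point = not use_profile or (meta is not None and not meta.has_profile)
    for term in _AE_STEPS[formulation]:
        col = term
        if one_point and term in ("S_H", "S_LE"):
            col = f"{term}_1P"
        if col not in df:
            raise KeyError(f"{formulation} needs column {col}")
        ae = ae - df[col]
    return ae.rename(formulation)


def turbulent_energy(table: FluxTable, keep: pd.DataFrame | None = None,
                     gapfilled: bool = False) -> pd.Series:
    """TE = H + LE, optionally masked by a tier keep-mask per flux."""
    suffix = "_F" if gapfilled else ""
    h = table.data[f"H{suffix}"].astype(float).copy()
    le = table.data[f"LE{suffix}"].astype(float).copy()
    if keep is not None:
        if "H" in keep:
            h[~keep["H"]] = np.nan
        if "LE" in keep:
            le[~keep["LE"]] = np.nan
    return (h + le).rename("TE")


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------

def _paired(te, ae) -> tuple[np.ndarray, np.ndarray]:
    te = np.asarray(te, dtype=float)
    ae = np.asarray(ae, dtype=float)
    ok = np.isfinite(te) & np.isfinite(ae)
    return te[ok], ae[ok]

def rma_slope(te: np.ndarray, ae: np.ndarray) -> tuple[float, float]:
    """Closed-form RMA line of TE on AE: slope = sign(r) s_TE/s_AE."""
    r = np.corrcoef(ae, te)[0, 1]
    s = np.sign(r) if r != 0 else 1.0
    slope = s * te.std(ddof=1) / ae.std(ddof=1)
    return slope, te.mean() - slope * ae.mean()


def rma_fit(te, ae, n_boot: int = 1000, seed: int | np.random.Generator = 0,
            **labels) -> EBCResult:
    """Reduced-major-axis regression with a nonparametric bootstrap CI.

    The 95 % CI resamples intervals with replacement (``n_boot`` draws,
    seeded); ``n_boot=0`` skips the bootstrap (CIs NaN).
    """
    te, ae = _paired(te, ae)
    if len(te) < 3:
        raise ValueError("need >= 3 paired finite values")
    if ae.std(ddof=1) == 0:
        raise ValueError("zero variance in AE")
    slope, intercept = rma_slope(te, ae)
    lo = hi = np.nan
    if n_boot:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        boots = np.empty(n_boot)
        chunk = max(1, int(2e6 // len(te)))
        done = 0
        while done < n_boot:
            m = min(chunk, n_boot - done)
            idx = rng.integers(0, len(te), size=(m, len(te)))
            x, y = ae[idx], te[idx]
            sx = x.std(axis=1, ddof=1)
            sy = y.std(axis=1, ddof=1)
            xc = x - x.mean(axis=1, keepdims=True)
            yc = y - y.mean(axis=1, keepdims=True)
            r = (xc * yc).mean(axis=1) / (x.std(axis=1) * y.std(axis=1))
            boots[done:done + m] = np.where(r >= 0, 1.0, -1.0) * sy / np.where(sx > 0, sx, np.nan)
            done += m
        lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return EBCResult("RMA", float(slope), float(intercept), float(lo), float(hi),
                     len(te), **labels)


def ols_fit(te, ae, **labels) -> EBCResult:
    """Ordinary least squares of TE on AE (95 % CI from the slope's
    standard error); attenuates under AE noise, kept for comparison."""
    te, ae = _paired(te, ae)
    if len(te) < 3:
        raise ValueError("need >= 3 paired finite values")
    if ae.std(ddof=1) == 0:
        raise ValueError("zero variance in AE")
    res = sps.linregress(ae, te)
    tcrit = sps.t.ppf(0.975, len(te) - 2)
    return EBCResult("OLS", float(res.slope), float(res.intercept),
                     float(res.slope - tcrit * res.stderr),
                     float(res.slope + tcrit * res.stderr), len(te), **labels)


# ---------------------------------------------------------------------------
# Bulk ratio
# ---------------------------------------------------------------------------

def bulk_ratio(te: pd.Series, ae: pd.Series, window: str = "annual",
               min_abs_ae_j: float = 1e6, iqr_trim: bool = False
               ) -> pd.DataFrame:
    """Energy balance bulk ratio EBR = sum(TE)/sum(AE) per window.

    ``window``: halfhourly | daily | weekly | monthly | seasonal | annual.
    Windows whose |sum(AE)| integrates to less than ``min_abs_ae_j`` J m-2
    are excluded (near-zero-energy windows make the ratio meaningless).
    Intervals where either series is missing are excluded from both sums.
    ``iqr_trim`` drops windows outside Q1 - 1.5 IQR .. Q3 + 1.5 IQR of the
    EBR distribution, mirroring outlier removal in aggregation plots.
    """
    ok = te.notna() & ae.notna()
    te, ae = te[ok], ae[ok]
    if window == "halfhourly":
        grp_te, grp_ae = te, ae
        n = pd.Series(1, index=te.index)
    else:
        freq = WINDOW_FREQ[window]
        grp_te = te.resample(freq).sum(min_count=1)
        grp_ae = ae.resample(freq).sum(min_count=1)
        n = te.resample(freq).count()
    out = pd.DataFrame({"te_sum": grp_te, "ae_sum": grp_ae, "n": n})
    out = out.dropna(subset=["te_sum", "ae_sum"])
    out = out[np.abs(out["ae_sum"]) * HALF_HOUR_S >= min_abs_ae_j]
    out["ebr"] = out["te_sum"] / out["ae_sum"]
    if iqr_trim and len(out) > 3:
        q1, q3 = out["ebr"].quantile([0.25, 0.75])
        iqr = q3 - q1
        out = out[(out["ebr"] >= q1 - 1.5 * iqr) & (out["ebr"] <= q3 + 1.5 * iqr)]
    return out


def bulk_ratio_result(te: pd.Series, ae: pd.Series, window: str = "annual",
                      n_boot: int = 1000, seed: int = 0, **labels) -> EBCResult:
    """Aggregate EBR over all windows (sum of sums) with a bootstrap CI
    across windows."""
    per = bulk_ratio(te, ae, window)
    if per.empty:
        raise ValueError("no valid windows")
    ratio = per["te_sum"].sum() / per["ae_sum"].sum()
    lo = hi = np.nan
    if n_boot and len(per) > 1:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(per), size=(n_boot, len(per)))
        t = per["te_sum"].to_numpy()[idx].sum(axis=1)
        a = per["ae_sum"].to_numpy()[idx].sum(axis=1)
        good = a != 0
        lo, hi = np.percentile(t[good] / a[good], [2.5, 97.5])
    return EBCResult("EBR", float(ratio), np.nan, float(lo), float(hi),
                     int(per["n"].sum()), window=window, **labels)


# ---------------------------------------------------------------------------
# Ladder analysis
# ---------------------------------------------------------------------------

@dataclass
class LadderReport:
    """Slope matrix over AE formulations x TE tiers plus stepwise deltas
    and per-window bulk ratios."""

    slopes: pd.DataFrame                     # index AE1..AE6, cols tiers
    n: pd.DataFrame
    ci: dict[tuple[str, str], tuple[float, float]]
    stepwise_deltas_pct: pd.Series           # Fig-1-style sequence
    ebr_by_window: pd.DataFrame = field(default_factory=pd.DataFrame)


def ladder_analysis(table: FluxTable, meta: SiteMeta,
                    tiers: dict, use_profile: bool = True,
                    n_boot: int = 0, seed: int = 0,
                    ebr_windows: tuple[str, ...] = (),
                    gapfilled_table: FluxTable | None = None) -> LadderReport:
    """RMA slope matrix for every AE formulation x TE tier pairing.

    ``tiers`` comes from :func:`ebcflux.qc.build_tiers`.  Stepwise deltas
    follow the ladder at the fullQC tier (each step vs the previous slope)
    and finish with the u*-filter step at AE6.  When ``ebr_windows`` and a
    gap-filled table are supplied, per-window bulk-ratio curves for AE1 and
    AE6 (u* tier) are included.
    """
    slopes = pd.DataFrame(index=list(AE_FORMULATIONS), columns=list(tiers), dtype=float)
    ns = slopes.copy()
    cis: dict[tuple[str, str], tuple[float, float]] = {}
    for ae_name in AE_FORMULATIONS:
        ae = build_ae(table, ae_name, meta, use_profile)
        for tier_name, tier in tiers.items():
            te = turbulent_energy(table, tier.keep)
            try:
                res = rma_fit(te, ae, n_boot=n_boot, seed=seed,
                              ae_formulation=ae_name, te_tier=tier_name)
            except ValueError:
                continue
            slopes.loc[ae_name, tier_name] = res.slope
            ns.loc[ae_name, tier_name] = res.n
            cis[(ae_name, tier_name)] = (res.ci_low, res.ci_high)

    seq = [("AE1", "fullQC")] + [(a, "fullQC") for a in AE_FORMULATIONS[1:]]
    seq.append(("AE6", "ustar_filter"))
    labels, deltas = [], []
    prev = None
    for ae_name, tier_name in seq:
        val = slopes.loc[ae_name, tier_name]
        label = f"{ae_name}({tier_name})" if tier_name != "fullQC" else ae_name
        if prev is not None and np.isfinite(val) and np.isfinite(prev) and prev != 0:
            deltas.append(100.0 * (val - prev) / abs(prev))
            labels.append(label)
        prev = val
    report = LadderReport(slopes, ns, cis,
                          pd.Series(deltas, index=labels, name="delta_pct"))

    if ebr_windows and gapfilled_table is not None:
        rows = []
        te_f = turbulent_energy(gapfilled_table, gapfilled=True)
        for ae_name in ("AE1", "AE6"):
            ae_f = build_ae(gapfilled_table, ae_name, meta, use_profile)
            for window in ebr_windows:
                try:
                    r = bulk_ratio_result(te_f, ae_f, window, n_boot=0)
                except (ValueError, KeyError):
                    continue
                rows.append({"ae": ae_name, "window": window,
                             "ebr": r.slope, "n": r.n})
        report.ebr_by_window = pd.DataFrame(rows)
    return report


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------

def group_tests(slopes: pd.Series, groups: pd.Series, alpha: float = 0.05,
                correction: str = "holm") -> dict:
    """Kruskal-Wallis across groups plus pairwise rank-sum tests.

    Groups with fewer than 2 members are excluded (reported in
    ``excluded``).  Pairwise Wilcoxon rank-sum (Mann-Whitney) p-values are
    corrected for multiple testing (Holm by default).
    """
    df = pd.DataFrame({"slope": slopes, "group": groups}).dropna()
    sizes = df.groupby("group").size()
    excluded = sizes[sizes < 2].index.tolist()
    df = df[~df["group"].isin(excluded)]
    names = sorted(df["group"].unique())
    if len(names) < 2:
        raise ValueError("need >= 2 groups with >= 2 members")
    samples = [df.loc[df["group"] == g, "slope"].to_numpy() for g in names]
    kw_stat, kw_p = sps.kruskal(*samples)
    pairs, raw_p = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            stat, p = sps.mannwhitneyu(samples[i], samples[j],
                                       alternative="two-sided")
            pairs.append((names[i], names[j]))
            raw_p.append(p)
    reject, p_adj, _, _ = multipletests(raw_p, alpha=alpha, method=correction)
    pairwise = pd.DataFrame({"group_a": [a for a, _ in pairs],
                             "group_b": [b for _, b in pairs],
                             "p_raw": raw_p, "p_adj": p_adj,
                             "significant": reject})
    return {"kruskal_stat": float(kw_stat), "kruskal_p": float(kw_p),
            "pairwise": pairwise, "excluded": excluded}


# ---------------------------------------------------------------------------
# Imbalance diagnostics
# ---------------------------------------------------------------------------

def summer_daytime_imbalance(table: FluxTable, meta: SiteMeta,
                             months: tuple[int, ...] = (6, 7, 8),
                             daytime: str = "solar", n_boot: int = 1000,
                             seed: int = 0) -> dict:
    """Mean summer-daytime half-hourly imbalance AE6 - TE per year (W m-2)
    with a bootstrap CI over the yearly means.

    ``daytime``: "solar" (solar elevation > 0) or "sw_in" (SW_IN > 20).
    """
    from . import solar as _solar
    df = table.data
    ae = build_ae(table, "AE6", meta)
    te = turbulent_energy(table)
    if daytime == "solar":
        elev = _solar.solar_state(df.index, meta.latitude, meta.longitude).elevation
        is_day = elev > 0
    else:
        is_day = df["SW_IN"].fillna(0).to_numpy() > 20.0
    sel = df.index.month.isin(months) & is_day
    imb = (ae - te)[sel].dropna()
    if imb.empty:
        raise ValueError("no summer daytime data")
    yearly = imb.groupby(imb.index.year).mean()
    rng = np.random.default_rng(seed)
    if len(yearly) > 1:
        draws = rng.choice(yearly.to_numpy(), size=(n_boot, len(yearly))).mean(axis=1)
        ci = tuple(np.percentile(draws, [2.5, 97.5]))
    else:
        ci = (np.nan, np.nan)
    return {"mean": float(yearly.mean()), "ci": ci,
            "yearly": yearly, "n": int(imb.size)}


def annual_median_abs_imbalance(table: FluxTable, meta: SiteMeta) -> pd.Series:
    """Annual median of absolute half-hourly imbalance |AE6 - TE| (W m-2)."""
    imb = (build_ae(table, "AE6", meta) - turbulent_energy(table)).dropna()
    return imb.abs().groupby(imb.index.year).median()


def imbalance_vs_biomass(imbalance: pd.Series, biomass: pd.Series) -> dict:
    """OLS of per-site median absolute imbalance on wet biomass.

    Returns intercept (baseline imbalance at zero biomass, W m-2), slope
    (W m-2 per kg m-2), R^2 and 95 % CIs of both coefficients.
    """
    import statsmodels.api as sm
    df = pd.DataFrame({"imb": imbalance, "bio": biomass}).dropna()
    model = sm.OLS(df["imb"], sm.add_constant(df["bio"])).fit()
    ci = model.conf_int(alpha=0.05)
    return {"intercept": float(model.params.iloc[0]),
            "slope": float(model.params.iloc[1]),
            "r2": float(model.rsquared),
            "intercept_ci": tuple(ci.iloc[0]),
            "slope_ci": tuple(ci.iloc[1]),
            "p_slope": float(model.pvalues.iloc[1]),
            "n": int(model.nobs)}
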