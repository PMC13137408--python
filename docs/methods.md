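# Methods

This note documents the models and procedures implemented in `ebcflux`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical choices that matter.

## Energy balance accounting

The surface energy balance at an eddy-covariance station requires, for
every 30-min averaging interval, that turbulent energy TE = H + LE equal
the available energy

AE = NETRAD − G − S_G − S_H − S_LE − S_pho − S_bio,

assuming no advective or lateral fluxes. Sign convention throughout the
package: a storage term is **positive when energy leaves the available
pool** (into soil, air, biomass or fixed carbon), so every term is
subtracted. The photosynthetic term deserves a note: the defining formula
S_pho = −μ·GPP yields a negative number (energy absorbed into chemical
storage); the table column `S_PHO` stores its magnitude +μ·GPP so that the
AE ladder subtracts it uniformly with the other terms. `ebcflux`
deliberately evaluates six nested AE formulations (AE1 = NETRAD only up to
the full AE6) against three turbulent-energy quality tiers, because the
point of the accounting is to show how much of the closure gap each term
explains.

### Storage terms

* **Soil (S_G):** calorimetric storage in the layer above the heat-flux
  plates (default plate depth 0.05 m), S_G = Σ c_s,i ΔT_s,i/Δt Δz_i. The
  volumetric heat capacity uses the simplest de Vries-type mixing rule
  c_s = c_dry + θ·c_w with c_w = 4.18 MJ m⁻³ K⁻¹ and configurable dry
  matrix capacity (default 1.2 MJ m⁻³ K⁻¹, a typical mineral soil).
  Replicate plates are spatially averaged over whatever plates report at
  each interval, with the count recorded.
* **Air column (S_H, S_LE):** S_H = ρ_a c_p Σ ΔTA_i/Δt Δz_i and
  S_LE = ρ_d λ M_w Σ ΔX_w,i/Δt Δz_i over profile levels up to the EC
  height z_m. Air densities come from the ideal-gas law at the interval's
  TA and PA (barometric fallback from site elevation when PA is absent);
  the latent heat of vaporization is the constant 2.45 MJ kg⁻¹. Each
  profile level represents the slab from the midpoint below to the
  midpoint above, bounded by the surface and z_m — the level-to-slab
  attribution is a choice, made once. One-point variants treat the column
  as a single slab carrying the top-of-column values (no vertical gradient
  below z_m); profile and one-point forms agree exactly for vertically
  uniform columns, which is the regression test for both code paths.
* **Photosynthesis (S_pho):** μ·GPP with μ = 10.88 MJ (kg CO₂)⁻¹ and GPP
  converted via the CO₂ molar mass 0.044 kg mol⁻¹. Negative GPP values
  (flux-partitioning artifacts) pass through unchanged by default; a
  clamp-at-zero switch exists. Sublimation is not distinguished from
  evaporation.
* **Biomass (S_bio):** m_v c_v ΔT_v/Δt with c_v = 2958 J kg⁻¹ K⁻¹ and wet
  biomass from dry inventory via a dry-to-fresh factor of 2. Biomass
  temperature change is proxied by the thickness-weighted column-mean air
  temperature change over the full column (air temperature is known to lag
  true canopy temperature; this underestimates S_bio under strong daytime
  heating — a recognized limitation, configurable through the profile
  weighting hook).

### Net-radiation corrections

Four independent corrections, each producing its own NETRAD variant from
the measured baseline — they are evaluated separately, never chained, so
their individual effect on closure can be compared:

1. **Terrain slope.** SW_IN(ψ) = SW_IN·exp(−k_t(ψ² − θ_s²))·(1 − ALB·sin²(ψ/2)),
   angles in radians, with ψ the sun–slope-normal incidence angle and k_t
   the clearness index. Applied only where the landscape slope reaches 2°
   (configurable). The albedo factor is applied as a multiplier; a
   `divide` switch exists because the source expression's rendering is
   typographically ambiguous. Per-interval albedo is SW_OUT/SW_IN clamped
   to [0.01, 0.99] with a daily-median fallback when SW_IN < 50 W m⁻²
   (the ratio is unstable at low sun; the guard is ours).
2. **Topographic shadowing.** The horizon elevation per 1° azimuth bin is
   extracted from a DEM by sampling rays at half-cell steps (planar
   geometry, adequate for ≤ 20 km frames). When the solar elevation is
   below the local horizon, SW_IN is reduced to its diffuse component;
   the reflected component is neglected. The diffuse fraction uses the
   two-predictor Reindl correlation in k_t and sin(elevation), with k_t
   clamped to [0.05, 0.98], each branch carrying its published constraint
   interval; continuity at branch edges is not guaranteed and not
   required. The correlation is only evaluated where extraterrestrial
   irradiance is positive and SW_IN exceeds 5 W m⁻².
3. **Tower interference.** The mounting tower is modelled as a vertical
   rectangle (width = cross-section × (1 − 0.40) lattice void reduction;
   height = radiometer mount height minus canopy height) whose solid angle
   from the sensor follows the exact corner-decomposition formula
   Ω = 2·atan(w/2·h / (D√((w/2)² + h² + D²))). The disturbance fraction
   δ_frac = Ω/Ω_FoV (Ω_FoV = 2π(1 − cos(FoV/2)); 170° for pyranometers,
   150° for pyrgeometers) enters linear mixing rules for FoV albedo and
   emissivity (tower albedo 0.2, emissivity 0.3), which are inverted for
   the ground values and used to rescale SW_OUT and LW_OUT. The
   radiometric emissivity retrieval uses T_surf ≈ TA + 4 K (day) / + 2 K
   (night), τ = 1, LW_ATM = 0. Two denominator readings are implemented:
   the literal (σT⁴ − LW_OUT) and the standard Jin–Liang-style
   (σT⁴ − LW_IN); the literal form frequently yields non-physical
   emissivities for typical mid-latitude values and such intervals are
   flagged and passed through rather than clipped.
4. **FoV/footprint mismatch.** Ratios δ_SW = SR_rad/SR_EC and
   δ_LW = LST_rad/LST_EC of disc-weighted vs footprint-weighted means over
   surface-reflectance and land-surface-temperature rasters rescale SW_OUT
   and LW_OUT. A ratio is undefined when fewer than 50 % of the pixels in
   either region are valid; the correction applies only where the
   footprint/disc overlap is below 60 % of the larger area.

### Quality tiers and u* filtering

Three nested tiers: `uncorrected` (plausibility ranges only, closed
intervals, defaults H ∈ [−250, 800], LE ∈ [−100, 800] W m⁻²), `fullQC`
(additionally drops network flag = 2; flags are consumed, never
recomputed), and `ustar_filter` (additionally drops u* below a
site-specific threshold). Mask nesting is guaranteed by construction. The
u* filter applies to all hours by default — low-turbulence advection is
not an exclusively nocturnal problem — with a night-only mode available.

The threshold estimator is a moving-point change detection: nocturnal
records are split by season (calendar quarters) and into 6 temperature
classes (quantiles); within a class, 20 u* quantile classes are scanned
upward and the threshold is the mean u* of the first class whose mean flux
reaches 99 % of the mean over the following up-to-10 classes. Classes with
|corr(TA, u*)| > 0.4 are excluded (temperature-driven flux variation would
masquerade as a u* effect). The flux series is sign-normalized so the
saturation test always reads upward. A season's value is the median over
temperature classes and the site value the maximum over seasons — the
conservative aggregation of the cited change-point method. With 20
quantile classes the detected value sits at the centre of the first
unsuppressed class, typically ~0.02–0.03 m s⁻¹ above a sharp true change
point; this resolution limit is inherent to class-based detection.

### Gap filling

A reduced marginal-distribution-sampling scheme ("MDS-like", not a full
network-pipeline replication): a gap is filled by the mean of records with
similar meteorology (SW_IN ± 50 W m⁻², TA ± 2.5 °C, VPD ± 5 hPa; VPD from
TA/RH via the Magnus saturation-pressure form) within ± 7 days, then ± 14
days, then by the mean diurnal course (same time of day ± 1 h over ± 7 and
± 14 days). The fill class (1/2/3) is recorded; unfillable gaps remain
missing and observed values are never altered.

### Closure metrics

RMA regression is the closure statistic of record: slope =
sign(r)·s_TE/s_AE, intercept through the means, 95 % CI by nonparametric
bootstrap over intervals (1000 resamples, seeded; resampling is chunked to
bound memory). OLS is kept for comparison — it attenuates when AE carries
noise, which is the reason RMA is preferred. Half-hourly regressions use
non-gap-filled data; bulk ratios (EBR = ΣTE/ΣAE per daily/weekly/monthly/
seasonal/annual window) use gap-filled data so the sums cover identical
intervals. Windows whose |ΣAE| integrates below 1 MJ m⁻² are excluded
(near-zero-energy windows make the ratio meaningless; the floor is ours),
and an optional IQR trim (1.5×IQR fences) cleans window distributions for
display. Aggregation windows group records by the calendar date of the
end-of-interval stamp, so a day's first record is the one stamped 00:30
and the record stamped midnight belongs to the following day.

Stepwise ladder deltas are percentage changes of each slope relative to
the previous step along AE1→AE6 (fullQC tier) finishing with the u*-filter
step at AE6. Group comparisons use Kruskal–Wallis across groups and
pairwise Wilcoxon rank-sum tests with Holm correction (the correction
method is a choice; any `statsmodels` method name is accepted). Imbalance
diagnostics report (a) summer (June–August, configurable for hemisphere)
daytime (solar elevation > 0, or SW_IN > 20 W m⁻² switchable) mean
half-hourly imbalance AE6 − TE per year with a bootstrap CI over yearly
means, and (b) OLS of the annual median absolute half-hourly imbalance on
wet biomass across sites.

## Timestamp and missing-data conventions

Records are stamped end-of-interval, covering (t − 30 min, t] — the
FLUXNET `TIMESTAMP_END` practice; network archives do not always state
their convention, so this is a documented choice. Solar geometry is
evaluated at the interval midpoint (t − 900 s). On disk missing values are
−9999; in memory they are NaN. Unit normalization (K→°C, Pa→kPa,
fraction→% RH) is threshold-based and idempotent.

## Solar geometry

Solar position uses the Astronomical Almanac low-precision algorithm
(Michalsky 1988), accurate to ~0.01° over 1950–2050; the test suite
cross-checks it against an independently coded second published algorithm
(NOAA solar-calculator equations) to < 0.2° over random instants at three
latitudes. Extraterrestrial horizontal irradiance is S₀·E₀·cos θ_s with
S₀ = 1361 W m⁻² and the standard day-angle cosine eccentricity factor
E₀ = 1 + 0.033·cos(2π·doy/365). No refraction correction is applied;
day/night decisions use geometric elevation.

## The synthetic generator

`generate_site` builds a half-hourly year (or any span) whose ground truth
is known exactly. Radiation: SW_IN = G0h·k_t with k_t an AR(1) process
(mean 0.6, lag-1 correlation 0.8, clipped to [0.05, 0.95] — a realistic
mid-latitude clearness spread); longwave terms from TA via
Stefan–Boltzmann with bulk emissivities; surface temperature exceeds TA in
proportion to insolation. Temperature: seasonal + diurnal sinusoids plus
AR(1) noise. Soil layers and soil heat flux respond to the surface with
first-order damping and lag, so the calorimetric modules produce realistic
nonzero storage; the air profile damps the diurnal cycle with height; GPP
follows a light-response curve with a seasonal envelope; the Bowen ratio
swings seasonally over 0.5–2 to exercise both H- and LE-dominated regimes.

The central construction: AE_true is assembled by the package's **own**
storage accounting on the generated profiles, and TE_true = f·AE_true at
every interval before noise. Energy conservation therefore holds by
construction and the imposed closure fraction f is the quantity every
metric must recover — exactly (to float precision) in the noise-free case,
within sampling error under noise. Degradations are applied in order:
nocturnal suppression (TE × factor where night and u* < threshold, with
nocturnal u* lognormal around a 0.28 m s⁻¹ median — a realistic forest
night), multiplicative and additive noise per flux, quality flags (2 %
flag-2, 5 % flag-1), and gaps in geometric-length runs (mean run 4
intervals) so the MDS windows are exercised by multi-interval holes.

What the generator does **not** emulate: mesoscale/advective transport
(the irreducible closure-gap candidate), instrument-specific spectral
attenuation, wetland water-column storage, precipitation events, or
horizontal heterogeneity of the flux footprint. Passing parameter-recovery
tests therefore demonstrates that the accounting and statistics are
implemented correctly — not that any particular real site will close.

DEM fixtures (`flat`, `single_peak`, `ridge`) and raster fixtures
(`homogeneous`, `two_patch`, `gradient`, with a 70 %-clipped Gaussian
footprint and an equal-weight radiometer disc) have closed-form horizon
angles and weighted means for use as analytic oracles.

## Numerical choices and degenerate inputs

- Storage terms are temporal differences; the first interval of any series
  is undefined (NaN) and propagates.
- RMA requires ≥ 3 paired finite values and nonzero AE variance; bulk
  ratios skip empty and low-energy windows; group tests exclude groups
  with fewer than 2 members (reported, not silent).
- Radiometric inversions (tower albedo/emissivity) that go non-physical
  are flagged and passed through, never clipped.
- All randomness (generator, bootstrap, Monte-Carlo oracles) is seeded;
  the test suite and the acceptance script are deterministic given their
  seeds.
- Problem sizes: the acceptance script uses 5 one-year realizations for
  closure recovery, 10 for threshold recovery, 20 random tower geometries
  × 10⁶ Monte-Carlo points, 100 null simulations for test calibration and
  20 × 20-site replicates for the imbalance regression — sizes at which
  every sampling error is comfortably below the tolerances being checked
  while the whole script runs in seconds.

## Known limitations

- Air temperature as the biomass-temperature proxy biases S_bio low in
  tall canopies under daytime heating.
- The reduced MDS filler ignores the look-up-table hierarchy of full
  network pipelines; fill quality classes are coarser.
- The horizon scan uses nearest-cell sampling; horizon angles are accurate
  to ~0.1° at 30 m cell size, degrading for very near obstacles.
- The u* threshold inherits the class-resolution bias described above.
- No netCDF/HDF ingestion and no network API clients — plain text formats
  only, by design.
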