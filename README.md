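# ebcflux

Surface energy-balance-closure accounting and diagnostics for half-hourly
eddy-covariance (EC) flux-tower data.

At an EC station the turbulent energy TE = H + LE (sensible plus latent
heat flux) should balance the available energy at the surface. In practice
the regression of TE on net radiation alone closes at only ~70–80 %; a
large part of that gap is not measurement error but energy bookkeeping —
heat flowing into soil, air, biomass and photosynthetic products below the
measurement height. `ebcflux` implements the complete accounting:

```
AE = NETRAD − G − S_G − S_H − S_LE − S_pho − S_bio
```

where `NETRAD = SW_IN + LW_IN − SW_OUT − LW_OUT`, `G` is the measured soil
heat flux (plate mean), `S_G = Σ c_s,i ΔT_s,i/Δt Δz_i` the calorimetric
heat storage in the soil above the plates, `S_H = ρ_a c_p Σ ΔTA_i/Δt Δz_i`
and `S_LE = ρ_d λ M_w Σ ΔX_w,i/Δt Δz_i` the air-column heat and moisture
storage below the EC height (profile or one-point form), `S_pho = μ·GPP`
the biochemical energy fixed by photosynthesis (μ = 10.88 MJ per kg CO₂),
and `S_bio = m_v c_v ΔT_v/Δt` the heat stored in above-ground biomass
(c_v = 2958 J kg⁻¹ K⁻¹).

The package provides:

- **storage terms** — all five calorimetric/biochemical terms above, from
  FLUXNET/ICOS-style profile columns;
- **net-radiation corrections** — terrain slope (Olmo-type clearness-index
  correction), topographic horizon shadowing from a DEM (with Reindl
  diffuse-fraction partitioning), mounting-tower field-of-view interference
  (exact rectangular solid angle), and radiometer-FoV / flux-footprint
  mismatch from surface-reflectance and land-surface-temperature rasters;
- **quality tiers** — plausibility screening, network-flag filtering and
  friction-velocity (u*) threshold filtering with Papale-style moving-point
  detection, plus MDS-like gap filling;
- **closure metrics** — reduced-major-axis (RMA) regression
  (slope = sign(r)·s_TE/s_AE, bootstrap CIs), OLS for comparison, and the
  energy balance bulk ratio EBR = ΣTE/ΣAE from daily to annual windows,
  over the full AE1…AE6 × quality-tier ladder;
- **a synthetic tower generator** with known ground truth (imposed closure
  fraction, storage amplitudes, noise, gaps, nocturnal low-u* suppression,
  analytic DEM/raster fixtures) so every stage is testable by parameter
  recovery.

## Worked example

Generate a year of synthetic data for a temperate site with an imposed
closure fraction of 0.85, 10 % flux noise, 5 % gaps and nocturnal flux
suppression below u* = 0.25 m s⁻¹, then run the full ladder analysis:

```python
from ebcflux import synthetic, qc, ebc

meta = synthetic.default_site_meta()
truth = synthetic.TruthRecord(closure_fraction=0.85, noise_mult=0.10,
                              gap_fraction=0.05, ustar_threshold=0.25, seed=7)
table, _ = synthetic.generate_site(meta, truth)

d = table.data
est = qc.estimate_ustar_threshold(d["H"], d["TA"], d["USTAR"], d["SW_IN"] < 12)
print(f"estimated u* threshold: {est.site:.3f} m/s")

tiers = qc.build_tiers(table, est.site)
report = ebc.ladder_analysis(table, meta, tiers)
print(report.slopes.round(3))
print(report.stepwise_deltas_pct.round(2))
```

Output:

```
estimated u* threshold: 0.274 m/s
     uncorrected  fullQC  ustar_filter
AE1        0.622   0.622         0.649
AE2        0.671   0.671         0.699
AE3        0.741   0.741         0.769
AE4        0.782   0.782         0.805
AE5        0.795   0.795         0.819
AE6        0.831   0.831         0.852
AE2                   7.83
AE3                  10.52
AE4                   5.47
AE5                   1.69
AE6                   4.53
AE6(ustar_filter)     2.51
```

Reading this: with net radiation alone (AE1) the apparent closure is 0.62;
subtracting soil heat flux (AE2), soil heat storage (AE3), air-column
storage (AE4), the photosynthetic sink (AE5) and biomass storage (AE6)
raises the RMA slope step by step, and u* filtering of calm nights brings
the slope to 0.852 — recovering the imposed closure fraction of 0.85. The
change-point estimator locates the injected 0.25 m s⁻¹ suppression
threshold at 0.274 m s⁻¹.

The same pipeline is available from the shell:

```
ebcflux generate --seed 4 --days 90 --out site1
ebcflux storage site1/fluxes.csv site1/site.yaml --out site1/with_storage.csv
ebcflux radcorr site1/with_storage.csv site1/site.yaml \
    --corrections slope,shadow,tower,fov --dem site1/dem.asc \
    --sr site1/sr.asc --lst site1/lst.asc \
    --footprint site1/footprint.asc --disc site1/disc.asc \
    --out site1/radcorr.csv
ebcflux filter site1/with_storage.csv site1/site.yaml --ustar auto --out site1/filtered.csv
ebcflux ebc site1/fluxes.csv site1/site.yaml --out site1/report
ebcflux report site1/report
```

## Data formats

Flux tables are plain CSV with FLUXNET-style names (`TIMESTAMP_END` in
`YYYYMMDDHHMM`, −9999 sentinel, profile groups as `VAR_1..VAR_n` with a
JSON sidecar mapping index to height/depth). Site metadata is YAML.
Rasters (DEM, surface reflectance, land-surface temperature, footprint
weights) are single-band ESRI ASCII grids. See `docs/methods.md` for the
model description, parameter defaults and known limitations.
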