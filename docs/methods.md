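# Methods

This note documents the statistical model behind `paddyclim`: what the
synthetic-data generator emulates, how the analysis stages are defined, the
parameters that matter, the numerical choices, and the known limitations.

## 1. What the generator emulates

The analysis chain assumes a causal structure

```
ENSO (Niño3.4)  →(−, 4-month lag)→  Philippine soil moisture
soil moisture   →(+, 1-quarter lag)→  rice harvested area and yield
```

with the soil-moisture response seasonally modulated (weaker in Q3–Q4, the
wet season, when background soils are already wet and rainfall variability is
dominated by storms) and crop sensitivity stronger in rainfed than irrigated
systems. The generator produces every input with this structure and known
parameters, so each downstream estimate can be compared against a prescribed
truth. All generators are pure functions of `(config, seed)`; one master seed
is split into fixed named sub-streams (`enso`, `sst`, `fields`, `crops`,
`ensemble`, `accessions`), so regenerating one input never perturbs another.

### ENSO index
AR(1) in months, x(t) = φ·x(t−1) + σ·a(m)·ε(t), with φ = 0.9 (ENSO-like
decorrelation of ~1 year), σ = 0.25, and a 12-vector of innovation amplitudes
a(m) peaking in boreal winter — the simplest structure giving the observed
winter phase lock of ENSO variance. A 20-year burn-in puts the series in its
stationary distribution. φ = 0 with flat amplitudes degenerates to white
noise (allowed, used as a null case).

### Gridded fields
Soil moisture (units mm) and 2 m temperature (°C) live on a 1° Philippines
box (117–128°E, 4–22°N); SST (°C) on a 2° tropical-Pacific grid covering the
Niño3.4 box. Each anomaly field is

```
b_q · ê(t − 4)  +  σ_c · η(t)  +  σ_l · L(t, x)
```

where ê is the sample-standardized ENSO index, η a domain-common white term
(large-scale weather, sd 0.8) and L locally-correlated noise (white fields
smoothed with an isotropic Gaussian of 2 grid cells, rescaled to exact unit
point-wise variance via the filter's impulse response). Loadings b_q are
derived from per-quarter *target point-wise correlations* (defaults
−0.6, −0.55, −0.35, −0.3 for soil moisture; +0.45 for temperature):
b = r·σ_n/√(1−r²) with σ_n the total point-wise noise sd. Because the driver
is sample-standardized, the prescribed correlation holds in expectation
without knowing how regional averaging attenuates the local noise; box
averages therefore run slightly *stronger* than the point-wise target (the
local term partially cancels). Seasonal climatologies: soil moisture peaks in
September (wet season); the temperature annual cycle (peak May) is calibrated
so observed quarterly box means stay below the 27 °C historical ceiling of
the century-scale record the study design assumes.

### Crop panels
Quarterly, per region × system (irrigated/rainfed), multiplicative so
production stays positive:

```
area(t)  = weight · A0 · cycle_a(q) · (1+g_a)^years · exp(a_anom(t))
yield(t) = Y0 · cycle_y(q) · (1+g_y)^years · exp(y_anom(t))
production = area × yield
```

The log anomalies couple to s(t−1), the standardized realized regional
soil-moisture anomaly of the previous quarter:
`y_anom = ρ·σ_y·s + σ_y·√(1−ρ²)·ε`, so `corr(y_anom, s) = ρ` exactly and σ_y
is the total log-anomaly scale. Defaults: yield coupling 0.3 (irrigated) vs
0.5 (rainfed); harvested area couples at half the yield coupling (planting
decisions respond to water availability, more weakly — the area/yield split
is a free design choice, set once); σ_y ≈ 0.04–0.05 (quarterly yield
anomalies a few percent of the mean), σ_a ≈ 0.06–0.08; area cycle peaking in
Q4 (wet-season crop), irrigated trend ~2%/yr vs flat rainfed area. 1% of
rainfed records (area and production independently) are replaced by missing
markers; irrigated series are complete, mirroring the survey record.

### Warming ensemble and accessions
Each of 18 pseudo-models gets a global annual-mean warming ΔT ~ U(2.6, 4.8) °C
between a present and a future epoch, a warming pattern
1 + gradient·(lat) + seasonal·cos(month) renormalized to area-weighted annual
global mean exactly 1, and a global annual-mean anomaly series with linear
rate ΔT/100 yr⁻¹ plus small noise (for crossing-year analysis). Occurrence
points sample tropical grid cells with weight exp(−(T_annual − 26 °C)²/2σ²),
σ = 1 °C, jittered uniformly inside the sampled cell so the containing cell
of every point is the cell it was drawn from.

## 2. Analysis definitions and parameters

| parameter | default | meaning |
|---|---|---|
| window_quarters | 27 (odd) | running-mean detrend window, ~7 yr ≈ one rice-genotype life cycle |
| sm_lead_quarters | 1 | soil moisture leads crops by one quarter (3 months) |
| enso_sm_lead_months | 4 | Niño3.4 leads soil moisture |
| enso_crop_lead_months | 7 | Niño3.4 leads crops (4 + 3 months) |
| confidence | 0.90 | two-tailed t-test level; critical r ≈ 0.306 at df = 28 |
| display_mask | 0.3 | map cells with smaller \|r\| flagged masked |
| n_eff_national | 30 | effective sample size = number of years |
| warming_targets | 2, 4 °C | global-mean warming scenarios |
| histogram_bin_width | 0.5 °C | bins aligned to integer °C |
| envelope_threshold_c | 28 °C | quarterly tolerance bound for tropical rice |
| envelope_rescale | 4 | display-only rescaling of occurrence counts |

Processing order (recorded in each output's provenance): crop series are
interpolated (linear inside, nearest value at the ends — extrapolating the
trend could go negative), then running-mean-detrended (window truncated to
the available points near the series ends, preserving the full record; a
trim mode is available), then per-quarter climatology-removed. Climate series:
climatology removal over the stated base period, then linear detrend. Monthly
leads are implemented by shifting the monthly series before forming 3-month
means, so a quarter pairs with the 3-month window ending the stated number of
months earlier (a December–February index value pairs with April–June soil
moisture at a 4-month lead); quarter leads cross year boundaries (Q1 pairs
with the previous year's Q4). Pairs lost to lag alignment are dropped, never
wrapped.

Significance treats seasonal anomalies as independent between years:
n_eff = number of years (30) with df = n_eff − 2 = 28, for the pooled national
quarterly correlations as well as the regional maps — not the number of
quarterly data points. p-values are per-cell, not multiplicity-adjusted; the
display mask at |r| < 0.3 is a presentation rule, not a test. Area averages
weight cells by cos(latitude) (membership by cell center; no partial-cell
weighting), which is the correct spherical weighting even though the
difference is small for near-equatorial boxes. Longitude boxes live on
[0, 360) and may wrap across the 0° meridian. Standardization uses the n−1
sample standard deviation everywhere.

Crossing years use a centered running mean of the global annual-mean anomaly,
window 21 years (odd/symmetric ≈ the usual "20-year" smoothing, chosen so the
running mean of a linear ramp equals its center value), full windows only, no
re-baselining by default (the generator's series is already an anomaly);
window and base period are configurable. Non-crossing models are reported,
not raised.

The envelope overlap coefficient (per-quarter histogram intersection of
unit-normalized occurrence vs scenario distributions) is a scalar summary
added by this package — the comparison it summarizes is traditionally made
visually — and is labeled as such in outputs. Rescaling occurrence counts
(the ×4 display factor) changes displayed counts only, never fractions or
overlap.

## 3. Numerical choices

- Missing crop cells are kept as NaN through loading (never coerced to zero);
  zero-area quarters yield missing yield with a warning, not infinities.
- Running-mean edge handling: `truncate` (default) clips the window to the
  available points; `trim` drops the half-window at each end. Both subtract
  the residual mean afterwards, so anomalies have exactly zero mean.
- The Gaussian-smoothed noise normalization computes the exact per-cell
  variance of the filter by pushing unit impulses through it (grids are
  small), rather than assuming an interior-kernel approximation.
- Pattern normalization rejects a global annual-mean change of zero;
  correlation rejects zero-variance inputs (an error, not r = 0); degenerate
  |r| = 1 maps to p = 0 without overflow.
- NetCDF output uses the NETCDF3 (scipy engine) format with CF-style units
  attributes.

## 4. Validation experiments

`pipeline.coupling_recovery_estimate` defines the known-truth recovery
experiment: one national-box region, harvested area held at a flat
deterministic baseline, log-yield coupled at a prescribed ρ to the realized
standardized soil-moisture driver — so the generating production correlation
is exactly ρ — then the full anomaly pipeline and the pooled national lagged
correlation (n_eff = 30). Across 200 seeded replicates per
ρ ∈ {−0.6, −0.3, 0.3, 0.6} the estimate falls in the Fisher-z 95% interval
(at n_eff = 30) well above the 93% bar.

Holding the area deterministic in this experiment is deliberate: a strong
multiplicative planting cycle (Q4 ≈ 1.3× Q2) riding on an exponential trend
leaves a growing-amplitude seasonal residual after *additive* running-mean
detrending and climatology removal, which dilutes raw-scale correlations (a
prescribed 0.6 measures ≈ 0.31 under the full default panel). This is a real
property of additive anomaly pipelines applied to multiplicative data — worth
knowing when interpreting production correlations — and the recovery
experiment is designed not to conflate it with estimator error. Yield-based
correlations are barely affected (the yield cycle is mild), which is why the
rainfed-vs-irrigated sensitivity ordering is validated on yield.

## 5. What passing tests do and do not show

The generator reproduces the *assumed statistical skeleton* — lagged
teleconnection with seasonal modulation, multiplicative crop panels with
survey gaps, warming patterns with known normalization, clustered occurrence
points — with rectangular stand-in regions, coarse grids (1°/2°), spatially
isotropic noise, and Gaussian innovations. It does not emulate: tropical
cyclones or other extreme events (subsumed into noise), real Philippine
geography or planting calendars, non-Gaussian tails, precipitation or
ENSO-variability change under warming, or nonlinear/threshold yield
responses. Green tests therefore certify the estimators and the pipeline
plumbing under the assumed structure, not the observational findings
themselves; real-data magnitudes (e.g., the national 10%-of-variance figure)
enter only as worked examples of the statistics, not as things the synthetic
study reproduces.

The synthetic envelope comparison is narrower than its real counterpart: the
occurrence points sample the same small Philippines-domain climatology used
for the scenarios, so the occurrence envelope is tight (~2 °C wide) and its
overlap with the +2 °C and +4 °C distributions is zero, whereas a
tropics-wide occurrence set spans a broader temperature range and would
retain partial overlap at +2 °C. Crossing-year outputs summarize the
generator's prescribed linear warming rates, not any real model ensemble.

Problem sizes used by the test suite and drivers: 30-year study period,
coarse (3°) grids and two regions for Monte-Carlo experiments, 100–200
replicates per Monte-Carlo claim, 100,000 replicates for the null-calibration
check — the package's standard configuration for these experiments.
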