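# Methods

## The model

`dnrflux` partitions half-hourly net ecosystem exchange (NEE, µmol C m⁻²
s⁻¹, release positive) with the DT-RH model — a daytime flux-partitioning
model extended with a relative-humidity term and, crucially, with
*separate* daytime and nighttime apparent temperature sensitivities:

```
daytime:   NEE = − αβQ/(αQ + β) + R_ref,day · g(Tair; E₀,day) · fh
nighttime: NEE =                  R_ref,night · g(Tair; E₀,night)

g(T; E₀) = exp( E₀ · ( 1/(T_ref − T₀) − 1/(T − T₀) ) )
fh       = max( 1 − ε·(RH − RH̄)/RH̄ , 0 )
β        = β₀·exp(−k·(VPD − VPD₀))  for VPD > VPD₀, else β₀
```

with T_ref = 15 °C, T₀ = −46.02 °C, VPD₀ = 10 hPa. The GPP term is a
rectangular hyperbola in global radiation Q whose plateau β is
down-regulated above the VPD threshold; the respiration term is the
Lloyd–Taylor exponential scaled by the humidity factor fh. ε ∈ {−1, +1}
is a site-level sign: +1 when standardized daytime respiration
(DER/R_ref,day) correlates negatively with window-mean RH across windows
(wet ecosystems — moisture suppresses respiration), −1 otherwise; an
exact zero correlation takes the +1 branch. Temperatures enter in °C;
the °C and Kelvin forms of the Lloyd–Taylor function differ only by a
constant absorbed in T₀, so E₀ is quoted in K.

Two sign/structure choices are deliberate and configurable:

- **Sign convention.** NEE = −GPP + ER (uptake negative), the
  micrometeorological convention; `predict_nee(gpp_sign=+1)` flips it.
- **No fh at night.** The nighttime model has exactly two parameters
  (R_ref,night, E₀,night); the humidity factor applies to the daytime fit
  only. Whether the original formulation applied fh at night is not
  stated in the sources this design follows; the two-parameter reading
  keeps the nighttime fit maximally comparable to the classical
  nighttime partitioner.
- **fh flooring.** fh can go negative for ε = +1 and RH > 2·RH̄; it is
  floored at 0 (respiration cannot be negative) with a warning.

The quantity of interest is the diel asymmetry **ΔE₀ = E₀,night/E₀,day**
(> 1: respiration more temperature-sensitive at night) and its seasonal
statistics.

## Moving-window estimation

Parameters are estimated in 7-day windows advanced in 5-day steps
(both configurable; the 7/5 overlap is one reading of a scheme that can
also be run as disjoint or other widths). Each window gets

1. a nighttime fit of (R_ref,night, E₀,night) on valid nighttime records
   (qc-passing NEE, ≥ 30 records, air-temperature spread ≥ 2 °C for E₀
   identifiability), and
2. a daytime fit of (α, β₀, k, R_ref,day, E₀,day) on valid daytime
   records (≥ 50 records, max radiation ≥ 100 W m⁻²) with the site ε
   fixed. k is pinned to 0 when no record exceeds VPD₀ (lower branch
   only — unidentifiable).

Day/night is `SW_IN > 20 W m⁻²` (strict), a common micrometeorological
convention; the threshold is configurable. Only measured NEE (qc = 0 by
default) is fitted; gap-filled values are masked but drivers retained
for prediction.

**RH̄ and overlapping windows.** fh needs the window-mean daytime RH.
Because consecutive windows overlap by two days, a record in the overlap
would see two different RH̄ values depending on which window is being
fit. The package resolves this by attributing every record to the window
whose *center* is nearest and using that window's daytime-RH mean as the
record's RH̄ — in the synthetic generator, in the window fits, and in
the ER reconstruction alike, so a noise-free synthetic series is exactly
invertible.

**Sampler.** Bayesian estimation by adaptive random-walk Metropolis:
Gaussian likelihood with the residual variance profiled out
(log L = −n/2·log SSR), uniform priors on finite bounds, chain seeded at
a deterministic trust-region least-squares fit (three starts), proposal
covariance initialized from the Gauss–Newton curvature at that point.
During burn-in (first 50% of iterations) a global proposal scale is
steered toward 30% acceptance and the proposal covariance is
re-estimated from the chain history (Haario-style); both are frozen
afterwards so the retained chain targets the exact posterior. The
retained half is thinned by 5; estimates are posterior medians with
central 95% credible intervals. Default chain length is 10,000
iterations; the acceptance suite and examples use 5,000, which matches
the least-squares oracle to well under 1% on identifiable noise-free
windows and keeps a full year of windows around 15 s on one CPU.

**Convergence.** A fit is flagged converged when the post-burn-in
acceptance rate is in [0.1, 0.6] and the Geweke z of the E₀ chain
(first 10% vs last 50% means, batch-means standard errors) satisfies
|z| < 2. Monthly aggregation uses converged windows by default.

**Prior bounds and the flux-scale cap.** Defaults: E₀ ∈ [10, 600] K,
R_ref ∈ (0, 50], α ∈ (0, 0.25], β₀ ∈ (0, 100], k ∈ [0, 2] — spanning
published flux-partitioning ranges. On top of these, per window, the
R_ref upper bound is capped at
`max(2, 5·q95(NEE⁺), 0.5·q98(|NEE|))` and β₀ at `max(5, 3·|q02(NEE)|)`
(`scale_r_ref_to_flux=True`). Rationale: in windows with weak
temperature leverage (cold season, small fluxes) the flat rectangular
prior concentrates posterior volume along the high-E₀/high-R_ref ridge
and along large-β₀ GPP/respiration trade-offs; the posterior median then
reflects prior volume rather than data. The caps only exclude parameter
values that the window's own fluxes rule out on physical grounds (a
base respiration many times larger than any observed efflux; a
saturating uptake several times the strongest observed uptake); on
synthetic benchmarks they cut the cold-season E₀ bias roughly in half
and bring the reconstructed annual ER of the DT-RH method within a few
percent of truth without affecting well-identified windows.

**ε estimation.** A fast deterministic DT-style pass (nighttime least
squares for E₀, daytime least squares with E₀ fixed, no fh) produces
per-window DER/R_ref,day — which reduces to the window-mean Lloyd–Taylor
exponential over daytime temperatures — and the Pearson correlation of
that ratio with window-mean RH across ≥ 5 windows sets ε once per site.
Note that because fh is centered on the *window* mean, a generator
driven by this same model produces almost no cross-window signal for ε;
recovery experiments therefore pass the known site ε explicitly, and ε
estimation is tested on planted monotone relations.

## Baseline partitioners

- **NT (nighttime method):** the two nighttime parameters are fit per
  window and extrapolated through the day unchanged — one E₀ for the
  whole diel cycle.
- **DT (daytime method):** E₀ from the nighttime fit, then
  (α, β₀, k, R_ref,day) from daytime data with E₀ fixed and no fh.

`er_bias_ignoring_delta` reports 100·(ER_NT − ER_DTRH)/ER_DTRH per year;
the synthetic experiments additionally compare both against the
generative truth.

## ER reconstruction

Each record takes the parameters of the fit whose window center is
nearest: daytime records use the daytime set (with fh when the fit used
one; NT fits fall back to the nighttime set — that *is* the NT
extrapolation), nighttime records the nighttime set. Records outside the
span of all windows (the tail a partial window would have covered) are
left missing. Monthly/annual aggregates carry mean flux, integrated
carbon (g C m⁻², 12·10⁻⁶ g per µmol per second) and gap counts.

## Monthly aggregation and seasonal statistics

Window estimates are averaged to site-months by window center; ΔE₀ is
the **ratio of monthly means**, not the mean of window ratios (less
noise amplification from small E₀,day; the alternative is available by
aggregating externally). Seasonal statistics per site-year, requiring at
least 8 non-missing months: CV = 100·sd/mean of the monthly values
(sample sd), and the seasonal amplitude ASV = max − min of monthly ΔE₀.
Day-vs-night comparisons per biome use Welch's unequal-variance t-test.
Spatial binning: absolute-latitude bins of 10° (hemispheres folded), a
4 °C × 1 mm day⁻¹ climate grid on mean annual temperature and
precipitation, and the thermal classification boreal (MAT < 2 °C),
temperate (2–17 °C inclusive), tropical (> 17 °C).

## Driver attribution

On a site-year feature table (response: ΔE₀ seasonal amplitude;
covariates: climate, vegetation and soil variables plus their seasonal
amplitudes), three complementary views:

- **PCA** of standardized covariates; per-variable contribution to a
  component is 100·loading² (summing to 100%), with 100/p as the
  average-contribution reference.
- **AICc-ranked linear models** over the fixed candidate set
  {Dim1 + Dim2, Dim1, Dim2}; AICc counts the residual variance as an
  estimated parameter and is verified in the tests against a from-scratch
  formula.
- **Random-forest permutation importance**: increase in mean-squared
  error when a covariate is permuted (10 repeats, seeded), normalized to
  shares summing to 100% and grouped into climate/vegetation/soil
  families. Missing covariates are imputed by per-biome medians first.

## The synthetic generator

The generator is the ground truth for every recovery claim. It emulates:
clear-sky solar geometry (declination/zenith) with uniform daily cloud
dimming; air temperature as a latitude-dependent seasonal sinusoid
(MAT = 27 − 0.42·|lat| °C, amplitude 2 + 0.28·|lat| °C) plus a daily
AR(1) synoptic component (φ = 0.8, σ = 2.2 °C — multi-day warm/cold
spells), a diurnal cycle lagging solar noon by ~2 h with a full range of
~6–10 °C (larger on clear days, matching typical mid-latitude diurnal
temperature ranges), and fast AR(1) noise; RH anti-correlated with the
diurnal temperature anomaly around a configurable daily baseline
(default 72%); VPD from the Magnus saturation vapour pressure;
occasional wet days. NEE is the forward model on per-day parameter
trajectories (constant, or 12 monthly anchors linearly interpolated)
plus homoscedastic Gaussian noise (default σ = 1 µmol C m⁻² s⁻¹), with a
default 10% of records flagged gap-filled. The default seasonal scenario
has E₀,day peaking and E₀,night dipping June–September, so ΔE₀ exceeds 1
outside summer and approaches 1 within it.

What it does **not** emulate — and hence what passing tests do not show
about real towers: u*-filtering artifacts and storage fluxes, energy-
balance gaps, flux-magnitude-dependent (heteroscedastic) and
non-Gaussian observation error, instrument drift, advection, and any
decoupling between the fitted model family and reality (the generator
and the fitter share the DT-RH equations, so recovery tests measure
estimation quality, not model adequacy).

## Numerical choices and degenerate inputs

- Profiled-σ log-likelihood with a 10⁻³⁰⁰ floor inside the log for
  noise-free windows.
- Least-squares seeding uses three starts across the E₀ range; ties
  resolved by lowest cost.
- Windows failing their data preconditions are skipped with a logged
  reason and never emit a fit.
- Constant-input correlation in ε estimation returns +1 (the stated
  "otherwise" branch).
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawn keys (per window, per day/night
  stream), so the full pipeline is bit-reproducible.

## Problem sizes

Recovery and bias experiments use single synthetic years (17,520
half-hourly records, ~72 windows) at 45° latitude with 5,000-iteration
chains; the oracle-equivalence check uses 20 noise-free summer windows;
attribution experiments use 200 site-year tables. These sizes were
chosen so the whole verification suite runs in a few minutes on one CPU.

## Known limitations

- Per-window E₀ from 7 days of half-hourly data at σ = 1 µmol noise is
  close to its information limit in the cold season: posterior medians
  scatter widely (the 95% intervals honestly reflect this, with ~95%
  empirical coverage), and monthly means built from ~6 windows typically
  carry a 10–15% median relative error on synthetic benchmarks —
  adequate for the diel ratio ΔE₀ (whose day/night errors partially
  cancel) but not for precise monthly E₀ level estimates in winter.
- The daytime fit shares the classical equifinality of daytime
  partitioning: part of respiration can be absorbed into the light
  response, biasing daytime ER slightly low (a few percent annually on
  synthetic benchmarks) even at the likelihood optimum.
- ε is a site constant; slowly varying humidity responses are not
  captured.
- The Welch biome test treats site-months as independent samples, as in
  standard practice; serial correlation within sites is ignored.
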