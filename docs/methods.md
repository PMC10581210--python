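# Methods

This note records the models behind `heatrisk`, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical decisions a user auditing results will want to know.

## Heat stress index

The HSI is the US NWS heat index reported in °C. Internally the default
`nws` mode works on the Fahrenheit scale: Steadman's simple formula
1.1·T_F − 10.3 + 0.047·RH is evaluated first; if it reaches 80 °F the
nine-term Rothfusz regression replaces it, minus a dry-air adjustment
((13 − RH)/4)·√((17 − |T_F − 95|)/17) when RH < 13 % and 26.7 °C ≤ T ≤
44.5 °C, plus a humid adjustment ((RH − 85)/10)·((87 − T_F)/5) when
RH > 85 % and 26.7 °C ≤ T ≤ 30.5 °C. Those Celsius windows are exactly
80/87/112 °F. The result converts back to °C.

The same formulas are sometimes printed with all quantities labelled °C
(the simple formula as 1.98·T + 24.9 + 0.047·RH, the dry-adjustment radical
as 1 − |9T − 315|/85, the humid factor as (275 − 9T)/25); these are
algebraically the Fahrenheit forms after substituting T_F = 1.8T + 32, which
is why `nws` mode treats the simple-formula output as Fahrenheit. A
`paper_literal` mode evaluates the printed equations verbatim with Celsius
inputs and no conversion, for auditing analyses that ran them that way; with
Celsius inputs its simple-formula gate (< 26.7) only triggers below about
−0.3 °C, a dimensional inconsistency the mode preserves deliberately.

The simple→Rothfusz switch makes the index discontinuous at 80 °F by
construction; the jump is largest at low humidity (about 2 °C at RH = 20 %)
and is bounded, not removed. Adjustment windows are evaluated on the input
temperature in °C with inclusive bounds. NaN inputs propagate to NaN; no
imputation anywhere.

## Site-level exposure–response (DLNM)

Daily deaths at a surveillance site are modelled quasi-Poisson with
log E(mort_i) = α + β·cb(HSI)_i + ns(time) + DOW. The cross-basis entry for
day *i* and basis pair (j, k) is Σ_{l=0..21} B_exp_j(HSI_{i−l})·B_lag_k(l).
Days with incomplete 21-day lag history are dropped from the likelihood, not
imputed. Seasonality and trend are controlled by a natural cubic spline of
the day index with 7 df per year (knots at equally spaced quantiles);
day-of-week enters as six indicators against Monday. Dispersion is the
Pearson χ²/df estimate and scales the coefficient covariance
(dispersion × (XᵀWX)⁻¹).

Exposure bases:

- `ns` (default): natural cubic spline, df 4, interior knots at the 10th,
  75th and 90th percentiles of site HSI, boundary knots at the data range —
  the standard configuration in temperature–mortality DLNM work, appropriate
  for smooth real-world curves.
- `lin`: centred linear, used for closed-form equivalence checks (with a
  constant lag basis the single cross-basis column is a 22-day moving sum,
  so a plain GLM on the moving-average exposure is an exact oracle).
- `thr`: the hinge max(0, HSI − θ). For hockey-stick-shaped risk — flat to
  a threshold, log-linear above — a C² spline cannot represent the corner:
  its best approximation smears the kink over the inter-knot span, biasing
  the heat-arm slope by tens of percent regardless of estimation quality.
  The hinge basis contains that curve class exactly. The threshold θ is
  estimated by profile likelihood: the hinge DLNM is refitted over a grid of
  candidate thresholds (jointly across sites, summing deviances) and the
  minimiser — quadratically interpolated around the grid minimum — is the
  MMHSI. This is the segmented-regression treatment of an unknown
  breakpoint. Downstream CIs condition on the profiled threshold; threshold
  uncertainty is not propagated (a known limitation, second-order for the
  slope at the sample sizes used here).

The overall cumulative curve sums lag contributions: reduced coefficient
η_j = Σ_k β_{jk}·C_k with C_k = Σ_l B_lag_k(l), covariance B·V·Bᵀ for the
corresponding linear map. For spline curves the MMHSI is the argmin of the
cumulative log-RR on a 0.1 °C grid within the 1st–99th percentile window of
observed HSI (ties to the lowest value; a flat curve warns and returns the
window midpoint); for hinge curves it is the threshold itself. `rr_at`
reports RR relative to the MMHSI (RR = 1 there exactly) with delta-method
intervals; an explicit `ref` argument allows a fixed reference instead —
calibration checks use a fixed reference, because conditioning on an
estimated minimum biases type-I error upward under a null effect.

## Regional pooling

Site reduced coefficients y_s with covariances V_s are pooled per subregion
under y_s ~ N(μ, V_s + Ψ). Ψ is estimated by REML with a Cholesky
parameterisation (log-diagonal free parameters, Nelder–Mead), started from
and falling back to a moments estimator projected to PSD. Uncentred
coefficients are pooled; centring at the MMHSI happens after pooling/BLUP.
BLUP shrinkage uses A = I − V_s(Ψ + V_s)⁻¹ (algebraically Ψ(Ψ + V_s)⁻¹ but
numerically exact in both limits); its covariance combines the shrunk site
variance with the pooled-mean uncertainty. The regional curve is the pooled
mean μ on the shared basis. Heterogeneity: Q = Σ (y_s − μ_FE)ᵀV_s⁻¹(y_s − μ_FE)
at the fixed-effect mean, df = (n_sites − 1)·dim, p from χ², and
I² = max(0, (Q − df)/Q)·100. A univariate cross-check against R `metafor`
(REML) is part of the test suite.

## Attribution

AF = (RR − 1)/RR, floored at zero (moot above the MMHSI for monotone heat
arms, enforced defensively). Daily attributable deaths at a cell are
Mt·Pop·AF(RR(HSI_d)) on days with HSI strictly above the regional MMHSI;
annual sums give HD, HD/Pop the rate HM reported in ‰. Regional deaths are
exact cell sums; regional rates divide by regional population; zero-
population regions report a missing rate. Decades are half-open windows
[y0, y0+10); change ratios are future-decade mean / baseline-period mean ×
100 %. Baseline mortality Mt is held at its baseline value for future years
(constant-vulnerability assumption), exposed per-year for sensitivity runs.
Population between decadal snapshots uses the decade's snapshot; a
regridding helper interpolates finer population bilinearly and rescales so
the national total is conserved (error well under 0.1 %). Cell-years missing
more than 10 % of days are flagged and excluded. Leap days are counted as
ordinary days. A configuration example ships the seven-subregion MMHSI set
(NE/NC/NW/EC/CC/SW/SC = 24/26/25/25/35/29/32 °C) used in Chinese
surveillance work; it is documentation, not a recomputed quantity.

## Uncertainty

Coefficient uncertainty: n (default 1000) draws from MVN(coef, vcov) of the
regional curve; a covariance failing the PSD check is projected to the
nearest PSD matrix with a warning. The heat-day filter stays at the curve's
stored MMHSI across draws (no per-draw re-centring). Ensemble uncertainty:
each climate model is evaluated separately; the central value is the mean of
per-model means; the 95 % interval takes the 2.5th and 97.5th percentiles of
the pooled draw × model distribution, with linear interpolation between
closest ranks (stated because percentile dialects differ). Per-model RNG
substreams spawn from one master seed, so results do not depend on worker
scheduling. Fewer than 40 pooled values triggers a resolution warning.

## Driver decomposition

Per subregion and scenario, every inhabited cell-year contributes one row:
mean temperature and mean humidity over that year's heat-risk days (HSI >
MMHSI) as features, annual HM as target; cell-years with no heat day are
dropped, as are uninhabited cells. A regression random forest (500 trees,
unrestricted depth, both features eligible at every split, bootstrap on,
fixed seed) supplies Gini (variance-reduction) importances, normalised to
shares summing to 100 %. Cell-years from all ensemble members pool into one
forest by default. The shares attribute variation in heat mortality *given*
established heat risk; they are not causal claims about humidity absent
heat. Annual-mean summarisation over heat days is a declared choice
(configurable to other statistics); the aggregation statistic is otherwise
underdetermined.

## Synthetic data

The generators supply the statistical structure the analysis assumes, with
a real calendar (leap years, weekdays):

- **Climate**: per cell, T = latitude-graded mean + sinusoidal annual cycle
  (amplitude 10 °C, peak mid-July) + linear scenario trend + iid N(0, 2 °C)
  daily noise; RH = baseline 70 % + trend + N(0, 8 %) noise clipped to
  [0, 100]. Four stand-in scenarios ramp 0.2/0.45/0.7/1.0 °C per decade
  (end-of-century spread echoing the Tier-1 SSP range) with humidity drifts
  of −0.2 to −0.35 % per decade, within the few-percent humidity changes
  downscaled ensembles show. An optional Gaussian-blur flag adds spatial
  smoothness; there is no weather autocorrelation, no physics, and no
  demographic age structure — so passing tests demonstrate statistical
  correctness of the estimators, not realism of any particular projection.
- **Population**: a fixed seeded lognormal spatial pattern scaled to a
  geometric national total per decade.
- **Mortality**: expected count = baseline × day-of-week multiplier ×
  exp(Σ_l w_l·slope·max(0, HSI_{i−l} − MMHSI)) with nonnegative lag weights
  summing to 1 (default exponential decay, mean lag ≈ 5 d); counts are NB1
  via a Gamma–Poisson mixture so Var = dispersion × mean exactly, matching
  the quasi-Poisson fit. Dispersion 1 reduces to Poisson.

Recovery analyses use 10 sites × 10 years at 30 deaths/day and dispersion
1.2 — a scale at which one desk CPU runs the whole chain in minutes while
leaving visible sampling noise. Because the generator's truth is a hinge,
recovery tests fit the hinge basis (the model class containing the truth);
the spline default is exercised by the null-calibration and property tests,
and its corner bias is documented above rather than hidden.

## Numerical and I/O decisions

- Natural splines use the truncated-power natural basis (linear tails
  beyond boundary knots); constant series get a token knot interval so the
  basis stays defined. Lag-axis knots sit at equally spaced log-lags.
- NetCDF I/O uses xarray's scipy backend (NetCDF3 classic). Temperature in
  Kelvin is auto-converted (units attribute or magnitude > 150); fractional
  humidity auto-scales to percent. Curves serialise to JSON with basis,
  coefficients, covariance, MMHSI and region.
- The pipeline writes a provenance manifest (config hash, version, master
  and per-stage seeds) beside its outputs; outputs are byte-identical for
  identical (config, seed).
- Pipeline runs and acceptance checks use small grids (2×2 cells), 3–10
  sites, 100 draws and 2–3 pseudo-models — sizes chosen so the full chain
  and its replication loops execute in minutes while keeping every
  statistical check well-powered.

## Known limitations

Threshold uncertainty is conditioned away after profiling; the spline
exposure default under-fits genuinely kinked curves (use `thr`); no
harvesting decomposition, no cold-attributable deaths (cold arms are fitted
implicitly but never attributed), no age/cause stratification; the
constant-vulnerability and constant-baseline-mortality assumptions carry
historical relationships unchanged into projections.
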