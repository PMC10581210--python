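# heatrisk

Projecting heat stress and heat-attributable mortality on gridded climate
scenarios, for epidemiologists and climate-health modellers.

The package implements the full chain used in climate-health impact
assessment over a region such as China and its climatic subregions:

1. **Heat stress index (HSI).** The US NWS heat index expressed in °C:
   Steadman's simple apparent-temperature formula below 80 °F, the nine-term
   Rothfusz regression above it, with low-humidity (RH < 13 %) and
   high-humidity (RH > 85 %) adjustment terms. Computed per day from
   near-surface temperature `tas` and relative humidity `hurs`.
2. **Exposure–response.** Site-level distributed lag nonlinear models
   (DLNM): a cross-basis over HSI × lag (0–21 days) inside a quasi-Poisson
   regression,

   log E(mort_i) = α + β·HSI_{i,l} + ns(time, 7 df/yr) + DOW,

   reduced to the overall cumulative curve RR(HSI) centred at the
   minimum-mortality HSI (MMHSI). Exposure bases: natural cubic spline
   (default), linear, or hinge with profile-likelihood threshold estimation.
3. **Pooling.** Multivariate random-effects meta-analysis of site curves per
   subregion (REML), BLUP shrinkage, Cochran's Q and I² heterogeneity.
4. **Attribution.** AF = (RR − 1)/RR on days with HSI > MMHSI;
   D_{x,d} = Mt_{x,y} · P_{x,y} · AF_{x,d}; annual cell sums HD, rates
   HM = HD/Pop (‰), regional aggregates, decadal means and change ratios
   versus a 1995–2014 baseline.
5. **Uncertainty.** 1000-sample multivariate-normal coefficient draws ×
   climate-model ensemble; 95 % intervals from the 2.5th–97.5th empirical
   percentiles; ensemble-mean central values.
6. **Drivers.** Random-forest Gini importance of heat-day temperature vs
   humidity for annual heat mortality, normalised to shares summing to 100 %.

Real surveillance mortality and downscaled CMIP6 archives are **not**
required: a synthetic-data module generates scenario climate fields, decadal
population surfaces and overdispersed site mortality from a known lagged
risk curve, so every stage is testable against ground truth.

## Worked example

Fit a site curve on synthetic data with a known truth (log-RR slope
0.05/°C above an MMHSI of 29 °C), as in `examples/02_fit_exposure_response.py`:

```python
import numpy as np, heatrisk as hr
from heatrisk.dlnm import CrossBasisSpec

grid = hr.GridDef(30.0, 30.25, 110.0, 110.25)
clim = hr.gen_climate(grid, hr.SCENARIOS["ssp245"], (2007, 2016), seed=7)
hsi  = hr.hsi_grid(clim).isel(lat=0, lon=0).to_series()

truth = hr.TrueRiskCurve(mmhsi_true=29.0, log_rr_slope=0.05)
mort  = hr.gen_site_mortality(hsi, truth, baseline_rate=30.0, seed=1)

thr, _ = hr.profile_threshold([(mort, hsi)], np.arange(25.0, 34.0, 1.0))
fit    = hr.fit_site_model(mort, hsi, CrossBasisSpec(exposure_df=1,
                           exposure_type="thr", exposure_thr=thr))
curve  = hr.reduce_overall(fit)
print(hr.rr_at(curve, [31.0, 34.0]))
```

Output:

```
profiled MMHSI: 28.86 degC (truth 29.0)
cumulative log-RR slope: 0.0417 /degC (truth 0.05)
RR at 31 degC: 1.093  (95% CI 1.056-1.132; truth 1.105)
RR at 34 degC: 1.239  (95% CI 1.141-1.346; truth 1.284)
```

The MMHSI is the HSI with the lowest fitted mortality risk (RR = 1 there);
the RR column is the cumulative relative risk over lags 0–21 at each HSI,
with delta-method confidence intervals. One ten-year site recovers the
threshold within ~0.2 °C and the slope within its CI.

The other scripts in `examples/` walk through the heat index itself,
regional pooling, gridded projection with Monte Carlo envelopes, driver
decomposition, and the one-call pipeline (`hr.run_pipeline`). A thin CLI
mirrors the stages: `heatrisk simulate | hsi | hsi-grid | fit | pool | run-all`.

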