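"""Synthetic gridded climate, population, and site mortality generators.

These emulate the statistical structure the analysis assumes — scenario
climate with a seasonal cycle plus a linear warming trend, decadally growing
population surfaces, and overdispersed daily death counts driven by a known
lagged heat-risk curve — so the whole pipeline is testable end to end with a
known ground truth.  They deliberately contain no atmospheric physics and no
spatial weather correlation (an optional smoothing flag exists for the
latter); the calendar is real, so leap years, day-of-week structure and
per-year spline degrees of freedom are all well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

__all__ = [
    "ScenarioSpec",
    "TrueRiskCurve",
    "SCENARIOS",
    "GridDef",
    "gen_climate",
    "gen_population",
    "gen_site_mortality",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one emission-scenario climate emulation.

    warming_rate and rh_trend are linear trends per decade; seasonal_amp is
    the amplitude of the sinusoidal annual temperature cycle; noise_sd the
    iid day-to-day Gaussian noise on temperature.
    """

    name: str
    warming_rate: float  # degC / decade
    rh_trend: float = 0.0  # % / decade
    seasonal_amp: float = 10.0  # degC
    noise_sd: float = 2.0  # degC
    rh_mean: float = 70.0  # %
    rh_noise_sd: float = 8.0  # %
    t_mean: float = 18.0  # degC annual mean at the grid centre

    def __post_init__(self):
        if not np.isfinite(self.warming_rate):
            raise ValueError("warming_rate must be finite")
        if not 0.0 < self.rh_mean < 100.0:
            raise ValueError("rh_mean must be in (0, 100)")
        if self.seasonal_amp < 0 or self.noise_sd < 0:
            raise ValueError("seasonal_amp and noise_sd must be >= 0")


# Desk-scale stand-ins for the four Tier-1 SSP scenarios.  Warming rates are
# set so the 2020s->2090s temperature rise echoes each scenario's published
# end-of-century spread (about 1.5 degC for SSP1-2.6 up to about 8 degC for
# SSP5-8.5); humidity drifts stay within a few percent per century, matching
# the small (|dRH| <~ 3 %) humidity changes such downscaled ensembles show.
SCENARIOS: dict[str, ScenarioSpec] = {
    "ssp126": ScenarioSpec("ssp126", warming_rate=0.2, rh_trend=-0.2),
    "ssp245": ScenarioSpec("ssp245", warming_rate=0.45, rh_trend=-0.25),
    "ssp370": ScenarioSpec("ssp370", warming_rate=0.7, rh_trend=-0.3),
    "ssp585": ScenarioSpec("ssp585", warming_rate=1.0, rh_trend=-0.35),
}


def _default_lag_weights() -> np.ndarray:
    w = np.exp(-np.arange(22) / 5.0)
    return w / w.sum()


@dataclass(frozen=True)
class TrueRiskCurve:
    """Ground-truth lagged heat-risk curve for parameter-recovery tests.

    Log relative risk is 0 at or below ``mmhsi_true`` and rises linearly at
    ``log_rr_slope`` per degC above it; the effect is spread over lags 0-21
    by ``lag_weights`` (nonnegative, summing to 1).
    """

    mmhsi_true: float = 29.0
    log_rr_slope: float = 0.05
    lag_weights: np.ndarray = field(default_factory=_default_lag_weights)

    def __post_init__(self):
        w = np.asarray(self.lag_weights, dtype=float)
        if w.shape != (22,):
            raise ValueError("lag_weights must have length 22")
        if np.any(w < 0):
            raise ValueError("lag_weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("lag_weights must sum to 1")
        if self.log_rr_slope < 0:
            raise ValueError("log_rr_slope must be >= 0")
        object.__setattr__(self, "lag_weights", w)

    def cumulative_log_rr(self, hsi) -> np.ndarray:
        """Overall cumulative log-RR at constant exposure ``hsi``."""
        return self.log_rr_slope * np.clip(np.asarray(hsi, float) - self.mmhsi_true, 0, None)


@dataclass(frozen=True)
class GridDef:
    """Regular cell-centred lat-lon grid."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float = 0.25

    def __post_init__(self):
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise ValueError("empty grid extent")
        for span in (self.lat_max - self.lat_min, self.lon_max - self.lon_min):
            n = span / self.resolution
            if abs(n - round(n)) > 1e-9:
                raise ValueError("resolution must divide the grid extent")

    @property
    def lats(self) -> np.ndarray:
        n = round((self.lat_max - self.lat_min) / self.resolution)
        return self.lat_min + self.resolution * (np.arange(n) + 0.5)

    @property
    def lons(self) -> np.ndarray:
        n = round((self.lon_max - self.lon_min) / self.resolution)
        return self.lon_min + self.resolution * (np.arange(n) + 0.5)


def gen_climate(
    grid: GridDef,
    scenario: ScenarioSpec,
    years: tuple[int, int],
    seed: int,
    ref_year: int | None = None,
    smooth_sigma: float = 0.0,
) -> xr.Dataset:
    """Daily temperature (`tas`, degC) and relative humidity (`hurs`, %) fields.

    Temperature is a latitude-graded annual mean + sinusoidal seasonal cycle
    + linear scenario trend (anchored at ``ref_year``, default the first
    year) + iid Gaussian noise; RH is a baseline + trend + noise, clipped to
    [0, 100].  ``smooth_sigma`` > 0 applies a Gaussian spatial blur to the
    noise fields.  Pure function of (parameters, seed).
    """
    y0, y1 = years
    if y1 < y0:
        raise ValueError("empty year range")
    lats, lons = grid.lats, grid.lons
    time = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    rng = np.random.default_rng(seed)
    if ref_year is None:
        ref_year = y0

    doy = time.dayofyear.to_numpy()
    # years since ref, as a continuous variable
    tyears = (time - pd.Timestamp(f"{ref_year}-01-01")).days.to_numpy() / 365.25
    seasonal = scenario.seasonal_amp * np.cos(2 * np.pi * (doy - 196) / 365.25)
    trend_t = scenario.warming_rate / 10.0 * tyears
    trend_rh = scenario.rh_trend / 10.0 * tyears

    # mild meridional gradient so cells differ; colder poleward
    lat_grad = -0.3 * (lats - lats.mean())
    base_t = scenario.t_mean + lat_grad[:, None] + np.zeros((1, lons.size))

    noise_t = rng.normal(0.0, scenario.noise_sd, size=(time.size, lats.size, lons.size))
    noise_rh = rng.normal(0.0, scenario.rh_noise_sd, size=(time.size, lats.size, lons.size))
    if smooth_sigma > 0:
        noise_t = ndimage.gaussian_filter(noise_t, sigma=(0, smooth_sigma, smooth_sigma))
        noise_rh = ndimage.gaussian_filter(noise_rh, sigma=(0, smooth_sigma, smooth_sigma))

    tas = base_t[None, :, :] + (seasonal + trend_t)[:, None, None] + noise_t
    hurs = np.clip(scenario.rh_mean + trend_rh[:, None, None] + noise_rh, 0.0, 100.0)

    return xr.Dataset(
        {
            "tas": (("time", "lat", "lon"), tas, {"units": "degC", "long_name": "daily mean air temperature"}),
            "hurs": (("time", "lat", "lon"), hurs, {"units": "%", "long_name": "daily mean relative humidity"}),
        },
        coords={"time": time, "lat": lats, "lon": lons},
        attrs={"scenario": scenario.name, "seed": int(seed)},
    )


def gen_population(
    grid: GridDef,
    base_total: float,
    decadal_growth: float,
    years: tuple[int, int],
    seed: int = 0,
) -> xr.Dataset:
    """Decadal population snapshots with geometric national growth.

    One `pop` field (persons per cell) per decade start covering ``years``;
    the spatial pattern is a fixed seeded lognormal density, each snapshot
    rescaled so the national total follows ``base_total * (1+g)^d`` exactly.
    """
    if base_total <= 0:
        raise ValueError("base_total must be > 0")
    if decadal_growth <= -1.0:
        raise ValueError("decadal growth below -100% is impossible")
    lats, lons = grid.lats, grid.lons
    rng = np.random.default_rng(seed)
    pattern = rng.lognormal(mean=0.0, sigma=1.0, size=(lats.size, lons.size))
    pattern /= pattern.sum()

    decades = np.arange(years[0] - years[0] % 10, years[1] + 1, 10)
    fields = np.stack(
        [pattern * base_total * (1.0 + decadal_growth) ** i for i in range(decades.size)]
    )
    return xr.Dataset(
        {"pop": (("year", "lat", "lon"), fields, {"units": "persons"})},
        coords={"year": decades, "lat": lats, "lon": lons},
    )


def gen_site_mortality(
    hsi: pd.Series,
    truth: TrueRiskCurve,
    baseline_rate: float,
    dow_effects=None,
    dispersion: float = 1.0,
    seed: int = 0,
    site_id: str = "site",
    region_id: str | None = None,
) -> pd.DataFrame:
    """Daily death counts from a known lagged HSI-risk curve.

    Expected count on day i is ``baseline_rate * dow_mult[weekday] *
    exp(sum_l w_l * slope * max(0, HSI_{i-l} - mmhsi_true))``; counts are
    drawn NB1 (Gamma-Poisson mixture) so that Var = dispersion * mean,
    reducing to plain Poisson at dispersion 1.  The first 21 days (incomplete
    lag history) are dropped from the output.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be > 0")
    if dispersion < 1.0:
        raise ValueError("dispersion must be >= 1")
    hsi = hsi.astype(float)
    if len(hsi) < 22:
        raise ValueError("HSI series shorter than the 21-day lag span")
    if dow_effects is None:
        dow_effects = np.ones(7)
    dow_effects = np.asarray(dow_effects, dtype=float)
    if dow_effects.shape != (7,):
        raise ValueError("dow_effects must have length 7 (Mon..Sun)")

    excess = np.clip(hsi.to_numpy() - truth.mmhsi_true, 0.0, None)
    # lagged weighted sum: contribution of day i-l with weight w_l
    w = truth.lag_weights
    lagged = np.full(len(hsi), np.nan)
    lagged[21:] = np.convolve(excess, w)[21 : len(hsi)]
    mu = baseline_rate * dow_effects[hsi.index.dayofweek] * np.exp(truth.log_rr_slope * lagged)

    rng = np.random.default_rng(seed)
    mu_valid = mu[21:]
    if dispersion == 1.0:
        deaths = rng.poisson(mu_valid)
    else:
        shape = mu_valid / (dispersion - 1.0)
        lam = rng.gamma(shape, dispersion - 1.0)
        deaths = rng.poisson(lam)

    out = pd.DataFrame(
        {"date": hsi.index[21:], "site_id": site_id, "deaths": deaths.astype(int)}
    )
    if region_id is not None:
        out["region_id"] = region_id
    return out
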