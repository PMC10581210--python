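"""First-stage distributed lag nonlinear modelling of HSI and mortality.

A cross-basis (tensor product of an exposure-axis spline and a lag-axis
spline over lags 0-21) enters a quasi-Poisson GLM together with a natural
cubic spline of time (7 df per year, controlling season and trend) and
day-of-week indicators.  The fitted bidimensional surface is then reduced to
the overall cumulative exposure-response curve by summing lag contributions,
and the curve is centred at its minimum-mortality HSI (MMHSI), the reference
where RR = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .splines import knots_from_quantiles, log_lag_knots, natural_cubic_basis

__all__ = [
    "CrossBasisSpec",
    "ExposureBasis",
    "CrossBasis",
    "SiteFit",
    "ExposureResponseCurve",
    "build_crossbasis",
    "resolve_basis",
    "fit_site_model",
    "reduce_overall",
    "find_mmhsi",
    "profile_threshold",
    "rr_at",
]

LAG_MAX_DEFAULT = 21


@dataclass(frozen=True)
class CrossBasisSpec:
    """Configuration of the exposure x lag cross-basis.

    ``exposure_knots`` / ``lag_knots`` are full knot vectors (boundaries
    included); when None they are resolved from data — exposure interior
    knots at the 10th/75th/90th HSI percentiles (standard practice in
    temperature-mortality DLNM work), lag interior knots equally spaced in
    log-lag.  ``exposure_type`` 'ns' or 'lin'; ``lag_type`` 'ns' (with
    intercept) or 'const'.
    """

    exposure_df: int = 4
    exposure_knots: tuple | None = None
    exposure_interior_percentiles: tuple = (10.0, 75.0, 90.0)
    lag_max: int = LAG_MAX_DEFAULT
    lag_df: int = 4
    lag_knots: tuple | None = None
    exposure_type: str = "ns"  # 'ns' | 'lin' | 'thr'
    exposure_thr: float | None = None  # hinge location for 'thr'
    lag_type: str = "ns"

    def __post_init__(self):
        if self.exposure_type == "ns" and self.exposure_df < 2:
            raise ValueError("exposure_df must be >= 2 for a spline basis")
        if self.exposure_type in ("lin", "thr") and self.exposure_df != 1:
            raise ValueError("linear and threshold exposure bases have df 1")
        if self.lag_type == "const" and self.lag_df != 1:
            raise ValueError("constant lag basis has df 1")
        if self.lag_max < 1:
            raise ValueError("lag_max must be >= 1")


@dataclass(frozen=True)
class ExposureBasis:
    """Resolved exposure-axis basis: evaluable at any HSI value.

    Kinds: ``ns`` natural cubic spline; ``lin`` centred linear; ``thr`` hinge
    ``max(0, x - thr)`` for threshold (hockey-stick) exposure-response, the
    model class under which the minimum-mortality HSI is the threshold
    itself.
    """

    kind: str  # 'ns' | 'lin' | 'thr'
    knots: np.ndarray | None = None
    centre: float = 0.0  # subtracted before the linear basis
    thr: float | None = None

    @property
    def df(self) -> int:
        return 1 if self.kind in ("lin", "thr") else len(self.knots) - 1

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "lin":
            return (x - self.centre)[..., None]
        if self.kind == "thr":
            return np.clip(x - self.thr, 0.0, None)[..., None]
        return natural_cubic_basis(x, self.knots)


@dataclass(frozen=True)
class CrossBasis:
    """Cross-basis with knots resolved against a concrete HSI series."""

    spec: CrossBasisSpec
    exposure: ExposureBasis
    lag_basis: np.ndarray  # (lag_max+1, lag_df)

    @property
    def n_coef(self) -> int:
        return self.exposure.df * self.lag_basis.shape[1]


def resolve_basis(hsi: np.ndarray, spec: CrossBasisSpec) -> CrossBasis:
    """Fix knot locations from the spec (or from HSI percentiles)."""
    hsi = np.asarray(hsi, dtype=float)
    if spec.exposure_type == "lin":
        exposure = ExposureBasis("lin", centre=float(np.nanmean(hsi)))
    elif spec.exposure_type == "thr":
        if spec.exposure_thr is None:
            raise ValueError("threshold basis needs exposure_thr (or profile it first)")
        exposure = ExposureBasis("thr", thr=float(spec.exposure_thr))
    else:
        if spec.exposure_knots is not None:
            knots = np.asarray(spec.exposure_knots, dtype=float)
        else:
            knots = knots_from_quantiles(
                hsi, spec.exposure_df, np.asarray(spec.exposure_interior_percentiles)
            )
        exposure = ExposureBasis("ns", knots=knots)

    lags = np.arange(spec.lag_max + 1, dtype=float)
    if spec.lag_type == "const":
        lag_b = np.ones((spec.lag_max + 1, 1))
    else:
        if spec.lag_knots is not None:
            lknots = np.asarray(spec.lag_knots, dtype=float)
        else:
            lknots = log_lag_knots(spec.lag_max, spec.lag_df - 2)
        lag_b = natural_cubic_basis(lags, lknots, intercept=True)
    return CrossBasis(spec=spec, exposure=exposure, lag_basis=lag_b)


def build_crossbasis(hsi: np.ndarray, spec_or_basis) -> tuple[np.ndarray, CrossBasis]:
    """Design matrix of the DLNM cross-basis for a daily HSI series.

    Row i, column (j, k) holds ``sum_l B_exp_j(HSI_{i-l}) * B_lag_k(l)``
    (exposure index j outer, lag index k inner).  The first ``lag_max`` rows
    have incomplete lag history and are NaN.
    """
    hsi = np.asarray(hsi, dtype=float)
    cb = spec_or_basis if isinstance(spec_or_basis, CrossBasis) else resolve_basis(hsi, spec_or_basis)
    lag_max = cb.spec.lag_max
    n = hsi.size
    if n <= lag_max:
        raise ValueError(f"series of length {n} shorter than lag span {lag_max + 1}")

    # lagged exposure matrix Q: Q[i, l] = hsi[i - l]
    Q = np.full((n, lag_max + 1), np.nan)
    for lag in range(lag_max + 1):
        Q[lag:, lag] = hsi[: n - lag]

    exp_df = cb.exposure.df
    lag_df = cb.lag_basis.shape[1]
    X = np.empty((n, exp_df * lag_df))
    BQ = cb.exposure(Q)  # (n, lag_max+1, exp_df)
    for j in range(exp_df):
        X[:, j * lag_df : (j + 1) * lag_df] = BQ[:, :, j] @ cb.lag_basis
    return X, cb


@dataclass
class SiteFit:
    """Quasi-Poisson DLNM fit for one surveillance site."""

    site_id: str
    coef: np.ndarray  # cross-basis block of the coefficient vector
    vcov: np.ndarray  # its covariance, scaled by the dispersion
    dispersion: float
    converged: bool
    n_days: int
    basis: CrossBasis
    deviance: float = np.nan
    region_id: str | None = None
    hsi_percentiles: np.ndarray | None = None  # 0..100 summary of site HSI


def _time_spline(n: int, df: int) -> np.ndarray:
    t = np.arange(n, dtype=float)
    knots = np.percentile(t, np.linspace(0, 100, df + 1))
    return natural_cubic_basis(t, knots)


def fit_site_model(
    site: pd.DataFrame,
    hsi: pd.Series,
    spec_or_basis=None,
    time_df_per_year: float = 7.0,
    dow: bool = True,
) -> SiteFit:
    """Fit the site-level quasi-Poisson DLNM.

    ``site`` needs columns date, deaths (and optionally site_id, region_id);
    ``hsi`` is a daily Series indexed by date covering at least the site's
    dates plus the 21 preceding days.  The linear predictor is intercept +
    cross-basis + natural cubic spline of time (``time_df_per_year`` df per
    year) + six day-of-week indicators (contrasts against Monday).  The
    covariance is scaled by the Pearson-chi-square dispersion estimate.
    """
    if spec_or_basis is None:
        spec_or_basis = CrossBasisSpec()
    site = site.sort_values("date").reset_index(drop=True)
    dates = pd.DatetimeIndex(site["date"])
    deaths = site["deaths"].to_numpy(dtype=float)
    if deaths.sum() == 0:
        raise ValueError("all-zero death series cannot be fitted")
    if np.any(deaths < 0):
        raise ValueError("negative death counts")
    n_years = (dates[-1] - dates[0]).days / 365.25
    if n_years < 2:
        warnings.warn(f"site {site.get('site_id', pd.Series(['?'])).iloc[0]}: "
                      f"under 2 years of data; estimates may be unstable")

    lag_max = (spec_or_basis.spec if isinstance(spec_or_basis, CrossBasis) else spec_or_basis).lag_max
    hsi = hsi.astype(float).sort_index()
    # align: for each mortality day we need that day plus lag_max predecessors
    start = dates[0] - pd.Timedelta(days=lag_max)
    hsi_win = hsi.loc[start : dates[-1]]
    full_idx = pd.date_range(start, dates[-1], freq="D")
    if not hsi_win.index.equals(full_idx):
        hsi_win = hsi_win.reindex(full_idx)
    X_cb_full, cb = build_crossbasis(hsi_win.to_numpy(), spec_or_basis)
    pos = full_idx.get_indexer(dates)
    if np.any(pos < 0):
        raise ValueError("mortality dates not covered by the HSI series")
    X_cb = X_cb_full[pos]

    time_df = max(2, round(time_df_per_year * n_years))
    X_time = _time_spline(len(site), time_df)
    parts = [np.ones((len(site), 1)), X_cb, X_time]
    if dow:
        dummies = np.eye(7)[dates.dayofweek][:, 1:]  # Tue..Sun vs Monday
        parts.append(dummies)
    X = np.column_stack(parts)

    # drop rows with incomplete lag history or missing HSI
    ok = np.isfinite(X).all(axis=1) & np.isfinite(deaths)
    X_ok, y_ok = X[ok], deaths[ok]

    model = sm.GLM(y_ok, X_ok, family=sm.families.Poisson())
    res = model.fit(scale="X2")
    converged = bool(getattr(res, "converged", True))
    if not converged:
        warnings.warn("site GLM did not converge; fit flagged")

    sl = slice(1, 1 + cb.n_coef)
    coef = np.asarray(res.params[sl])
    vcov = np.asarray(res.cov_params())[sl, sl]
    return SiteFit(
        site_id=str(site["site_id"].iloc[0]) if "site_id" in site else "site",
        coef=coef,
        vcov=0.5 * (vcov + vcov.T),
        dispersion=float(res.scale),
        converged=converged,
        n_days=int(ok.sum()),
        basis=cb,
        deviance=float(res.deviance),
        region_id=str(site["region_id"].iloc[0]) if "region_id" in site else None,
        hsi_percentiles=np.percentile(hsi_win.dropna().to_numpy(), np.arange(101)),
    )


@dataclass
class ExposureResponseCurve:
    """Overall cumulative exposure-response curve, centred at its MMHSI."""

    basis: ExposureBasis
    coef_reduced: np.ndarray
    vcov_reduced: np.ndarray
    mmhsi: float
    hsi_range: tuple[float, float]
    region_id: str | None = None

    def log_rr(self, hsi, ref: float | None = None) -> np.ndarray:
        ref = self.mmhsi if ref is None else ref
        db = self.basis(np.asarray(hsi, float)) - self.basis(ref)
        return db @ self.coef_reduced

    def with_reference(self, ref: float) -> "ExposureResponseCurve":
        return replace(self, mmhsi=float(ref))


def reduction_matrix(cb: CrossBasis) -> np.ndarray:
    """Linear map from cross-basis coefficients to overall-cumulative ones.

    Summing the lag basis over lags 0..lag_max gives, per exposure basis
    function j, eta_j = sum_k beta_{jk} * C_k with C_k = sum_l B_lag_k(l).
    """
    C = cb.lag_basis.sum(axis=0)  # (lag_df,)
    exp_df, lag_df = cb.exposure.df, cb.lag_basis.shape[1]
    B = np.zeros((exp_df, exp_df * lag_df))
    for j in range(exp_df):
        B[j, j * lag_df : (j + 1) * lag_df] = C
    return B


def reduce_overall(
    fit: SiteFit, search_percentiles: tuple[float, float] = (1.0, 99.0)
) -> ExposureResponseCurve:
    """Collapse a site fit to its overall cumulative curve and locate MMHSI."""
    if not fit.converged:
        raise ValueError("cannot reduce a non-converged fit")
    B = reduction_matrix(fit.basis)
    coef_red = B @ fit.coef
    vcov_red = B @ fit.vcov @ B.T
    if not np.all(np.isfinite(vcov_red)):
        raise ValueError("singular reduction: non-finite reduced covariance")
    pcts = fit.hsi_percentiles
    lo, hi = float(pcts[0]), float(pcts[100])
    curve = ExposureResponseCurve(
        basis=fit.basis.exposure,
        coef_reduced=coef_red,
        vcov_reduced=0.5 * (vcov_red + vcov_red.T),
        mmhsi=np.nan,
        hsi_range=(lo, hi),
        region_id=fit.region_id,
    )
    if fit.basis.exposure.kind == "thr":
        # hinge curve: risk is flat below the threshold, so the threshold is
        # the minimum-mortality HSI by construction
        curve.mmhsi = float(fit.basis.exposure.thr)
    else:
        window = (float(pcts[int(search_percentiles[0])]), float(pcts[int(search_percentiles[1])]))
        curve.mmhsi = find_mmhsi(curve, window)
    return curve


def find_mmhsi(curve: ExposureResponseCurve, window: tuple[float, float]) -> float:
    """Minimum-mortality HSI: argmin of cumulative log-RR on a 0.1 degC grid.

    Ties break to the lowest HSI; a flat curve (log-RR range < 1e-10) yields
    the window midpoint with a warning.
    """
    lo, hi = window
    if hi < lo:
        raise ValueError("empty MMHSI search window")
    grid = np.arange(lo, hi + 1e-9, 0.1)
    lrr = curve.basis(grid) @ curve.coef_reduced
    if lrr.max() - lrr.min() < 1e-10:
        warnings.warn("flat exposure-response curve; MMHSI set to window midpoint")
        return float(0.5 * (lo + hi))
    return float(grid[int(np.argmin(lrr))])


def profile_threshold(
    sites: list[tuple[pd.DataFrame, pd.Series]],
    thr_grid: np.ndarray,
    spec: CrossBasisSpec | None = None,
    time_df_per_year: float = 7.0,
    refine: bool = True,
) -> tuple[float, pd.DataFrame]:
    """Profile-likelihood estimate of a common hinge threshold (the MMHSI).

    For each candidate threshold the hinge-basis DLNM is refitted at every
    site and the deviances are summed; the threshold minimising the total
    deviance is returned (with optional quadratic interpolation around the
    grid minimum for sub-grid resolution).  This is the segmented-regression
    approach to locating a breakpoint, applied across sites jointly.

    Parameters
    ----------
    sites : list of (mortality DataFrame, daily HSI Series) pairs.
    thr_grid : candidate thresholds, degC.
    spec : cross-basis settings; the exposure part is overridden to 'thr'.

    Returns
    -------
    (threshold estimate, profile table with columns thr and deviance).
    """
    if spec is None:
        spec = CrossBasisSpec()
    thr_grid = np.asarray(thr_grid, dtype=float)
    rows = []
    for thr in thr_grid:
        spec_t = replace(
            spec, exposure_type="thr", exposure_thr=float(thr), exposure_df=1
        )
        dev = 0.0
        for mort, hsi in sites:
            fit = fit_site_model(mort, hsi, spec_t, time_df_per_year=time_df_per_year)
            dev += fit.deviance
        rows.append({"thr": float(thr), "deviance": dev})
    profile = pd.DataFrame(rows)
    i = int(profile["deviance"].idxmin())
    thr_hat = profile.loc[i, "thr"]
    if refine and 0 < i < len(profile) - 1:
        # quadratic interpolation through the three points around the minimum
        x = profile["thr"].to_numpy()[i - 1 : i + 2]
        y = profile["deviance"].to_numpy()[i - 1 : i + 2]
        denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
        if denom != 0:
            a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2]) + x[0] * (y[2] - y[1])) / denom
            b = (x[2] ** 2 * (y[0] - y[1]) + x[1] ** 2 * (y[2] - y[0]) + x[0] ** 2 * (y[1] - y[2])) / denom
            if a > 0:
                vertex = -b / (2 * a)
                if x[0] <= vertex <= x[2]:
                    thr_hat = vertex
    return float(thr_hat), profile


def rr_at(
    curve: ExposureResponseCurve,
    hsi,
    ref: float | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Relative risk (with delta-method CI) at ``hsi`` versus the reference.

    The reference defaults to the curve's MMHSI, where RR = 1 exactly.
    Values outside the curve's fitted HSI range trigger an extrapolation
    warning.
    """
    hsi = np.atleast_1d(np.asarray(hsi, dtype=float))
    ref = curve.mmhsi if ref is None else float(ref)
    lo, hi = curve.hsi_range
    if np.any((hsi < lo) | (hsi > hi)):
        warnings.warn("RR requested outside the fitted HSI range; extrapolating")
    db = curve.basis(hsi) - curve.basis(ref)
    log_rr = db @ curve.coef_reduced
    var = np.einsum("ij,jk,ik->i", db, curve.vcov_reduced, db)
    se = np.sqrt(np.clip(var, 0.0, None))
    z = stats.norm.ppf(1 - alpha / 2)
    return pd.DataFrame(
        {
            "hsi": hsi,
            "rr": np.exp(log_rr),
            "rr_low": np.exp(log_rr - z * se),
            "rr_high": np.exp(log_rr + z * se),
            "log_rr": log_rr,
            "se": se,
        }
    )
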