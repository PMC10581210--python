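"""Cross-basis construction, quasi-Poisson fitting, reduction, and RR."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import heatrisk as hr
from heatrisk.dlnm import (
    CrossBasisSpec,
    ExposureBasis,
    ExposureResponseCurve,
    build_crossbasis,
    find_mmhsi,
    reduction_matrix,
    resolve_basis,
    rr_at,
)
from heatrisk.dlnm import _time_spline


@pytest.fixture(scope="module")
def hsi_series(ten_year_hsi):
    return ten_year_hsi.isel(lat=0, lon=0).to_series()


class TestCrossBasis:
    def test_shape_contract(self):
        rng = np.random.default_rng(0)
        X, cb = build_crossbasis(rng.uniform(0, 40, 1000), CrossBasisSpec(4, lag_df=4))
        assert X.shape == (1000, 16)
        assert np.isnan(X[:21]).all() and np.isfinite(X[21:]).all()

    def test_constant_series_rows_identical(self):
        X, _ = build_crossbasis(np.full(100, 25.0), CrossBasisSpec())
        complete = X[21:]
        np.testing.assert_allclose(
            complete, np.broadcast_to(complete[0], complete.shape), atol=1e-12
        )

    def test_linear_constant_reduces_to_moving_sum(self):
        """exposure lin x lag const: the single column is a 22-day moving sum
        of centred HSI."""
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 40, 300)
        spec = CrossBasisSpec(exposure_df=1, exposure_type="lin", lag_df=1, lag_type="const")
        X, cb = build_crossbasis(x, spec)
        centred = x - cb.exposure.centre
        expected = pd.Series(centred).rolling(22).sum().to_numpy()
        np.testing.assert_allclose(X[21:, 0], expected[21:], atol=1e-9)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            build_crossbasis(np.arange(10.0), CrossBasisSpec())


class TestSiteFit:
    def test_linear_fit_matches_moving_average_glm(self, hsi_series, truth):
        """With a linear/constant cross-basis the cumulative slope equals a
        plain quasi-Poisson GLM on the 22-day moving-mean exposure."""
        w = np.ones(22) / 22
        lin_truth = hr.TrueRiskCurve(mmhsi_true=-100.0, log_rr_slope=0.01, lag_weights=w)
        mort = hr.gen_site_mortality(hsi_series, lin_truth, 30.0, seed=3)
        spec = CrossBasisSpec(exposure_df=1, exposure_type="lin", lag_df=1, lag_type="const")
        fit = hr.fit_site_model(mort, hsi_series, spec)
        curve = hr.reduce_overall(fit)

        dates = pd.DatetimeIndex(mort["date"])
        y = mort["deaths"].to_numpy(float)
        ma = hsi_series.rolling(22).mean().reindex(dates).to_numpy()
        X = np.column_stack(
            [
                np.ones(len(y)),
                ma,
                _time_spline(len(y), 70),
                np.eye(7)[dates.dayofweek][:, 1:],
            ]
        )
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit(scale="X2")
        assert curve.coef_reduced[0] == pytest.approx(res.params[1], rel=1e-6)
        # and both recover the simulated cumulative slope
        assert curve.coef_reduced[0] == pytest.approx(0.01, rel=0.25)

    def test_doubling_counts_preserves_coefficients(self, hsi_series, truth):
        mort = hr.gen_site_mortality(hsi_series, truth, 30.0, seed=4)
        spec = CrossBasisSpec()
        fit1 = hr.fit_site_model(mort, hsi_series, spec)
        doubled = mort.assign(deaths=mort["deaths"] * 2)
        fit2 = hr.fit_site_model(doubled, hsi_series, spec)
        np.testing.assert_allclose(fit2.coef, fit1.coef, atol=5e-3)
        assert fit2.dispersion == pytest.approx(2 * fit1.dispersion, rel=0.05)

    def test_all_zero_deaths_rejected(self, hsi_series):
        mort = pd.DataFrame(
            {"date": hsi_series.index[21:100], "site_id": "z", "deaths": 0}
        )
        with pytest.raises(ValueError):
            hr.fit_site_model(mort, hsi_series)


class TestReduction:
    def test_constant_lag_reduction_is_22x(self, hsi_series, truth):
        """With a constant lag basis the reduction multiplies by lag_max+1."""
        mort = hr.gen_site_mortality(hsi_series, truth, 30.0, seed=5)
        spec = CrossBasisSpec(exposure_df=4, lag_df=1, lag_type="const")
        fit = hr.fit_site_model(mort, hsi_series, spec)
        curve = hr.reduce_overall(fit)
        np.testing.assert_allclose(curve.coef_reduced, 22 * fit.coef, rtol=1e-12)

    def test_vcov_propagation_is_sandwich(self, hsi_series, truth):
        mort = hr.gen_site_mortality(hsi_series, truth, 30.0, seed=6)
        fit = hr.fit_site_model(mort, hsi_series, CrossBasisSpec())
        curve = hr.reduce_overall(fit)
        B = reduction_matrix(fit.basis)
        np.testing.assert_allclose(curve.vcov_reduced, B @ fit.vcov @ B.T, atol=1e-14)


def _quad_curve(centre=30.0):
    """Synthetic ns-basis curve whose log-RR is (x - centre)^2 scaled."""
    knots = np.array([10.0, 20.0, 30.0, 40.0])
    basis = ExposureBasis("ns", knots=knots)
    grid = np.linspace(10, 40, 200)
    target = 0.002 * (grid - centre) ** 2
    coef, *_ = np.linalg.lstsq(basis(grid), target - target.mean(), rcond=None)
    return ExposureResponseCurve(
        basis=basis,
        coef_reduced=coef,
        vcov_reduced=1e-6 * np.eye(3),
        mmhsi=np.nan,
        hsi_range=(10.0, 40.0),
    )


class TestMMHSI:
    def test_u_shaped_curve_minimum_located(self):
        """Grid argmin agrees with a brute-force scan and sits near the
        centre of the U (spline boundary effects allowed a small shift)."""
        curve = _quad_curve(centre=30.0)
        found = find_mmhsi(curve, (15.0, 40.0))
        dense = np.linspace(15.0, 40.0, 25001)
        brute = dense[int(np.argmin(curve.basis(dense) @ curve.coef_reduced))]
        assert found == pytest.approx(brute, abs=0.06)
        assert found == pytest.approx(30.0, abs=1.5)

    def test_monotone_curve_hits_window_floor(self):
        basis = ExposureBasis("lin", centre=0.0)
        curve = ExposureResponseCurve(
            basis=basis,
            coef_reduced=np.array([0.05]),
            vcov_reduced=np.eye(1) * 1e-6,
            mmhsi=np.nan,
            hsi_range=(0.0, 40.0),
        )
        assert find_mmhsi(curve, (12.0, 35.0)) == pytest.approx(12.0, abs=1e-9)

    def test_flat_curve_warns_and_returns_midpoint(self):
        basis = ExposureBasis("lin", centre=0.0)
        curve = ExposureResponseCurve(
            basis=basis,
            coef_reduced=np.array([0.0]),
            vcov_reduced=np.eye(1),
            mmhsi=np.nan,
            hsi_range=(0.0, 40.0),
        )
        with pytest.warns(UserWarning):
            assert find_mmhsi(curve, (10.0, 30.0)) == 20.0


class TestRR:
    def test_rr_is_one_at_reference(self):
        curve = _quad_curve()
        curve.mmhsi = find_mmhsi(curve, (15.0, 40.0))
        out = rr_at(curve, curve.mmhsi)
        assert out["rr"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert out["se"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_ci_widens_with_distance_for_linear_curve(self):
        basis = ExposureBasis("lin", centre=0.0)
        curve = ExposureResponseCurve(
            basis=basis,
            coef_reduced=np.array([0.05]),
            vcov_reduced=np.array([[1e-4]]),
            mmhsi=20.0,
            hsi_range=(0.0, 40.0),
        )
        out = rr_at(curve, [22.0, 25.0, 30.0, 38.0])
        widths = np.log(out["rr_high"]) - np.log(out["rr_low"])
        assert np.all(np.diff(widths) > 0)

    def test_extrapolation_warns(self):
        curve = _quad_curve()
        curve.mmhsi = 30.0
        with pytest.warns(UserWarning):
            rr_at(curve, 60.0)


class TestThresholdProfile:
    def test_profile_recovers_hinge_location(self, recovery, truth):
        """Joint deviance profiling finds the true threshold within 1 degC."""
        assert recovery["thr_hat"] == pytest.approx(truth.mmhsi_true, abs=1.0)
        prof = recovery["profile"]
        # deviance minimum is interior, not at the grid edge
        i = prof["deviance"].idxmin()
        assert 0 < i < len(prof) - 1


class TestNullCalibration:
    def test_null_effect_not_significant(self, hsi_series):
        """A site simulated with zero heat effect yields an insignificant
        joint Wald statistic for the cross-basis block."""
        null_truth = hr.TrueRiskCurve(log_rr_slope=0.0)
        mort = hr.gen_site_mortality(hsi_series, null_truth, 30.0, seed=11)
        fit = hr.fit_site_model(mort, hsi_series, CrossBasisSpec())
        wald = fit.coef @ np.linalg.inv(fit.vcov) @ fit.coef
        from scipy import stats

        p = stats.chi2.sf(wald, len(fit.coef))
        assert p > 0.01
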