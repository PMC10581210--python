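"""Attributable-fraction identities, grid attribution, aggregation, regridding."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

import heatrisk as hr
from heatrisk.dlnm import ExposureBasis, ExposureResponseCurve


def exp_curve(thr=0.0, vcov=1e-8):
    """Hinge curve with slope 1: RR(x) = exp(max(0, x - thr))."""
    return ExposureResponseCurve(
        basis=ExposureBasis("thr", thr=thr),
        coef_reduced=np.array([1.0]),
        vcov_reduced=np.array([[vcov]]),
        mmhsi=thr,
        hsi_range=(-10.0, 10.0),
    )


class TestAttributableFraction:
    @pytest.mark.parametrize("rr, af", [(1.0, 0.0), (2.0, 0.5), (4.0, 0.75)])
    def test_exact_values(self, rr, af):
        assert hr.af_from_rr(rr) == af

    def test_limit_toward_one(self):
        assert hr.af_from_rr(1e6) >= 0.999999
        assert hr.af_from_rr(1e8) > 0.999999

    def test_protective_rr_floored(self):
        assert hr.af_from_rr(0.5) == 0.0
        assert hr.af_from_rr(0.5, floor=False) == -1.0

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            hr.af_from_rr(0.0)


class TestAnnualHeatDeaths:
    def test_three_day_toy_example(self):
        """RR {1.0, 1.25, 2.0}, pop 1e5, mt 2e-5: HD = 2e-5*1e5*(0.2+0.5) = 1.4."""
        curve = exp_curve(thr=0.0)
        days = np.array([0.0, np.log(1.25), np.log(2.0)])  # RR = 1, 1.25, 2
        hd, n_hot = hr.annual_heat_deaths(days, curve, mt=2e-5, pop=1e5)
        assert hd == pytest.approx(1.4, abs=1e-12)
        assert n_hot == 2

    def test_cool_year_contributes_nothing(self):
        curve = exp_curve(thr=5.0)
        hd, n_hot = hr.annual_heat_deaths(np.full(365, 2.0), curve, 1e-5, 1e5)
        assert hd == 0.0 and n_hot == 0

    def test_linearity_in_population_and_rate(self):
        curve = exp_curve()
        days = np.linspace(-1, 3, 365)
        hd1, _ = hr.annual_heat_deaths(days, curve, 2e-5, 1e5)
        hd2, _ = hr.annual_heat_deaths(days, curve, 2e-5, 2e5)
        hd3, _ = hr.annual_heat_deaths(days, curve, 4e-5, 1e5)
        assert hd2 == pytest.approx(2 * hd1) and hd3 == pytest.approx(2 * hd1)

    def test_additive_over_day_partitions(self):
        curve = exp_curve()
        rng = np.random.default_rng(0)
        days = rng.normal(0.5, 1.0, 365)
        hd_all, _ = hr.annual_heat_deaths(days, curve, 2e-5, 1e5)
        cut = 150
        hd_a, _ = hr.annual_heat_deaths(days[:cut], curve, 2e-5, 1e5)
        hd_b, _ = hr.annual_heat_deaths(days[cut:], curve, 2e-5, 1e5)
        assert hd_a + hd_b == pytest.approx(hd_all, rel=1e-12)

    def test_too_many_missing_days_excluded(self):
        curve = exp_curve()
        days = np.full(365, 1.0)
        days[:60] = np.nan
        with pytest.warns(UserWarning):
            hd, _ = hr.annual_heat_deaths(days, curve, 2e-5, 1e5)
        assert np.isnan(hd)


def _toy_grid(n_lat=2, n_lon=3, seed=0):
    rng = np.random.default_rng(seed)
    lat = 30.0 + 0.25 * np.arange(n_lat)
    lon = 110.0 + 0.25 * np.arange(n_lon)
    time = pd.date_range("2020-01-01", "2020-12-31", freq="D")
    hsi = xr.DataArray(
        rng.normal(0.5, 1.5, (time.size, n_lat, n_lon)),
        coords={"time": time, "lat": lat, "lon": lon},
        dims=("time", "lat", "lon"),
    )
    pop = xr.DataArray(
        rng.uniform(1e4, 1e5, (n_lat, n_lon)),
        coords={"lat": lat, "lon": lon},
        dims=("lat", "lon"),
    )
    mask = xr.DataArray(
        np.array([["A", "A", "B"], ["A", "B", "B"]], dtype=object)[:n_lat, :n_lon],
        coords={"lat": lat, "lon": lon},
        dims=("lat", "lon"),
    )
    return hsi, pop, mask


class TestRegionalAggregate:
    def test_cellwise_sum_is_exact(self):
        hsi, pop, mask = _toy_grid()
        curves = {"A": exp_curve(), "B": exp_curve(thr=1.0)}
        cell = hr.grid_heat_deaths(hsi, pop, 2e-5, mask, curves)
        reg = hr.regional_aggregate(cell, mask, pop)
        for region in ("A", "B"):
            expected = float(cell["hd"].values[mask.values == region].sum())
            got = reg.loc[reg["region"] == region, "hd"].iloc[0]
            assert got == pytest.approx(expected, rel=1e-14)
        total = reg.loc[reg["region"] == "total", "hd"].iloc[0]
        assert total == pytest.approx(float(cell["hd"].sum()), rel=1e-14)

    def test_one_cell_region_rate_equals_cell_rate(self):
        hsi, pop, mask = _toy_grid()
        mask.values[:] = "A"
        mask.values[0, 0] = "solo"
        cell = hr.grid_heat_deaths(hsi, pop, 2e-5, mask, {"A": exp_curve(), "solo": exp_curve()})
        reg = hr.regional_aggregate(cell, mask, pop)
        solo = reg[reg["region"] == "solo"].iloc[0]
        assert solo["hm"] == pytest.approx(float(cell["hm"][0, 0]), rel=1e-12)

    def test_merged_region_rate_is_weighted_mean(self):
        hsi, pop, mask = _toy_grid()
        curves = {"A": exp_curve(), "B": exp_curve()}
        cell = hr.grid_heat_deaths(hsi, pop, 2e-5, mask, curves)
        reg = hr.regional_aggregate(cell, mask, pop)
        a, b = (reg[reg["region"] == r].iloc[0] for r in ("A", "B"))
        merged_rate = (a["hd"] + b["hd"]) / (a["pop"] + b["pop"]) * 1000
        assert min(a["hm"], b["hm"]) <= merged_rate <= max(a["hm"], b["hm"])

    def test_zero_population_region_reports_missing_rate(self):
        hsi, pop, mask = _toy_grid()
        pop = pop.where(mask != "B", 0.0)
        cell = hr.grid_heat_deaths(hsi, pop, 2e-5, mask, {"A": exp_curve(), "B": exp_curve()})
        with pytest.warns(UserWarning):
            reg = hr.regional_aggregate(cell, mask, pop)
        assert np.isnan(reg.loc[reg["region"] == "B", "hm"].iloc[0])


class TestDecadalSummary:
    def test_constant_series_ratio_100(self):
        annual = pd.DataFrame({"year": range(1995, 2060), "hm": 0.07})
        out = hr.decadal_summary(annual)
        assert np.allclose(out["ratio_pct"], 100.0)
        assert np.allclose(out["hm"], 0.07)

    def test_change_ratio_arithmetic(self):
        years = list(range(1995, 2015)) + list(range(2030, 2040))
        vals = [0.04] * 20 + [0.10] * 10
        out = hr.decadal_summary(pd.DataFrame({"year": years, "hm": vals}))
        assert out.loc[out["decade"] == 2030, "ratio_pct"].iloc[0] == pytest.approx(250.0)

    def test_half_open_decade_windows(self):
        annual = pd.DataFrame(
            {"year": [2039, 2040], "hm": [1.0, 9.0]}
        )
        base = pd.DataFrame({"year": range(1995, 2015), "hm": 1.0})
        out = hr.decadal_summary(pd.concat([base, annual]), decades=[2030, 2040])
        with_2039 = out[out["decade"] == 2030]["hm"].iloc[0]
        with_2040 = out[out["decade"] == 2040]["hm"].iloc[0]
        assert with_2039 == 1.0 and with_2040 == 9.0


class TestRegrid:
    @staticmethod
    def _fine(values, n=8):
        lat = 30.0 + 0.125 * (np.arange(n) + 0.5)
        lon = 110.0 + 0.125 * (np.arange(n) + 0.5)
        return xr.DataArray(values, coords={"lat": lat, "lon": lon}, dims=("lat", "lon"))

    def test_uniform_field_stays_uniform(self):
        fine = self._fine(np.full((8, 8), 100.0))
        lat = 30.0 + 0.25 * (np.arange(4) + 0.5)
        lon = 110.0 + 0.25 * (np.arange(4) + 0.5)
        coarse = hr.regrid_population(fine, lat, lon)
        np.testing.assert_allclose(coarse.values, coarse.values[0, 0])
        assert float(coarse.sum()) == pytest.approx(float(fine.sum()), rel=1e-12)

    def test_point_mass_spreads_locally(self):
        values = np.zeros((8, 8))
        values[3, 4] = 1000.0
        fine = self._fine(values)
        lat = 30.0 + 0.25 * (np.arange(4) + 0.5)
        lon = 110.0 + 0.25 * (np.arange(4) + 0.5)
        coarse = hr.regrid_population(fine, lat, lon)
        assert int((coarse.values > 1e-9).sum()) <= 4

    def test_random_fields_conserve_total(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            fine = self._fine(rng.lognormal(3.0, 1.0, (8, 8)))
            lat = 30.0 + 0.25 * (np.arange(4) + 0.5)
            lon = 110.0 + 0.25 * (np.arange(4) + 0.5)
            coarse = hr.regrid_population(fine, lat, lon)
            err = abs(float(coarse.sum()) - float(fine.sum())) / float(fine.sum())
            assert err < 1e-3

    def test_disjoint_grids_rejected(self):
        fine = self._fine(np.ones((8, 8)))
        with pytest.raises(ValueError):
            hr.regrid_population(fine, np.array([50.0, 50.25]), np.array([110.1, 110.35]))
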