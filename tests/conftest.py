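"""Shared fixtures: synthetic climate, HSI series, and the multi-site
recovery pipeline reused by several integration-level tests."""

import warnings

import numpy as np
import pytest

import heatrisk as hr
from heatrisk.dlnm import CrossBasisSpec


@pytest.fixture(scope="session")
def ten_year_hsi():
    """Daily HSI for a 2x2 grid over ten years (seasonal subtropical cell)."""
    grid = hr.GridDef(30.0, 30.5, 110.0, 110.5)
    clim = hr.gen_climate(grid, hr.SCENARIOS["ssp245"], (2007, 2016), seed=7)
    return hr.hsi_grid(clim)


@pytest.fixture(scope="session")
def truth():
    return hr.TrueRiskCurve(mmhsi_true=29.0, log_rr_slope=0.05)


@pytest.fixture(scope="session")
def recovery(ten_year_hsi, truth):
    """Ten-site, ten-year parameter-recovery pipeline with a hinge basis.

    Mortality is generated at 30 deaths/day baseline from the known hinge
    risk curve; a common threshold is profiled across sites, hinge DLNMs are
    fitted per site, and the reduced slopes are REML-pooled.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sites = []
        for s in range(10):
            hsi_s = ten_year_hsi.isel(lat=s % 2, lon=(s // 2) % 2).to_series()
            mort = hr.gen_site_mortality(
                hsi_s,
                truth,
                baseline_rate=30.0,
                dispersion=1.2,
                seed=100 + s,
                site_id=f"s{s:02d}",
                region_id="R1",
            )
            sites.append((mort, hsi_s))
        thr_hat, profile = hr.profile_threshold(sites, np.arange(24.0, 34.5, 1.0))
        spec = CrossBasisSpec(exposure_df=1, exposure_type="thr", exposure_thr=thr_hat)
        curves = [hr.reduce_overall(hr.fit_site_model(m, h, spec)) for m, h in sites]
        pooled = hr.pool(curves, region_id="R1")
        region = hr.region_curve(pooled, curves[0])
    return {
        "sites": sites,
        "thr_hat": thr_hat,
        "profile": profile,
        "curves": curves,
        "pooled": pooled,
        "region": region,
    }
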