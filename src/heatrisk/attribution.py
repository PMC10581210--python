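"""Heat-attributable deaths and mortality rates on the climate grid.

Daily attributable deaths at a cell are baseline deaths times the
attributable fraction AF = (RR - 1) / RR of the day's HSI relative to the
regional minimum-mortality HSI; only days with HSI above the MMHSI count as
heat-risk days.  Annual cell totals aggregate to regional deaths and rates
(reported per mille), then to decadal means and change ratios against the
baseline period.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr

from .dlnm import ExposureResponseCurve

__all__ = [
    "af_from_rr",
    "annual_heat_deaths",
    "grid_heat_deaths",
    "regional_aggregate",
    "decadal_summary",
    "regrid_population",
    "REGIONAL_MMHSI_EXAMPLE",
]

# Documented configuration example: regional minimum-mortality HSI (degC) for
# the seven Chinese subregions as estimated from the 195-site surveillance
# analysis this package's methodology follows.  Shipped as a config example,
# not recomputed here.
REGIONAL_MMHSI_EXAMPLE = {
    "NE": 24.0,
    "NC": 26.0,
    "NW": 25.0,
    "EC": 25.0,
    "CC": 35.0,
    "SW": 29.0,
    "SC": 32.0,
}


def af_from_rr(rr, floor: bool = True):
    """Attributable fraction AF = (RR - 1) / RR; floored at 0 by default."""
    rr = np.asarray(rr, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("relative risk must be > 0")
    af = (rr - 1.0) / rr
    if floor:
        af = np.clip(af, 0.0, None)
    return af if af.ndim else float(af)


def annual_heat_deaths(
    hsi_days: np.ndarray,
    curve: ExposureResponseCurve,
    mt: float,
    pop: float,
    max_missing_frac: float = 0.10,
) -> tuple[float, int]:
    """Annual heat-attributable deaths for one cell-year.

    hd = sum over days with HSI > MMHSI of mt * pop * AF(RR(HSI_d)); days at
    or below the MMHSI contribute zero.  Returns (hd, number of heat days).
    Years missing more than ``max_missing_frac`` of days yield NaN with a
    warning so callers can flag and exclude the cell.
    """
    hsi_days = np.asarray(hsi_days, dtype=float)
    missing = ~np.isfinite(hsi_days)
    if missing.mean() > max_missing_frac:
        warnings.warn("cell-year missing more than 10% of days; excluded")
        return float("nan"), 0
    hsi_ok = hsi_days[~missing]
    hot = hsi_ok > curve.mmhsi
    n_hot = int(hot.sum())
    if n_hot == 0:
        return 0.0, 0
    rr = np.exp(curve.log_rr(hsi_ok[hot]))
    hd = float(np.sum(mt * pop * af_from_rr(rr)))
    return hd, n_hot


def grid_heat_deaths(
    hsi: xr.DataArray,
    pop: xr.DataArray,
    mt: xr.DataArray | float,
    region_mask: xr.DataArray,
    curves: dict[str, ExposureResponseCurve],
) -> xr.Dataset:
    """Per-cell annual heat deaths (`hd`) and rate (`hm`, per mille).

    ``hsi`` is daily (time, lat, lon) for one calendar year; ``region_mask``
    holds region labels per cell; ``curves`` maps region label to its
    exposure-response curve.  Cells with zero population get hd = 0 and
    missing hm.
    """
    hsi_v = hsi.transpose("time", "lat", "lon").values
    pop_v = np.asarray(pop.broadcast_like(region_mask).values, dtype=float)
    mt_v = (
        np.asarray(mt.broadcast_like(region_mask).values, dtype=float)
        if isinstance(mt, xr.DataArray)
        else np.full_like(pop_v, float(mt))
    )
    regions = region_mask.values
    hd = np.zeros(pop_v.shape)
    n_hot = np.zeros(pop_v.shape, dtype=int)
    for region, curve in curves.items():
        cells = regions == region
        if not cells.any():
            continue
        sub = hsi_v[:, cells]  # (days, n_cells)
        hot = sub > curve.mmhsi
        af = np.zeros(sub.shape)
        if hot.any():
            rr = np.exp(curve.log_rr(sub[hot]))
            af[hot] = af_from_rr(rr)
        hd[cells] = mt_v[cells] * pop_v[cells] * af.sum(axis=0)
        n_hot[cells] = hot.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        hm = np.where(pop_v > 0, hd / pop_v * 1000.0, np.nan)
    return xr.Dataset(
        {
            "hd": (("lat", "lon"), hd, {"units": "deaths/year"}),
            "hm": (("lat", "lon"), hm, {"units": "per mille"}),
            "heat_days": (("lat", "lon"), n_hot),
        },
        coords=region_mask.coords,
    )


def regional_aggregate(
    cell: xr.Dataset, region_mask: xr.DataArray, pop: xr.DataArray
) -> pd.DataFrame:
    """Regional heat deaths and rates: Reg_HD = sum hd; Reg_HM = Reg_HD / sum pop.

    Regions with zero population report a missing rate.  A 'total' row sums
    all masked cells.
    """
    regions = region_mask.values
    hd = cell["hd"].values
    pop_v = np.asarray(pop.broadcast_like(region_mask).values, dtype=float)
    rows = []
    labels = [r for r in np.unique(regions[regions != None]) if r is not None]  # noqa: E711
    for region in labels:
        cells = regions == region
        reg_hd = float(np.nansum(hd[cells]))
        reg_pop = float(np.nansum(pop_v[cells]))
        if reg_pop == 0:
            warnings.warn(f"region {region} has zero population; rate undefined")
            reg_hm = np.nan
        else:
            reg_hm = reg_hd / reg_pop * 1000.0
        rows.append({"region": region, "hd": reg_hd, "pop": reg_pop, "hm": reg_hm})
    inhabited = np.isin(regions, labels)
    tot_hd = float(np.nansum(hd[inhabited]))
    tot_pop = float(np.nansum(pop_v[inhabited]))
    rows.append(
        {
            "region": "total",
            "hd": tot_hd,
            "pop": tot_pop,
            "hm": tot_hd / tot_pop * 1000.0 if tot_pop > 0 else np.nan,
        }
    )
    return pd.DataFrame(rows)


def decadal_summary(
    annual: pd.DataFrame,
    value_col: str = "hm",
    baseline: tuple[int, int] = (1995, 2014),
    decades: list[int] | None = None,
) -> pd.DataFrame:
    """Per-decade means and change ratios versus the baseline window.

    ``annual`` needs columns year and ``value_col`` (plus optional grouping
    columns such as region/scenario, preserved in the output).  Decades are
    half-open windows [y0, y0 + 10); the ratio is future mean / baseline
    mean x 100 %.
    """
    group_cols = [c for c in annual.columns if c not in ("year", value_col)]
    if decades is None:
        future = annual.loc[annual["year"] > baseline[1], "year"]
        decades = sorted({int(y) - int(y) % 10 for y in future})

    def summarise(g):
        base_rows = g[(g["year"] >= baseline[0]) & (g["year"] <= baseline[1])]
        base = base_rows[value_col].mean()
        out = []
        for d in decades:
            window = g[(g["year"] >= d) & (g["year"] < d + 10)]
            if len(window) == 0:
                continue
            if len(window) < 10:
                warnings.warn(f"decade {d}s covered by only {len(window)} years")
            mean = window[value_col].mean()
            out.append(
                {
                    "decade": d,
                    value_col: mean,
                    "baseline": base,
                    "ratio_pct": mean / base * 100.0 if base else np.nan,
                }
            )
        return pd.DataFrame(out)

    if group_cols:
        return (
            annual.groupby(group_cols, sort=False)
            .apply(summarise, include_groups=False)
            .reset_index(level=-1, drop=True)
            .reset_index()
        )
    return summarise(annual)


def regrid_population(pop_fine: xr.DataArray, lat, lon) -> xr.DataArray:
    """Bilinear regrid of a population field onto a coarser grid.

    Interpolates density linearly onto the target cell centres, then rescales
    so the total person count is conserved (to well under 0.1 %).
    """
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    f_lat, f_lon = pop_fine["lat"].values, pop_fine["lon"].values
    if lat.min() < f_lat.min() - (f_lat[1] - f_lat[0]) or lat.max() > f_lat.max() + (
        f_lat[1] - f_lat[0]
    ):
        raise ValueError("target grid does not overlap the source grid")
    coarse = pop_fine.interp(lat=lat, lon=lon, method="linear", kwargs={"fill_value": 0.0})
    total_fine = float(pop_fine.sum())
    total_coarse = float(coarse.sum())
    if total_coarse <= 0:
        raise ValueError("regridded field sums to zero; grids do not overlap")
    return coarse * (total_fine / total_coarse)
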