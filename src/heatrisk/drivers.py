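"""Temperature-versus-humidity driver decomposition of heat mortality.

For each subregion and scenario, annual mean temperature and humidity over
heat-risk days (HSI above the regional MMHSI) at every inhabited cell are
regressed on annual heat-related mortality with a random forest; the Gini
(variance-reduction) importances of the two features, normalised to sum to
100 %, give their relative contributions.  This attributes variation in
heat mortality *given* established heat risk — it makes no claim that
humidity alone creates heat vulnerability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.ensemble import RandomForestRegressor

__all__ = ["DriverContribution", "driver_table", "gini_contributions"]


@dataclass(frozen=True)
class DriverContribution:
    """Relative contributions of temperature and humidity (percent)."""

    region_id: str
    scenario: str
    temp_share: float
    hum_share: float
    n_rows: int


def driver_table(
    tas: xr.DataArray,
    hurs: xr.DataArray,
    hsi: xr.DataArray,
    hm: xr.DataArray,
    pop: xr.DataArray,
    mmhsi: float,
    year: int | None = None,
) -> pd.DataFrame:
    """Feature/target rows for one year: heat-day mean T and RH per cell.

    Only inhabited cells (pop > 0) enter; cell-years with no day above the
    MMHSI are dropped.  ``tas``/``hurs``/``hsi`` are daily (time, lat, lon);
    ``hm`` and ``pop`` are per-cell annual fields.
    """
    hot = hsi.values > mmhsi  # (time, lat, lon)
    n_hot = hot.sum(axis=0)
    pop_v = np.asarray(pop.broadcast_like(hm).values, dtype=float)
    keep = (pop_v > 0) & (n_hot > 0) & np.isfinite(hm.values)
    if not keep.any():
        raise ValueError("no inhabited cell has heat-risk days; empty driver table")
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.where(n_hot > 0, n_hot, 1)
        t_mean = np.where(hot, tas.values, 0.0).sum(axis=0) / denom
        rh_mean = np.where(hot, hurs.values, 0.0).sum(axis=0) / denom
        t_mean = np.where(n_hot > 0, t_mean, np.nan)
        rh_mean = np.where(n_hot > 0, rh_mean, np.nan)
    out = pd.DataFrame(
        {
            "t_heat_mean": t_mean[keep],
            "rh_heat_mean": rh_mean[keep],
            "hm": hm.values[keep],
        }
    )
    if year is not None:
        out.insert(0, "year", year)
    return out


def gini_contributions(
    table: pd.DataFrame,
    region_id: str = "region",
    scenario: str = "scenario",
    n_trees: int = 500,
    seed: int = 0,
    min_rows: int = 30,
) -> DriverContribution:
    """Random-forest Gini importances of T and RH, scaled to sum to 100 %.

    A regression forest (variance-reduction impurity, both features eligible
    at every split, bootstrap resampling) is fitted to the cell-year table;
    importances are deterministic given the seed.
    """
    if len(table) < min_rows:
        raise ValueError(f"need at least {min_rows} cell-year rows, got {len(table)}")
    y = table["hm"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant heat-mortality target; importances undefined")
    X = table[["t_heat_mean", "rh_heat_mean"]].to_numpy(dtype=float)
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=None,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    imp = forest.feature_importances_
    total = imp.sum()
    if total == 0:
        raise ValueError("forest found no informative splits; importances undefined")
    shares = imp / total * 100.0
    return DriverContribution(
        region_id=region_id,
        scenario=scenario,
        temp_share=float(shares[0]),
        hum_share=float(shares[1]),
        n_rows=len(table),
    )
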