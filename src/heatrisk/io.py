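"""Readers and writers for the pipeline's on-disk formats.

Grids travel as CF-style NetCDF (written with xarray's scipy backend,
NetCDF3 classic); mortality as CSV (date ISO-8601, site_id, deaths, optional
region_id); fitted curves as JSON bundles carrying coefficients, covariance,
basis knots and the MMHSI.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .dlnm import ExposureBasis, ExposureResponseCurve

__all__ = [
    "read_climate",
    "write_climate",
    "read_mortality",
    "write_mortality",
    "save_curve",
    "load_curve",
]

_T_NAMES = ("tas", "temperature", "t2m", "temp")
_RH_NAMES = ("hurs", "relative_humidity", "rh")


def _find_var(ds: xr.Dataset, names) -> str:
    for name in names:
        if name in ds:
            return name
    raise KeyError(
        f"no variable named one of {names} in dataset with {list(ds.data_vars)}"
    )


def read_climate(path) -> xr.Dataset:
    """Load a daily climate grid, normalising units.

    Temperature is converted to degC when stored in Kelvin (units attribute
    'K' or magnitudes above 150); relative humidity to percent when stored as
    a fraction (units '1' or max <= 1.5).  Returns a Dataset with variables
    ``tas`` (degC) and ``hurs`` (%) over (time, lat, lon).
    """
    ds = xr.open_dataset(path, engine="scipy").load()
    t_name = _find_var(ds, _T_NAMES)
    rh_name = _find_var(ds, _RH_NAMES)
    tas = ds[t_name].astype(float)
    hurs = ds[rh_name].astype(float)

    units = str(tas.attrs.get("units", "")).strip()
    if units in ("K", "Kelvin", "kelvin") or float(tas.max()) > 150.0:
        tas = tas - 273.15
    tas.attrs["units"] = "degC"
    rh_units = str(hurs.attrs.get("units", "")).strip()
    if rh_units == "1" or float(hurs.max()) <= 1.5:
        hurs = hurs * 100.0
    hurs.attrs["units"] = "%"
    out = xr.Dataset({"tas": tas, "hurs": hurs})
    out.attrs.update(ds.attrs)
    return out


def write_climate(ds: xr.Dataset, path, kelvin: bool = False) -> None:
    """Write a climate grid to NetCDF (scipy backend, NetCDF3)."""
    out = ds.copy()
    if kelvin:
        out["tas"] = out["tas"] + 273.15
        out["tas"].attrs["units"] = "K"
    out.to_netcdf(path, engine="scipy")


def read_mortality(path) -> pd.DataFrame:
    """Read a mortality CSV (date, site_id, deaths[, region_id])."""
    df = pd.read_csv(path, parse_dates=["date"])
    required = {"date", "site_id", "deaths"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mortality CSV missing columns {sorted(missing)}")
    if (df["deaths"] < 0).any():
        raise ValueError("negative death counts in mortality CSV")
    return df


def write_mortality(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def save_curve(curve: ExposureResponseCurve, path) -> None:
    """Serialise an exposure-response curve to JSON."""
    payload = {
        "basis_kind": curve.basis.kind,
        "knots": None if curve.basis.knots is None else curve.basis.knots.tolist(),
        "centre": curve.basis.centre,
        "thr": curve.basis.thr,
        "coef_reduced": curve.coef_reduced.tolist(),
        "vcov_reduced": curve.vcov_reduced.tolist(),
        "mmhsi": curve.mmhsi,
        "hsi_range": list(curve.hsi_range),
        "region_id": curve.region_id,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_curve(path) -> ExposureResponseCurve:
    payload = json.loads(Path(path).read_text())
    basis = ExposureBasis(
        kind=payload["basis_kind"],
        knots=None if payload["knots"] is None else np.asarray(payload["knots"]),
        centre=payload["centre"],
        thr=payload.get("thr"),
    )
    return ExposureResponseCurve(
        basis=basis,
        coef_reduced=np.asarray(payload["coef_reduced"]),
        vcov_reduced=np.asarray(payload["vcov_reduced"]),
        mmhsi=payload["mmhsi"],
        hsi_range=tuple(payload["hsi_range"]),
        region_id=payload["region_id"],
    )
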