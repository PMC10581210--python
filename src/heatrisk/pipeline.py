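"""End-to-end orchestration: simulate -> HSI -> fit -> pool -> project -> drivers.

A RunConfig describes the grid, scenarios, study windows, cross-basis and
Monte Carlo settings; ``run_pipeline`` executes the stages in order, writes
every artifact class (HSI grids, curve files, attribution tables, envelopes,
driver shares) under one output directory, and stamps a provenance manifest
(config hash, package version, seeds) into each run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .attribution import decadal_summary, grid_heat_deaths, regional_aggregate
from .dlnm import (
    CrossBasisSpec,
    fit_site_model,
    profile_threshold,
    reduce_overall,
    resolve_basis,
)
from .drivers import driver_table, gini_contributions
from .heat_index import heat_index_series
from .io import save_curve, write_climate, write_mortality
from .meta import pool, region_curve
from .synthetic import (
    SCENARIOS,
    GridDef,
    TrueRiskCurve,
    gen_climate,
    gen_population,
    gen_site_mortality,
)
from .uncertainty import ensemble_envelope, heat_deaths_draws, model_seeds, sample_coefficients

log = logging.getLogger("heatrisk")

__all__ = ["RunConfig", "run_pipeline", "hsi_grid", "config_hash"]


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run (synthetic inputs)."""

    grid: GridDef = field(default_factory=lambda: GridDef(30.0, 31.25, 110.0, 111.25))
    scenarios: tuple = ("ssp126", "ssp585")
    baseline_years: tuple = (1995, 2014)
    future_years: tuple = (2031, 2100)
    n_sites: int = 3
    site_years: tuple = (2010, 2016)
    baseline_deaths_per_day: float = 30.0
    baseline_mortality_rate: float = 2e-5  # deaths/person/day
    population_total: float = 1e6
    population_growth: float = 0.02  # per decade
    crossbasis: CrossBasisSpec = field(default_factory=CrossBasisSpec)
    draws: int = 100
    n_models: int = 3
    seed: int = 0
    hsi_mode: str = "nws"

    def __post_init__(self):
        if self.baseline_years[1] >= self.future_years[0]:
            raise ValueError("baseline and future windows must be disjoint")
        if self.draws > 0 and self.seed is None:
            raise ValueError("a seed is required when Monte Carlo draws are requested")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "grid" in raw:
            raw["grid"] = GridDef(**raw["grid"])
        if "crossbasis" in raw:
            raw["crossbasis"] = CrossBasisSpec(**raw["crossbasis"])
        for key in ("scenarios", "baseline_years", "future_years", "site_years"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def hsi_grid(climate: xr.Dataset, mode: str = "nws") -> xr.DataArray:
    """Daily HSI grid from a climate dataset (tas degC, hurs %)."""
    hsi = heat_index_series(climate["tas"].values, climate["hurs"].values, mode=mode)
    return xr.DataArray(
        hsi,
        coords=climate["tas"].coords,
        dims=climate["tas"].dims,
        name="hsi",
        attrs={"units": "degC", "long_name": "heat stress index"},
    )


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
            log.info("stage %s done in %.1fs", name, time.time() - t0)
            return out

        return inner

    return wrap


def run_pipeline(config: RunConfig, outdir, truth: TrueRiskCurve | None = None) -> dict:
    """Run every stage on synthetic inputs and write all artifacts.

    Returns a dict of the in-memory results (curves, tables, envelopes).
    Deterministic for a given (config, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    truth = truth or TrueRiskCurve()
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % 2**31) for name, s in zip(
        ("climate", "population", "mortality", "mc", "models", "drivers"), ss.spawn(6)
    )}

    results: dict = {"config_hash": chash}
    region = "R1"

    # --- simulate site-era climate and mortality, fit and pool curves -----
    site_scenario = SCENARIOS["ssp245"]
    site_climate = gen_climate(
        config.grid, site_scenario, config.site_years, seed=seeds["climate"]
    )
    hsi_site = hsi_grid(site_climate, config.hsi_mode)
    write_climate(site_climate, outdir / f"climate_sites_{chash}.nc")

    sites = []
    for s in range(config.n_sites):
        hsi_s = hsi_site.isel(
            lat=s % hsi_site.sizes["lat"],
            lon=(s // hsi_site.sizes["lat"]) % hsi_site.sizes["lon"],
        ).to_series()
        mort = gen_site_mortality(
            hsi_s,
            truth,
            baseline_rate=config.baseline_deaths_per_day,
            dispersion=1.2,
            seed=seeds["mortality"] + s,
            site_id=f"site{s:03d}",
            region_id=region,
        )
        sites.append((mort, hsi_s))

    cb_spec = config.crossbasis
    if cb_spec.exposure_type == "thr" and cb_spec.exposure_thr is None:
        # estimate the common hinge threshold by profile likelihood over the
        # upper half of the observed HSI distribution
        all_hsi = np.concatenate([h.to_numpy() for _, h in sites])
        grid_thr = np.arange(*np.percentile(all_hsi, [60, 97]), 1.0)
        thr_hat, _ = _stage("profile")(profile_threshold)(sites, grid_thr, cb_spec)
        cb_spec = replace(cb_spec, exposure_thr=thr_hat)
    basis = resolve_basis(np.concatenate([h.to_numpy() for _, h in sites]), cb_spec)

    frames, curves = [], []
    for mort, hsi_s in sites:
        frames.append(mort)
        fit = _stage("fit")(fit_site_model)(mort, hsi_s, basis)
        if fit.converged:
            curves.append(reduce_overall(fit))
    write_mortality(pd.concat(frames), outdir / f"mortality_{chash}.csv")
    if len(curves) < 2:
        raise RuntimeError("pipeline stage 'pool' failed: fewer than 2 converged site fits")
    pooled = _stage("pool")(pool)(curves, region_id=region)
    reg_curve = region_curve(pooled, curves[0])
    save_curve(reg_curve, outdir / f"curve_{region}_{chash}.json")
    results["pooled"] = pooled
    results["curve"] = reg_curve

    # --- projection over scenarios -----------------------------------------
    pop = gen_population(
        config.grid,
        config.population_total,
        config.population_growth,
        (config.baseline_years[0], config.future_years[1]),
        seed=seeds["population"],
    )
    mask = xr.DataArray(
        np.full((config.grid.lats.size, config.grid.lons.size), region, dtype=object),
        coords={"lat": config.grid.lats, "lon": config.grid.lons},
        dims=("lat", "lon"),
    )
    rngs = model_seeds(seeds["models"], config.n_models)
    draws = sample_coefficients(reg_curve, n=max(config.draws, 1), seed=seeds["mc"])

    annual_rows, envelope_rows, driver_frames = [], [], {}
    eval_years = sorted(
        set(range(config.baseline_years[0], config.baseline_years[1] + 1, 5))
        | set(range(config.future_years[0], config.future_years[1] + 1, 10))
    )
    for scen_name in config.scenarios:
        scen = SCENARIOS[scen_name]
        per_model_hm: dict[int, list] = {}
        driver_frames[scen_name] = []
        for m, rng in enumerate(rngs):
            model_seed = int(rng.integers(2**31))
            climate = gen_climate(
                config.grid,
                scen,
                (config.baseline_years[0], config.future_years[1]),
                seed=model_seed,
                ref_year=config.baseline_years[0],
            )
            hsi_all = hsi_grid(climate, config.hsi_mode)
            for year in eval_years:
                hsi_y = hsi_all.sel(time=str(year))
                pop_y = pop["pop"].sel(year=year - year % 10)
                cell = grid_heat_deaths(
                    hsi_y, pop_y, config.baseline_mortality_rate, mask, {region: reg_curve}
                )
                reg = regional_aggregate(cell, mask, pop_y)
                total = reg[reg["region"] == "total"].iloc[0]
                annual_rows.append(
                    {
                        "scenario": scen_name,
                        "model": m,
                        "year": year,
                        "hd": total["hd"],
                        "hm": total["hm"],
                    }
                )
                per_model_hm.setdefault(year, [[] for _ in range(config.n_models)])
                if config.draws > 0:
                    hm_draws = np.zeros(draws.shape[0])
                    for cell_idx in np.ndindex(cell["hd"].shape):
                        hsi_days = hsi_y.values[(slice(None),) + cell_idx]
                        hd_d = heat_deaths_draws(
                            hsi_days,
                            reg_curve,
                            draws,
                            config.baseline_mortality_rate,
                            float(pop_y.values[cell_idx]),
                        )
                        hm_draws += hd_d
                    hm_draws = hm_draws / float(pop_y.sum()) * 1000.0
                    per_model_hm[year][m] = hm_draws
                else:
                    per_model_hm[year][m] = [total["hm"]]
                climate_y = climate.sel(time=str(year))
                try:
                    driver_frames[scen_name].append(
                        driver_table(
                            climate_y["tas"],
                            climate_y["hurs"],
                            hsi_y,
                            cell["hm"],
                            pop_y,
                            reg_curve.mmhsi,
                            year=year,
                        )
                    )
                except ValueError:
                    pass
        for year, per_model in per_model_hm.items():
            env = ensemble_envelope(per_model)
            envelope_rows.append(
                {
                    "scenario": scen_name,
                    "year": year,
                    "hm_mean": env.mean,
                    "hm_lo": env.lo,
                    "hm_hi": env.hi,
                }
            )

    annual = pd.DataFrame(annual_rows)
    annual.to_csv(outdir / f"annual_{chash}.csv", index=False)
    envelopes = pd.DataFrame(envelope_rows)
    envelopes.to_csv(outdir / f"envelopes_{chash}.csv", index=False)
    national = annual.groupby(["scenario", "year"], as_index=False)["hm"].mean()
    decades = decadal_summary(national, value_col="hm", baseline=config.baseline_years)
    decades.to_csv(outdir / f"decades_{chash}.csv", index=False)
    results["annual"] = annual
    results["envelopes"] = envelopes
    results["decades"] = decades

    share_rows = []
    for scen_name, frames_ in driver_frames.items():
        if not frames_:
            continue
        table = pd.concat(frames_, ignore_index=True)
        if len(table) >= 30 and np.ptp(table["hm"].to_numpy()) > 0:
            contrib = gini_contributions(
                table, region_id=region, scenario=scen_name,
                n_trees=200, seed=seeds["drivers"],
            )
            share_rows.append(
                {
                    "scenario": scen_name,
                    "region": region,
                    "temp_share": contrib.temp_share,
                    "hum_share": contrib.hum_share,
                    "n_rows": contrib.n_rows,
                }
            )
    shares = pd.DataFrame(share_rows)
    shares.to_csv(outdir / f"drivers_{chash}.csv", index=False)
    results["drivers"] = shares

    manifest = {
        "config_hash": chash,
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "mmhsi": reg_curve.mmhsi,
    }
    (outdir / f"manifest_{chash}.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    return results
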