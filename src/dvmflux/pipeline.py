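"""End-to-end pipeline: simulate -> preprocess -> isopycnal -> track ->
nitrate-loss -> climatology -> report.

Each stage reads the previous stage's output, writes NetCDF/CSV/JSON into the
run directory and logs what it overrode.  The summary report contains only
numbers traceable to a stage output file, plus provenance (config hash, seed,
package version).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import __version__
from .budget import NitrateLossModel, NitrateLossResults
from .climatology import fit_climatology_line
from .config import AnalysisConfig, RunConfig
from .isopycnal import to_isopycnal
from .metrics import (correlate_gain_loss, estimate_descent_speed,
                      integrate_biomass, n_to_chl_ratio)
from .sensors import FLAG_BELOW_DETECTION, FLAG_GOOD, euphotic_depth, preprocess
from .synthetic import generate_scenario
from .units import convert_flux_units

log = logging.getLogger("dvmflux")

__all__ = ["run_pipeline"]


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Run the configured stages; returns the summary dictionary."""
    cfg.validate()
    if cfg.seed is not None:
        cfg.scenario.seed = int(cfg.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))

    profiles = truth = clean = iso = pairs = results = None

    if "simulate" in cfg.stages:
        log.info("simulate: generating synthetic scenario (seed=%d)",
                 cfg.scenario.seed)
        profiles, truth = generate_scenario(cfg.scenario)
        profiles.to_netcdf(out / "profiles.nc")
        truth.to_netcdf(out / "truth.nc")
    elif cfg.input_path:
        profiles = xr.open_dataset(cfg.input_path)
        missing = {"sigma_theta", "nitrate", "temperature",
                   "salinity"} - set(profiles)
        if missing:
            raise ValueError(f"input is missing required variables: {missing}")

    if "preprocess" in cfg.stages:
        log.info("preprocess: sensor QC / NPQ / PAR / turbidity")
        clean = preprocess(profiles, cfg.analysis)
        clean.to_netcdf(out / "clean.nc")
    else:
        clean = profiles

    if "isopycnal" in cfg.stages:
        log.info("isopycnal: remapping onto %.3f kg m-3 bins",
                 cfg.analysis.density_bin_width)
        iso = to_isopycnal(clean, cfg.analysis)
        iso.to_netcdf(out / "iso.nc")

    model = None
    if "track" in cfg.stages:
        log.info("track: spice binning and reappearance pairing")
        model = NitrateLossModel(iso, config=cfg.analysis)
        pairs = model.pairs
        pairs.to_csv(out / "pairs.csv", index=False)

    if "nitrate-loss" in cfg.stages:
        log.info("nitrate-loss: rate fits and loss-field integration")
        if model is None:
            model = NitrateLossModel(iso, pairs=pairs, config=cfg.analysis)
        results = model.fit()
        results.loss.to_netcdf(out / "loss.nc")
        results.depth_integrated("nloss").to_csv(
            out / "integrated_nloss.csv", index=False)
        results.depth_integrated("rho").to_csv(
            out / "integrated_rho.csv", index=False)

    clim = None
    if "climatology" in cfg.stages:
        log.info("climatology: T-N PDF and cold-branch line fit")
        clim = _stage_climatology(clean, cfg.analysis)
        with open(out / "climatology.json", "w") as fh:
            json.dump(clim, fh, indent=2, sort_keys=True)

    summary = {}
    if "report" in cfg.stages:
        log.info("report: bloom metrics and summary")
        summary = _stage_report(cfg, clean, iso, results, clim)
        summary["provenance"] = {
            "config_hash": cfg.config_hash(),
            "seed": int(cfg.scenario.seed),
            "version": __version__,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _climatology_samples(clean: xr.Dataset, cfg: AnalysisConfig):
    """(T, N) sample pairs from the early-record baseline window.

    Below-detection nitrate enters as zero (the bottle-data analogue of an
    undetectable concentration); unusable cells are dropped.
    """
    t = clean["time"].values
    sel = t <= t[0] + cfg.clim_window_days
    temp = clean["temperature"].values[:, sel].ravel()
    nitr = clean["nitrate"].values[:, sel].ravel()
    flags = clean["nitrate_flag"].values[:, sel].ravel()
    ok = np.isin(flags, (FLAG_GOOD, FLAG_BELOW_DETECTION)) & np.isfinite(nitr)
    return temp[ok], nitr[ok]


def _stage_climatology(clean: xr.Dataset, cfg: AnalysisConfig) -> dict:
    temp, nitr = _climatology_samples(clean, cfg)
    fit = fit_climatology_line(temp, nitr, cfg.t_cutoff, cfg)
    return {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "slope_se": fit.slope_se,
        "intercept_se": fit.intercept_se,
        "t_cutoff": fit.t_cutoff,
        "n_bins": fit.n_bins,
    }


def _bin_series(t, *series, width: float):
    """Average aligned series in consecutive time bins of the given width."""
    if width <= 0:
        return series
    idx = np.floor((t - t[0]) / width).astype(int)
    out = []
    for s in series:
        out.append(np.array([s[idx == k].mean() for k in np.unique(idx)]))
    return tuple(out)


def _first_descent_window(clean: xr.Dataset, cfg: RunConfig):
    sc = cfg.scenario
    start = sc.descent_start_hour / 24.0
    t0 = float(clean["time"].values[0])
    while start < t0:
        start += 1.0
    fit_start = start + cfg.analysis.descent_fit_start_hours / 24.0
    fit_end = start + (24.0 - sc.descent_start_hour + sc.day_start_hour) / 24.0
    return fit_start, fit_end


def _stage_report(cfg: RunConfig, clean: xr.Dataset, iso: xr.Dataset,
                  results: NitrateLossResults | None,
                  clim: dict | None) -> dict:
    a = cfg.analysis
    summary: dict = {}

    # euphotic depth (record median of resolved daytime profiles)
    if "par" in clean:
        par = clean["par"].values
        depth = clean["depth"].values
        zeu = []
        for j in range(par.shape[1]):
            if par[:, j].max() <= 0:
                continue
            z, resolved = euphotic_depth(par[:, j], depth,
                                         a.par_reference_depth)
            if resolved:
                zeu.append(z)
        if zeu:
            summary["median_euphotic_depth_m"] = float(np.median(zeu))

    # descent speed over the first full night of migration
    try:
        window = _first_descent_window(clean, cfg)
        track = estimate_descent_speed(iso, window, a)
        summary["descent_speed_um_s"] = track.speed_um_s
        summary["descent_speed_se_um_s"] = track.speed_se_um_s
    except ValueError as err:
        log.warning("descent tracking skipped: %s", err)

    if results is not None:
        flux, flux_se = results.average_flux()
        flux_mg, flux_mg_se = convert_flux_units(flux, flux_se)
        summary["avg_integrated_loss_rate_mmol_m2_d"] = flux
        summary["avg_integrated_loss_rate_se_mmol_m2_d"] = flux_se
        summary["avg_integrated_loss_rate_mg_m2_d"] = flux_mg
        summary["avg_integrated_loss_rate_se_mg_m2_d"] = flux_mg_se
        summary["modal_loss_rate_mmol_m3_d"] = results.modal_rate(
            zmin=20.0, zmax=a.zmax)

        nloss = results.depth_integrated("nloss")
        ok = ~nloss["flagged"] & np.isfinite(nloss["value"])
        chl = integrate_biomass(iso, "chl", a.zmin, a.zmax)
        turb = integrate_biomass(iso, "turbidity", a.zmin, a.zmax)
        loss_t = nloss.loc[ok, "time"].to_numpy()
        loss_v = nloss.loc[ok, "value"].to_numpy()

        for name, series in (("chl", chl), ("turbidity", turb)):
            sok = ~series["flagged"] & np.isfinite(series["value"])
            sv = np.interp(loss_t, series.loc[sok, "time"],
                           series.loc[sok, "value"])
            gain = sv - sv[0]
            # bin both series (default: daily means) so the diel sweep of the
            # migrating layer across the integration boundary does not
            # swamp the accumulation signal
            lv_b, gain_b = _bin_series(loss_t, loss_v, gain,
                                       width=a.corr_bin_days)
            try:
                r, p, n = correlate_gain_loss(lv_b, gain_b)
                summary[f"corr_nloss_{name}_R"] = r
                summary[f"corr_nloss_{name}_p"] = p
                summary[f"corr_nloss_{name}_n"] = n
            except ValueError as err:
                log.warning("correlation with %s skipped: %s", name, err)

        # N:Chl yield: loss increase and chlorophyll increase taken as
        # differences of 6-h end-member means over the same window, so both
        # sides of the ratio cover identical time spans
        try:
            span = 0.25
            early = loss_t <= loss_t[0] + span
            late = loss_t >= loss_t[-1] - span
            chl_on_loss = np.interp(loss_t, chl.loc[~chl["flagged"], "time"],
                                    chl.loc[~chl["flagged"], "value"])
            d_loss = float(loss_v[late].mean() - loss_v[early].mean())
            d_chl = float(chl_on_loss[late].mean() - chl_on_loss[early].mean())
            ratio, mode = n_to_chl_ratio(d_loss, d_chl, a.ratio_mode)
            summary["n_to_chl_ratio"] = ratio
            summary["n_to_chl_ratio_mode"] = mode
        except ValueError as err:
            log.warning("N:Chl ratio skipped: %s", err)

    # nitrate deficit relative to the in-record baseline climatology
    if clim is not None:
        from .climatology import ClimatologyResults

        fit = ClimatologyResults(
            model=None, slope=clim["slope"], intercept=clim["intercept"],
            slope_se=clim["slope_se"], intercept_se=clim["intercept_se"],
            t_cutoff=clim["t_cutoff"], n_bins=clim["n_bins"], rsquared=np.nan,
        )
        temp = clean["temperature"].values
        nitr = clean["nitrate"].values
        flags = clean["nitrate_flag"].values
        ok = np.isin(flags, (FLAG_GOOD, FLAG_BELOW_DETECTION))
        d = fit.deficit(temp[ok], nitr[ok])
        if np.isfinite(d).any():
            summary["max_nitrate_deficit_mmol_m3"] = float(np.nanmax(d))
        summary["climatology_slope"] = clim["slope"]
        summary["climatology_intercept"] = clim["intercept"]

    return summary
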