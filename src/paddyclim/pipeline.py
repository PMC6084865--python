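"""End-to-end orchestration: simulate → repair → anomalies → correlations →
projections → envelope, with tidy-table outputs and a run manifest.

The stage functions here are the package's statement of the analysis design
(processing order, leads, effective sample size); the numbered scripts under
``analysis/`` and the test-suite experiments all call these rather than
re-plumbing the stages.
"""

from __future__ import annotations

import json
import shutil
import time
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import anomalies, crops, envelope, fields, projection, synthetic, teleconnection
from .config import PipelineConfig, Region, SimConfig
from .fields import PHILIPPINES_BOX

__all__ = [
    "simulate_inputs",
    "crop_anomaly",
    "climate_quarterly_anomaly",
    "pooled_national_correlation",
    "coupling_recovery_estimate",
    "system_contrast_estimates",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Stage helpers


def simulate_inputs(config: SimConfig) -> dict:
    """All synthetic inputs for one seed: index, fields, panel, ensemble, points."""
    enso = synthetic.gen_enso_index(config)
    sm, temp = synthetic.gen_climate_fields(config, enso)
    sst = synthetic.gen_sst(config, enso)
    panel = synthetic.gen_crop_panel(config, sm)
    ensemble = synthetic.gen_model_ensemble(config)
    temp_clim = temp.groupby("time.month").mean("time")
    accessions = synthetic.gen_accessions(config, temp_clim)
    return {
        "enso": enso,
        "soil_moisture": sm,
        "temperature": temp,
        "sst": sst,
        "panel": panel,
        "ensemble": ensemble,
        "temperature_climatology": temp_clim,
        "accessions": accessions,
    }


def crop_anomaly(series: pd.Series, window: int = 27) -> pd.Series:
    """Crop-series anomaly pipeline: interpolate gaps, remove the 27-quarter
    (~7-year) running mean plus residual mean, then the per-quarter climatology."""
    if series.isna().any():
        series = crops.interpolate_missing(series)
    detrended = anomalies.running_mean_detrend(series, window=window)
    return anomalies.remove_annual_cycle(detrended)


def climate_quarterly_anomaly(
    field: xr.DataArray,
    box,
    climatology_period: tuple[int, int] | None = None,
    lead_months: int = 0,
) -> pd.Series:
    """Quarterly regional climate anomaly: cos-weighted box average, annual
    cycle removed over the climatology period, linear trend removed, then
    (optionally shifted forward by ``lead_months``) averaged per quarter.

    With a lead, each quarter's value is the 3-month mean ending ``lead_months``
    before the quarter's own 3-month window — the month-shifted season
    convention (DJF index paired with AMJ soil moisture at a 4-month lead).
    """
    monthly = fields.area_average(field, box)
    anom = anomalies.remove_annual_cycle(monthly, climatology_period)
    anom = anomalies.remove_linear_trend(anom)
    return monthly_series_to_quarterly(anom, lead_months=lead_months)


def monthly_series_to_quarterly(series: pd.Series, lead_months: int = 0) -> pd.Series:
    """3-month means on the quarterly grid, optionally lagged by whole months.

    Shifting the monthly index forward by ``lead_months`` before averaging makes
    quarter (y, q) carry the mean of the 3 months ending ``lead_months`` before
    the end of that quarter. Incomplete edge quarters are dropped.
    """
    shifted = pd.Series(series.values, index=series.index + lead_months)
    grouped = shifted.groupby(shifted.index.asfreq("Q"))
    full = grouped.count() == 3
    out = grouped.mean()[full]
    out.attrs.update(series.attrs)
    out.attrs["lead_months"] = lead_months
    return out


def pooled_national_correlation(
    crop_anom: pd.Series,
    climate_anom: pd.Series,
    lead_quarters: int = 0,
    n_eff: int = 30,
    confidence: float = 0.90,
) -> teleconnection.CorrelationResult:
    """Correlation of two quarterly anomaly series pooled over all quarters.

    Significance follows the seasonal-independence convention: n_eff defaults
    to the number of years (30 → df = 28), not the number of quarterly points.
    """
    lagged = pd.Series(climate_anom.values, index=climate_anom.index + lead_quarters)
    common = crop_anom.index.intersection(lagged.index)
    return teleconnection.lagged_seasonal_correlation(
        crop_anom[common], lagged[common], n_eff=n_eff, lead=lead_quarters,
        confidence=confidence,
    )


# ---------------------------------------------------------------------------
# Validation experiments (known-truth recovery; also used by the test suite)


def _recovery_config(rho: float, n_years: int, seed: int) -> SimConfig:
    """Study configuration with a prescribed production↔soil-moisture coupling.

    One national-box region. Harvested area is held at a flat deterministic
    baseline (no coupling, no noise, no planting cycle or trend), so production
    inherits the yield anomaly and the generating correlation between the log
    production anomaly and the previous-quarter standardized soil-moisture
    anomaly is exactly ``rho``. A strong multiplicative planting cycle on top
    of a growing trend would otherwise leave a growing-amplitude seasonal
    residual that additive detrending cannot remove, confounding the recovery
    experiment with a known limitation of additive anomaly pipelines on
    multiplicative data (see the methods note).
    """
    from dataclasses import replace

    base = SimConfig().crops.systems["irrigated"]
    system = replace(
        base, coupling=rho, area_coupling_frac=0.0, area_noise_sd=0.0,
        area_trend_per_yr=0.0, area_cycle=(1.0, 1.0, 1.0, 1.0),
        yield_noise_sd=0.04,
    )
    from .config import CropParams

    return SimConfig(
        n_years=n_years,
        regions=(Region("NATIONAL-BOX", PHILIPPINES_BOX, weight=1.0),),
        crops=CropParams(systems={"irrigated": system}, missing_fraction=0.0),
        seed=seed,
    )


def coupling_recovery_estimate(
    rho: float, n_years: int = 30, seed: int = 0, window: int = 27
) -> teleconnection.CorrelationResult:
    """Full-pipeline estimate of a prescribed soil-moisture→production coupling.

    Generates one synthetic study at coupling ``rho``, runs the production
    series and the regional soil-moisture field through the standard anomaly
    pipeline, and returns the pooled lagged correlation (1-quarter soil-moisture
    lead, n_eff = n_years).
    """
    cfg = _recovery_config(rho, n_years, seed)
    enso = synthetic.gen_enso_index(cfg)
    sm, _ = synthetic.gen_climate_fields(cfg, enso)
    panel = synthetic.gen_crop_panel(cfg, sm)
    series = crops.extract_series(panel, "NATIONAL-BOX", "irrigated", "production_t")
    c_anom = crop_anomaly(series, window=window)
    s_anom = climate_quarterly_anomaly(sm, PHILIPPINES_BOX)
    return pooled_national_correlation(c_anom, s_anom, lead_quarters=1, n_eff=n_years)


def system_contrast_estimates(
    rainfed_coupling: float = 0.6,
    irrigated_coupling: float = 0.2,
    n_years: int = 30,
    seed: int = 0,
    variable: str = "yield",
) -> dict[str, float]:
    """Pipeline-estimated national correlation per production system.

    Used to check the qualitative ordering that rainfed output tracks soil
    moisture more closely than irrigated output when generated that way.
    """
    from dataclasses import replace

    from .config import CropParams

    defaults = SimConfig().crops.systems
    systems = {
        "irrigated": replace(defaults["irrigated"], coupling=irrigated_coupling),
        "rainfed": replace(defaults["rainfed"], coupling=rainfed_coupling),
    }
    cfg = SimConfig(
        n_years=n_years,
        regions=(Region("NATIONAL-BOX", PHILIPPINES_BOX, weight=1.0),),
        crops=CropParams(systems=systems, missing_fraction=0.0),
        seed=seed,
    )
    enso = synthetic.gen_enso_index(cfg)
    sm, _ = synthetic.gen_climate_fields(cfg, enso)
    panel = synthetic.gen_crop_panel(cfg, sm)
    s_anom = climate_quarterly_anomaly(sm, PHILIPPINES_BOX)
    out = {}
    for system in systems:
        series = crops.extract_series(panel, "NATIONAL-BOX", system, variable)
        c_anom = crop_anomaly(series)
        out[system] = pooled_national_correlation(
            c_anom, s_anom, lead_quarters=1, n_eff=n_years
        ).r
    return out


# ---------------------------------------------------------------------------
# Full pipeline


def _national_table(panel, sm_q, n34_sm_q, n34_crop_q, cfg: PipelineConfig):
    """Headline national correlations (production/yield vs drivers)."""
    rows = []
    for system in sorted(panel.loc[panel.region == crops.NATIONAL, "system"].unique()):
        for variable in ("production_t", "yield"):
            series = crops.extract_series(panel, crops.NATIONAL, system, variable)
            c_anom = crop_anomaly(series, window=cfg.window_quarters)
            label = "production" if variable == "production_t" else "yield"
            res = pooled_national_correlation(
                c_anom, sm_q, lead_quarters=cfg.sm_lead_quarters,
                n_eff=cfg.n_eff_national, confidence=cfg.confidence,
            )
            rows.append((system, label, "soil_moisture",
                         f"{3 * cfg.sm_lead_quarters} months", res))
            res = pooled_national_correlation(
                c_anom, n34_crop_q, lead_quarters=0,
                n_eff=cfg.n_eff_national, confidence=cfg.confidence,
            )
            rows.append((system, label, "nino34",
                         f"{cfg.enso_crop_lead_months} months", res))
    res = pooled_national_correlation(
        sm_q, n34_sm_q, lead_quarters=0, n_eff=cfg.n_eff_national,
        confidence=cfg.confidence,
    )
    rows.append(("-", "soil_moisture", "nino34", f"{cfg.enso_sm_lead_months} months", res))
    return pd.DataFrame(
        [
            {
                "system": system, "variable": variable, "driver": driver,
                "driver_lead": lead, "r": res.r,
                "variance_explained": teleconnection.variance_explained(res.r),
                "df": res.df, "p_value": res.p_value, "significant": res.significant,
            }
            for system, variable, driver, lead, res in rows
        ]
    )


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute every stage from a single config; write tables + manifest.

    Deterministic given ``cfg`` (byte-identical tables for the same seed). On a
    stage error the partially written output directory is removed and the
    error re-raised naming the stage.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    t0 = time.time()
    try:
        inputs = simulate_inputs(cfg.sim)
        panel = crops.national_aggregate(inputs["panel"])

        stage = "climate indices"
        n34 = fields.nino34_index(inputs["sst"], base_period=_base(cfg))
        sm_q = climate_quarterly_anomaly(
            inputs["soil_moisture"], PHILIPPINES_BOX, cfg.climatology_period
        )
        n34_q = monthly_series_to_quarterly(n34)
        n34_sm_q = monthly_series_to_quarterly(n34, lead_months=cfg.enso_sm_lead_months)
        n34_crop_q = monthly_series_to_quarterly(n34, lead_months=cfg.enso_crop_lead_months)

        stage = "national correlations"
        national = _national_table(panel, sm_q, n34_sm_q, n34_crop_q, cfg)
        national.to_csv(outdir / "national_correlations.csv", index=False)
        _national_series_table(panel, sm_q, n34_q, cfg).to_csv(
            outdir / "national_series.csv", index=False
        )

        stage = "regional ENSO-soil moisture map"
        region_names = [r.name for r in cfg.sim.regions]
        sm_regional = {
            r.name: climate_quarterly_anomaly(
                inputs["soil_moisture"], r.box, cfg.climatology_period
            )
            for r in cfg.sim.regions
        }
        enso_map = teleconnection.correlation_map(
            {(name, "-"): sm_regional[name] for name in region_names},
            {name: n34_sm_q for name in region_names},
            variable="soil_moisture_vs_nino34",
            lead_quarters=0,
            n_eff=cfg.n_eff_national,
            confidence=cfg.confidence,
            display_mask=cfg.display_mask,
        )
        enso_map.to_csv(outdir / "enso_soil_moisture_map.csv", index=False)

        stage = "crop correlation maps"
        for variable, label in (("production_t", "production"), ("yield", "yield")):
            crop_anoms = {
                (r, s): crop_anomaly(
                    crops.extract_series(panel, r, s, variable), cfg.window_quarters
                )
                for r in region_names
                for s in sorted(panel.loc[panel.region == r, "system"].unique())
            }
            cmap = teleconnection.correlation_map(
                crop_anoms, sm_regional, variable=label,
                lead_quarters=cfg.sm_lead_quarters, n_eff=cfg.n_eff_national,
                confidence=cfg.confidence, display_mask=cfg.display_mask,
            )
            cmap.to_csv(outdir / f"correlation_map_{label}.csv", index=False)

        stage = "warming projection"
        ens = inputs["ensemble"]
        pattern = projection.canonical_pattern(ens.present, ens.future)
        pattern_ph = projection.pattern_box_series(pattern, PHILIPPINES_BOX)
        observed = fields.area_average(inputs["temperature"], PHILIPPINES_BOX)
        observed_q = monthly_series_to_quarterly(observed)
        scenarios = {
            f"{target:g}C": projection.project_scenario(observed, pattern_ph, target)
            for target in cfg.warming_targets
        }
        scenario_q = {
            label: {
                q: np.concatenate(
                    [
                        monthly_series_to_quarterly(frame[m])[lambda s: s.index.quarter == q].values
                        for m in frame.columns
                    ]
                )
                for q in (1, 2, 3, 4)
            }
            for label, frame in scenarios.items()
        }
        stage = "envelope"
        acc = envelope.accession_quarterly_temps(
            inputs["accessions"], inputs["temperature_climatology"]
        )
        all_vals = [observed_q.values] + [
            np.concatenate(list(d.values())) for d in scenario_q.values()
        ]
        if not acc.empty:
            all_vals.append(acc[[f"q{q}" for q in range(1, 5)]].to_numpy().ravel())
        edges = projection.make_bins(*all_vals, width=cfg.histogram_bin_width)
        hist_rows = []
        observed_hists = {
            q: projection.histogram_counts(
                observed_q[observed_q.index.quarter == q].values, edges
            )
            for q in (1, 2, 3, 4)
        }
        scen_hists = {
            label: {q: projection.histogram_counts(v, edges) for q, v in d.items()}
            for label, d in scenario_q.items()
        }
        for q in (1, 2, 3, 4):
            for label, hists in {"observed": observed_hists, **scen_hists}.items():
                counts = hists[q] if isinstance(hists, dict) else hists
                for lo, c in zip(edges[:-1], counts):
                    hist_rows.append(
                        {"quarter": q, "scenario": label, "bin_left_c": lo,
                         "bin_width_c": cfg.histogram_bin_width, "count": int(c)}
                    )
        pd.DataFrame(hist_rows).to_csv(outdir / "scenario_histograms.csv", index=False)

        exceed_rows = []
        for label, series in [("observed", observed_q)] + [
            (label, pd.concat(
                [monthly_series_to_quarterly(frame[m]) for m in frame.columns]
            ))
            for label, frame in scenarios.items()
        ]:
            st = projection.exceedance_stats(series, threshold=27.0,
                                             bin_width=cfg.histogram_bin_width,
                                             edges=edges)
            exceed_rows.append(
                {"scenario": label, "threshold_c": 27.0,
                 "fraction_above": st["pooled"]["fraction_above"],
                 "max_c": st["pooled"]["max"], "median_c": st["pooled"]["median"]}
            )
        pd.DataFrame(exceed_rows).to_csv(outdir / "exceedance.csv", index=False)

        cross_rows = []
        for target in cfg.warming_targets:
            res = projection.crossing_year(ens.global_anomaly, target)
            for model, year in res["per_model"].items():
                cross_rows.append({"target_c": target, "model": model,
                                   "crossing_year": year})
            cross_rows.append({"target_c": target, "model": "ENSEMBLE_MEDIAN",
                               "crossing_year": res["summary"]["median"]})
        pd.DataFrame(cross_rows).to_csv(outdir / "crossing_years.csv", index=False)

        env = envelope.envelope_summary(
            acc, scen_hists, edges, threshold=cfg.envelope_threshold_c,
            rescale=cfg.envelope_rescale,
        ) if not acc.empty else None
        if env is not None:
            env_rows = [
                {
                    "quarter": q,
                    "fraction_below_threshold": e["fraction_below_threshold"],
                    **{f"overlap_{label}": e["overlap"].get(label, np.nan)
                       for label in scen_hists},
                }
                for q, e in env["by_quarter"].items()
            ]
            pd.DataFrame(env_rows).to_csv(outdir / "envelope_summary.csv", index=False)

        stage = "manifest"
        manifest = {
            "seed": cfg.seed,
            "sim_seed": cfg.sim.seed,
            "n_years": cfg.sim.n_years,
            "window_quarters": cfg.window_quarters,
            "confidence": cfg.confidence,
            "display_mask": cfg.display_mask,
            "n_eff_national": cfg.n_eff_national,
            "warming_targets": list(cfg.warming_targets),
            "sm_lead_quarters": cfg.sm_lead_quarters,
            "enso_sm_lead_months": cfg.enso_sm_lead_months,
            "enso_crop_lead_months": cfg.enso_crop_lead_months,
            "area_weighting": "cos(latitude), cell centers in box",
            "running_mean_edges": "truncate",
            "versions": _versions(),
            "elapsed_s": round(time.time() - t0, 2),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as err:
        shutil.rmtree(outdir, ignore_errors=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    return {
        "national": national,
        "enso_map": enso_map,
        "edges": edges,
        "scenario_histograms": scen_hists,
        "envelope": env,
        "outdir": outdir,
    }


def _base(cfg: PipelineConfig) -> tuple[int, int]:
    if cfg.climatology_period is not None:
        return cfg.climatology_period
    return (cfg.sim.start_year, cfg.sim.start_year + cfg.sim.n_years - 1)


def _national_series_table(panel, sm_q, n34_q, cfg: PipelineConfig) -> pd.DataFrame:
    frames = {}
    for system in sorted(panel.loc[panel.region == crops.NATIONAL, "system"].unique()):
        for variable, label in (("production_t", "production"), ("yield", "yield")):
            series = crops.extract_series(panel, crops.NATIONAL, system, variable)
            anom = anomalies.standardize(
                crop_anomaly(series, window=cfg.window_quarters)
            )
            frames[f"{system}_{label}_anom"] = anom
    frames["soil_moisture_anom"] = anomalies.standardize(sm_q)
    frames["nino34"] = anomalies.standardize(n34_q)
    df = pd.DataFrame(frames)
    df.insert(0, "year", df.index.year)
    df.insert(1, "quarter", df.index.quarter)
    return df.reset_index(drop=True)


def _versions() -> dict:
    import importlib.metadata as md

    out = {}
    for pkg in ("paddyclim", "numpy", "scipy", "pandas", "xarray"):
        try:
            out[pkg] = md.version(pkg)
        except md.PackageNotFoundError:
            out[pkg] = "unknown"
    return out
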