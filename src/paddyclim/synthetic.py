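"""Synthetic inputs with known ground truth.

Every dataset the analysis consumes can be generated here with prescribed
parameters, so each downstream stage is testable without the undistributed
observational sources. The generators are pure functions of ``(config, seed)``:
a single master seed is split into fixed, named sub-streams (one per
generator), so regenerating one input never perturbs another.

Couplings are prescribed as *target correlations*: the corresponding
regression coefficient is computed against the sample-standardized driver
(the ENSO index for gridded fields, the realized regional soil-moisture
anomaly for crop panels), so the generating correlation holds in expectation
whatever the spatial noise structure does under regional averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from .config import SimConfig
from .fields import GridSpec, area_average, make_field, month_index

__all__ = [
    "gen_enso_index",
    "gen_sst",
    "gen_climate_fields",
    "gen_crop_panel",
    "gen_model_ensemble",
    "gen_accessions",
    "ModelEnsemble",
    "temperature_climatology",
    "coupling_coefficient",
]

# Fixed sub-stream identifiers hung off the master seed.
_STREAMS = {
    "enso": 0,
    "sst": 1,
    "fields": 2,
    "crops": 3,
    "ensemble": 4,
    "accessions": 5,
}

_ENSO_BURN_IN_MONTHS = 240


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


def coupling_coefficient(target_corr: float, noise_sd: float) -> float:
    """Regression coefficient on a unit-variance driver yielding ``target_corr``.

    For y = b·s + n with Var(s)=1 and Var(n)=noise_sd², corr(y, s) = target_corr
    when b = target_corr · noise_sd / sqrt(1 − target_corr²).
    """
    if abs(target_corr) >= 1:
        raise ValueError("target correlation must satisfy |r| < 1")
    return target_corr * noise_sd / np.sqrt(1.0 - target_corr**2)


def _standardized(values: np.ndarray) -> np.ndarray:
    v = values - values.mean()
    return v / v.std(ddof=1)


# ---------------------------------------------------------------------------
# ENSO index


def gen_enso_index(config: SimConfig) -> pd.Series:
    """Seasonally phase-locked AR(1) ENSO index, monthly, length 12·n_years.

    x(t) = φ·x(t−1) + σ·a(month)·ε(t); the month-dependent innovation amplitude
    a peaks in boreal winter, reproducing the winter peak of ENSO variance.
    A 20-year burn-in is discarded so the series starts from the stationary
    distribution.
    """
    config.validate()
    p = config.enso
    rng = _rng(config.seed, "enso")
    n = config.n_months + _ENSO_BURN_IN_MONTHS
    amps = np.asarray(p.phase_lock)
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = p.innovation_sd * amps[0] * eps[0]
    for t in range(1, n):
        x[t] = p.ar1 * x[t - 1] + p.innovation_sd * amps[t % 12] * eps[t]
    # burn-in is a multiple of 12, so calendar months stay aligned to January;
    # a PeriodIndex is built directly so multi-millennial runs don't overflow
    # the nanosecond datetime range
    series = pd.Series(
        x[_ENSO_BURN_IN_MONTHS:],
        index=pd.period_range(
            f"{config.start_year}-01", periods=config.n_months, freq="M"
        ),
        name="enso_index",
    )
    series.attrs["units"] = "1"
    return series


# ---------------------------------------------------------------------------
# Spatially correlated noise


@lru_cache(maxsize=8)
def _smoothing_variance_map(nlat: int, nlon: int, sigma: float) -> np.ndarray:
    """Exact per-cell variance of Gaussian-smoothed unit white noise.

    For the linear filter y = A x with white x, Var(y_i) = Σ_j A_ij²; computed
    by pushing every unit impulse through the filter (grids here are small).
    """
    impulses = np.eye(nlat * nlon).reshape(nlat * nlon, nlat, nlon)
    filtered = ndimage.gaussian_filter(
        impulses, sigma=(0.0, sigma, sigma), mode="reflect"
    )
    return (filtered**2).sum(axis=0)


def _smooth_unit_noise(
    rng: np.random.Generator, n_time: int, nlat: int, nlon: int, sigma: float
) -> np.ndarray:
    """Spatially correlated noise, unit variance at every grid cell."""
    white = rng.standard_normal((n_time, nlat, nlon))
    if sigma <= 0:
        return white
    smooth = ndimage.gaussian_filter(white, sigma=(0.0, sigma, sigma), mode="reflect")
    return smooth / np.sqrt(_smoothing_variance_map(nlat, nlon, sigma))


# ---------------------------------------------------------------------------
# Gridded fields


def _lagged_driver(enso: pd.Series, lead_months: int) -> np.ndarray:
    """Sample-standardized ENSO shifted to lead by ``lead_months``; the first
    ``lead_months`` entries (no antecedent index available) carry zero forcing."""
    e = _standardized(enso.values.astype(float))
    out = np.zeros_like(e)
    if lead_months == 0:
        return e
    out[lead_months:] = e[:-lead_months]
    return out


def _month_numbers(n_months: int) -> np.ndarray:
    return np.arange(n_months) % 12 + 1


def soil_moisture_climatology(grid: GridSpec) -> np.ndarray:
    """Monthly-mean soil moisture [mm], wet-season (Sep) peak, flat in space."""
    months = np.arange(1, 13)
    cycle = 400.0 + 80.0 * np.cos(2 * np.pi * (months - 9) / 12.0)
    return np.broadcast_to(
        cycle[:, None, None], (12, grid.lats.size, grid.lons.size)
    ).copy()


def temperature_climatology(grid: GridSpec) -> np.ndarray:
    """Monthly-mean 2 m temperature [°C]: mild May peak, weak poleward cooling.

    Calibrated so Philippines-box quarterly means sit near 26 °C and below
    27 °C, the observed envelope of the 20th-century record.
    """
    months = np.arange(1, 13)
    cycle = 26.0 + 0.7 * np.cos(2 * np.pi * (months - 5) / 12.0)
    lat_term = -0.08 * np.abs(grid.lats - 8.0)
    return (
        cycle[:, None, None]
        + lat_term[None, :, None]
        + np.zeros((12, grid.lats.size, grid.lons.size))
    )


def gen_climate_fields(
    config: SimConfig, enso: pd.Series
) -> tuple[xr.DataArray, xr.DataArray]:
    """Soil-moisture and temperature fields on the regional grid.

    Anomalies at month t carry a term (per-quarter loading) × ENSO(t−4) plus a
    seasonal climatology, a domain-common noise term (large-scale weather) and
    spatially correlated local noise. Soil-moisture loadings are negative and
    weaker in Q3–Q4; temperature loadings positive.
    """
    config.validate()
    if len(enso) != config.n_months:
        raise ValueError(
            f"ENSO series length {len(enso)} does not match config horizon "
            f"{config.n_months}"
        )
    p = config.teleconnection
    grid = config.grid
    nlat, nlon = grid.lats.size, grid.lons.size
    rng = _rng(config.seed, "fields")
    n = config.n_months
    months = _month_numbers(n)
    quarters = (months - 1) // 3  # 0..3
    driver = _lagged_driver(enso, p.lead_months)
    noise_sd = float(np.hypot(p.common_noise_sd, p.local_noise_sd))
    time = month_index(config.start_year, n)

    def build(target_corrs, clim, scale, name, units):
        b = np.array([coupling_coefficient(r, noise_sd) for r in target_corrs])
        signal = b[quarters] * driver
        common = p.common_noise_sd * rng.standard_normal(n)
        local = p.local_noise_sd * _smooth_unit_noise(
            rng, n, nlat, nlon, p.noise_smoothing_cells
        )
        anom = signal[:, None, None] + common[:, None, None] + local
        values = clim[months - 1] + scale * anom
        return make_field(values, grid, time, name, units)

    sm = build(p.sm_corr, soil_moisture_climatology(grid), p.sm_anom_scale,
               "soil_moisture", "mm")
    temp = build(p.temp_corr, temperature_climatology(grid), p.temp_anom_scale,
                 "temperature", "degC")
    return sm, temp


def gen_sst(config: SimConfig, enso: pd.Series) -> xr.DataArray:
    """ENSO-forced SST on the tropical-Pacific grid (for Niño3.4 recovery).

    SST(t,x) = climatology(month) + loading(x)·ENSO(t) + local noise, with the
    loading a Gaussian bump centered in the central equatorial Pacific.
    """
    config.validate()
    if len(enso) != config.n_months:
        raise ValueError("ENSO series length does not match config horizon")
    grid = config.sst_grid
    rng = _rng(config.seed, "sst")
    n = config.n_months
    months = _month_numbers(n)
    lats, lons = grid.lats, grid.lons
    lat2d, lon2d = np.meshgrid(lats, lons, indexing="ij")
    loading = np.exp(-((lat2d / 10.0) ** 2) - ((lon2d - 215.0) / 45.0) ** 2)
    cycle = 27.0 + 1.0 * np.cos(2 * np.pi * (np.arange(1, 13) - 4) / 12.0)
    clim = cycle[:, None, None] - 0.02 * np.abs(lat2d)[None]
    e = _standardized(enso.values.astype(float))
    noise = 0.5 * _smooth_unit_noise(rng, n, lats.size, lons.size, 2.0)
    values = clim[months - 1] + loading[None] * e[:, None, None] + noise
    return make_field(values, grid, month_index(config.start_year, n), "sst", "degC")


# ---------------------------------------------------------------------------
# Crop panel


def regional_sm_driver(soil_moisture: xr.DataArray, box) -> pd.Series:
    """Standardized quarterly regional soil-moisture anomaly (generator truth).

    Field minus its own monthly climatology, cos-weighted box average,
    quarterly means, then sample standardization.
    """
    monthly = area_average(soil_moisture, box)
    clim = monthly.groupby(monthly.index.month).transform("mean")
    anom = monthly - clim
    quarterly = anom.groupby(anom.index.asfreq("Q")).mean()
    return pd.Series(_standardized(quarterly.values), index=quarterly.index)


def gen_crop_panel(config: SimConfig, soil_moisture: xr.DataArray) -> pd.DataFrame:
    """Quarterly crop panel per region × system with known couplings.

    Production is multiplicative — trend × annual cycle × exp(anomaly) — so it
    stays positive; the log-yield anomaly couples to the standardized regional
    soil-moisture anomaly of the previous quarter, harvested area couples at a
    configurable fraction of the yield coupling. A configurable fraction of
    rainfed records is replaced by missing markers (irrigated series are
    complete, as in the source statistics).
    """
    config.validate()
    rng = _rng(config.seed, "crops")
    n_q = 4 * config.n_years
    years = config.start_year + np.arange(n_q) // 4
    quarters = np.arange(n_q) % 4 + 1
    t_years = (np.arange(n_q) // 4).astype(float)

    rows = []
    for region in config.regions:
        s = regional_sm_driver(soil_moisture, region.box).values
        s_lag = np.zeros(n_q)
        s_lag[1:] = s[:-1]
        for system, prm in config.crops.systems.items():
            def _anomaly(rho: float, sd: float) -> np.ndarray:
                # total anomaly s.d. = sd; correlation with s_lag = rho
                if sd == 0:
                    return rho * s_lag  # degenerate: pure signal
                return rho * sd * s_lag + sd * np.sqrt(1 - rho**2) * (
                    rng.standard_normal(n_q)
                )

            y_anom = _anomaly(prm.coupling, prm.yield_noise_sd)
            a_anom = _anomaly(prm.coupling * prm.area_coupling_frac, prm.area_noise_sd)
            area = (
                region.weight
                * prm.base_area_ha
                * np.asarray(prm.area_cycle)[quarters - 1]
                * (1.0 + prm.area_trend_per_yr) ** t_years
                * np.exp(a_anom)
            )
            yld = (
                prm.base_yield_t_ha
                * np.asarray(prm.yield_cycle)[quarters - 1]
                * (1.0 + prm.yield_trend_per_yr) ** t_years
                * np.exp(y_anom)
            )
            production = area * yld
            rows.append(
                pd.DataFrame(
                    {
                        "region": region.name,
                        "system": system,
                        "year": years,
                        "quarter": quarters,
                        "area_ha": area,
                        "production_t": production,
                    }
                )
            )
    panel = pd.concat(rows, ignore_index=True)

    frac = config.crops.missing_fraction
    if frac > 0:
        rainfed = panel.index[panel["system"] == "rainfed"].to_numpy()
        for col in ("area_ha", "production_t"):
            k = int(round(frac * rainfed.size))
            if k:
                hit = rng.choice(rainfed, size=k, replace=False)
                panel.loc[hit, col] = np.nan
    return panel


# ---------------------------------------------------------------------------
# Pseudo-model warming ensemble


@dataclass(frozen=True)
class ModelEnsemble:
    """Per-model monthly climatologies for two epochs plus global-mean series."""

    present: xr.DataArray  # (model, month, lat, lon), °C
    future: xr.DataArray  # same geometry
    delta_t_global: pd.Series  # °C per model (true, by construction)
    global_anomaly: pd.DataFrame  # year × model, °C
    pattern_true: xr.DataArray  # (model, month, lat, lon), °C per °C

    @property
    def models(self) -> list[str]:
        return list(self.present.model.values)


def _area_weights(lats: np.ndarray) -> np.ndarray:
    return np.cos(np.deg2rad(lats))


def _global_annual_mean(pattern: np.ndarray, lats: np.ndarray) -> float:
    w = _area_weights(lats)[None, :, None] * np.ones_like(pattern)
    return float((pattern * w).sum() / w.sum())


def gen_model_ensemble(config: SimConfig) -> ModelEnsemble:
    """Pseudo-model ensemble with known warming patterns and global-mean ΔT.

    Each model's raw pattern 1 + gradient·(lat term) + seasonal·cos(month) is
    renormalized to area-weighted, annually averaged global mean exactly 1, so
    future = present + ΔT·pattern has global annual-mean change exactly ΔT.
    """
    config.validate()
    p = config.warming
    grid = config.grid
    rng = _rng(config.seed, "ensemble")
    lats, lons = grid.lats, grid.lons
    base = temperature_climatology(grid)
    months = np.arange(1, 13)
    lat_norm = (lats - lats.mean()) / max((lats.max() - lats.min()) / 2.0, 1e-9)

    names = [f"model_{i + 1:02d}" for i in range(p.n_models)]
    patterns, deltas = [], []
    for _ in names:
        delta_t = rng.uniform(*p.delta_t_range)
        grad = rng.uniform(*p.gradient_range)
        seas = rng.uniform(*p.seasonal_range)
        raw = (
            1.0
            + grad * lat_norm[None, :, None]
            + seas * np.cos(2 * np.pi * (months[:, None, None] - 1) / 12.0)
        ) * np.ones((12, lats.size, lons.size))
        gm = _global_annual_mean(raw, lats)
        if abs(gm) < 1e-9:
            raise ValueError("pseudo-model pattern has zero global mean")
        patterns.append(raw / gm)
        deltas.append(delta_t)
    if any(d == 0 for d in deltas):
        raise ValueError("zero global-mean warming; pattern normalization undefined")

    coords = {"model": names, "month": months, "lat": lats, "lon": lons}
    pattern = xr.DataArray(
        np.stack(patterns), dims=("model", "month", "lat", "lon"), coords=coords,
        name="warming_pattern", attrs={"units": "K K-1"},
    )
    present = xr.DataArray(
        np.broadcast_to(base, (p.n_models, 12, lats.size, lons.size)).copy(),
        dims=("model", "month", "lat", "lon"), coords=coords,
        name="tas_present", attrs={"units": "degC"},
    )
    delta = pd.Series(deltas, index=names, name="delta_t_global")
    future = present + pattern * xr.DataArray(delta.values, dims="model",
                                              coords={"model": names})
    future.name = "tas_future"
    future.attrs["units"] = "degC"

    y0, y1 = p.series_years
    years = np.arange(y0, y1 + 1)
    # linear warming reaching each model's ΔT between epoch centers 1990→2090
    rates = np.asarray(deltas) / 100.0
    anom = rates[None, :] * (years[:, None] - 1990.0)
    anom = anom + p.series_noise_sd * rng.standard_normal(anom.shape)
    global_anom = pd.DataFrame(anom, index=years, columns=names)

    return ModelEnsemble(
        present=present, future=future, delta_t_global=delta,
        global_anomaly=global_anom, pattern_true=pattern,
    )


# ---------------------------------------------------------------------------
# Rice accessions


TROPICS_LAT = 23.5


def gen_accessions(config: SimConfig, temperature_clim: xr.DataArray) -> pd.DataFrame:
    """Geo-referenced occurrence points clustered around a temperature optimum.

    Cells inside the tropical band (23.5°S–23.5°N) are sampled with weight
    exp(−(T_annual − optimum)² / 2·spread²); points are jittered uniformly
    within their cell (and kept inside both cell and band), so the containing
    grid cell of every point is the cell it was drawn from.
    """
    config.validate()
    p = config.accessions
    rng = _rng(config.seed, "accessions")
    annual = temperature_clim.mean("month") if "month" in temperature_clim.dims else (
        temperature_clim.mean("time")
    )
    lats = annual.lat.values
    lons = annual.lon.values
    band = np.abs(lats) <= TROPICS_LAT
    if p.n_points == 0:
        return pd.DataFrame(columns=["id", "lat", "lon"]).astype(
            {"id": str, "lat": float, "lon": float}
        )
    if not band.any():
        raise ValueError("grid does not intersect the tropical band 23.5°S–23.5°N")
    temps = annual.values[band]  # (nlat_band, nlon)
    w = np.exp(-((temps - p.optimum_c) ** 2) / (2.0 * p.spread_c**2)).ravel()
    if w.sum() == 0:
        raise ValueError("no tropical cell has non-zero occurrence weight")
    cells = rng.choice(w.size, size=p.n_points, p=w / w.sum())
    band_lats = lats[band]
    ilat, ilon = np.unravel_index(cells, temps.shape)
    step_lat = np.diff(lats).mean() if lats.size > 1 else 1.0
    step_lon = np.diff(lons).mean() if lons.size > 1 else 1.0
    jit_lat = rng.uniform(-0.499, 0.499, p.n_points) * step_lat
    jit_lon = rng.uniform(-0.499, 0.499, p.n_points) * step_lon
    lat_pts = np.clip(band_lats[ilat] + jit_lat, -TROPICS_LAT, TROPICS_LAT)
    lon_pts = np.mod(lons[ilon] + jit_lon, 360.0)
    return pd.DataFrame(
        {
            "id": [f"acc_{i + 1:05d}" for i in range(p.n_points)],
            "lat": lat_pts,
            "lon": lon_pts,
        }
    )
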