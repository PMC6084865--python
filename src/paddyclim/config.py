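"""Configuration dataclasses for the synthetic study and the pipeline.

Defaults mirror the study conditions: 30 years of quarterly crop statistics
(1987–2016), a seasonally phase-locked ENSO index, a negative 4-month-lead
ENSO → soil-moisture teleconnection that weakens in Q3–Q4, crop panels with a
technology trend and an annual planting cycle, soil-moisture sensitivity
stronger in rainfed than irrigated systems, an 18-member pseudo-model warming
ensemble, and tropical rice occurrence points clustered near 26 °C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import yaml

from .fields import BoundingBox, GridSpec

__all__ = [
    "Region",
    "EnsoParams",
    "TeleconnectionParams",
    "CropSystemParams",
    "CropParams",
    "WarmingParams",
    "AccessionParams",
    "SimConfig",
    "PipelineConfig",
    "default_regions",
]

SYSTEMS = ("irrigated", "rainfed")


@dataclass(frozen=True)
class Region:
    name: str
    box: BoundingBox
    #: share of national production attributed to the region
    weight: float = 1.0


def default_regions() -> tuple[Region, ...]:
    """Four rectangular stand-ins for Philippine political regions."""
    return (
        Region("Northern Luzon", BoundingBox(119, 123, 15, 22), weight=0.3),
        Region("Central Luzon", BoundingBox(119, 123, 12, 15), weight=0.3),
        Region("Visayas", BoundingBox(121, 126, 9, 12), weight=0.2),
        Region("Mindanao", BoundingBox(121, 127, 4, 9), weight=0.2),
    )


def _check_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"non-finite value in parameter {name!r}")


@dataclass(frozen=True)
class EnsoParams:
    """AR(1) index with month-dependent innovation s.d. (winter phase lock)."""

    ar1: float = 0.9
    innovation_sd: float = 0.25
    #: multiplicative amplitude on the innovation s.d. per calendar month (Jan..Dec);
    #: default peaks in boreal winter (Nov–Jan), the observed ENSO phase locking.
    phase_lock: tuple[float, ...] = tuple(
        1.0 + 0.4 * math.cos(2 * math.pi * (m - 12) / 12.0) for m in range(1, 13)
    )

    def validate(self) -> None:
        _check_finite("ar1", self.ar1)
        _check_finite("innovation_sd", self.innovation_sd)
        _check_finite("phase_lock", *self.phase_lock)
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("ar1 coefficient must lie in [0, 1)")
        if self.innovation_sd <= 0:
            raise ValueError("innovation_sd must be > 0")
        if len(self.phase_lock) != 12 or any(a <= 0 for a in self.phase_lock):
            raise ValueError("phase_lock needs 12 positive amplitudes")


@dataclass(frozen=True)
class TeleconnectionParams:
    """Prescribed standardized lag correlations of gridded anomalies with ENSO.

    ``sm_corr``/``temp_corr`` are target point-wise Pearson correlations (per
    quarter) between the local anomaly and the standardized ENSO index
    ``lead_months`` earlier. Soil-moisture loading is negative (El Niño dries
    the Philippines) and weaker in Q3–Q4; temperature loading is positive.
    """

    lead_months: int = 4
    sm_corr: tuple[float, float, float, float] = (-0.6, -0.55, -0.35, -0.3)
    temp_corr: tuple[float, float, float, float] = (0.45, 0.45, 0.45, 0.45)
    common_noise_sd: float = 0.8
    local_noise_sd: float = 0.6
    #: isotropic Gaussian smoothing length of the local noise, in grid cells
    noise_smoothing_cells: float = 2.0
    #: physical scale of one standardized soil-moisture anomaly unit [mm]
    sm_anom_scale: float = 25.0
    temp_anom_scale: float = 0.4

    def validate(self) -> None:
        for name, vals in (("sm_corr", self.sm_corr), ("temp_corr", self.temp_corr)):
            _check_finite(name, *vals)
            if any(abs(r) >= 1 for r in vals):
                raise ValueError(f"{name} entries must satisfy |r| < 1")
        if self.common_noise_sd <= 0 or self.local_noise_sd < 0:
            raise ValueError("noise s.d. must be positive")
        if self.lead_months < 0:
            raise ValueError("lead_months must be >= 0")


@dataclass(frozen=True)
class CropSystemParams:
    """Generative parameters for one production system within a region.

    ``coupling`` is the target correlation between the (log) yield anomaly and
    the standardized regional soil-moisture anomaly of the previous quarter;
    harvested area couples at ``area_coupling_frac`` of that (planting
    decisions respond to water availability too, more weakly).

    ``yield_noise_sd`` / ``area_noise_sd`` set the *total* standard deviation of
    the log anomalies (signal + noise); the noise share is scaled by
    sqrt(1 − coupling²) so the generating correlation is exactly ``coupling``.
    """

    base_area_ha: float = 500_000.0
    base_yield_t_ha: float = 2.5
    area_trend_per_yr: float = 0.01
    yield_trend_per_yr: float = 0.015
    #: annual planting cycle, multiplicative per quarter (Q4 wet-season peak)
    area_cycle: tuple[float, float, float, float] = (0.95, 0.80, 0.95, 1.30)
    yield_cycle: tuple[float, float, float, float] = (1.05, 1.00, 0.95, 1.00)
    coupling: float = 0.3
    area_coupling_frac: float = 0.5
    yield_noise_sd: float = 0.04
    area_noise_sd: float = 0.06

    def validate(self, system: str) -> None:
        _check_finite(f"{system} crop params", self.base_area_ha, self.base_yield_t_ha,
                      self.area_trend_per_yr, self.yield_trend_per_yr, self.coupling,
                      self.yield_noise_sd, self.area_noise_sd)
        if abs(self.coupling) >= 1:
            raise ValueError("crop coupling must satisfy |rho| < 1")
        if self.base_area_ha <= 0 or self.base_yield_t_ha <= 0:
            raise ValueError("base area and yield must be positive")
        if self.area_trend_per_yr <= -1 or self.yield_trend_per_yr <= -1:
            raise ValueError("trend would drive production non-positive")
        if self.yield_noise_sd < 0 or self.area_noise_sd < 0:
            raise ValueError("noise s.d. must be >= 0")
        if any(c <= 0 for c in self.area_cycle + self.yield_cycle):
            raise ValueError("annual-cycle multipliers must be positive")


def _default_crop_systems() -> dict[str, CropSystemParams]:
    return {
        # Irrigation buffers yield against soil moisture; rainfed is exposed.
        "irrigated": CropSystemParams(
            base_area_ha=600_000, base_yield_t_ha=3.0, area_trend_per_yr=0.02,
            yield_trend_per_yr=0.017, coupling=0.3,
        ),
        "rainfed": CropSystemParams(
            base_area_ha=300_000, base_yield_t_ha=2.0, area_trend_per_yr=0.0,
            yield_trend_per_yr=0.01, coupling=0.5,
            yield_noise_sd=0.05, area_noise_sd=0.08,
        ),
    }


@dataclass(frozen=True)
class CropParams:
    systems: dict[str, CropSystemParams] = dfield(default_factory=_default_crop_systems)
    #: fraction of rainfed records replaced by missing markers (survey gaps run
    #: under 1% of records); irrigated series are complete.
    missing_fraction: float = 0.01

    def validate(self) -> None:
        if set(self.systems) - set(SYSTEMS):
            raise ValueError(f"unknown production system in {sorted(self.systems)}")
        for system, params in self.systems.items():
            params.validate(system)
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")


@dataclass(frozen=True)
class WarmingParams:
    """Pseudo-model ensemble: known warming patterns and global-mean targets."""

    n_models: int = 18
    #: uniform range the per-model global annual-mean warming is drawn from [°C]
    delta_t_range: tuple[float, float] = (2.6, 4.8)
    #: range of the meridional pattern gradient (dimensionless, ± across domain)
    gradient_range: tuple[float, float] = (-0.3, 0.3)
    #: range of the seasonal pattern modulation amplitude
    seasonal_range: tuple[float, float] = (0.0, 0.3)
    #: global annual-mean anomaly series span for crossing-year analysis
    series_years: tuple[int, int] = (1950, 2150)
    series_noise_sd: float = 0.08

    def validate(self) -> None:
        if self.n_models < 1:
            raise ValueError("need at least one pseudo-model")
        if self.delta_t_range[0] <= 0:
            raise ValueError("global-mean warming must be positive (normalization)")


@dataclass(frozen=True)
class AccessionParams:
    n_points: int = 800
    optimum_c: float = 26.0
    spread_c: float = 1.0

    def validate(self) -> None:
        if self.n_points < 0:
            raise ValueError("n_points must be >= 0")
        if self.spread_c <= 0:
            raise ValueError("spread_c must be > 0")


@dataclass(frozen=True)
class SimConfig:
    """Master configuration of the synthetic study. Pure function of (config, seed)."""

    n_years: int = 30
    start_year: int = 1987
    grid: GridSpec = GridSpec(4.0, 22.0, 117.0, 128.0, 1.0)
    sst_grid: GridSpec = GridSpec(-10.0, 10.0, 160.0, 300.0, 2.0)
    regions: tuple[Region, ...] = dfield(default_factory=default_regions)
    enso: EnsoParams = dfield(default_factory=EnsoParams)
    teleconnection: TeleconnectionParams = dfield(default_factory=TeleconnectionParams)
    crops: CropParams = dfield(default_factory=CropParams)
    warming: WarmingParams = dfield(default_factory=WarmingParams)
    accessions: AccessionParams = dfield(default_factory=AccessionParams)
    seed: int = 0

    @property
    def n_months(self) -> int:
        return 12 * self.n_years

    def validate(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        self.enso.validate()
        self.teleconnection.validate()
        self.crops.validate()
        self.warming.validate()
        self.accessions.validate()
        for region in self.regions:
            lat2, lon2 = _box_grid_overlap(region.box, self.grid)
            if not (lat2 and lon2):
                raise ValueError(f"region {region.name!r} does not overlap the grid")


def _box_grid_overlap(box: BoundingBox, grid: GridSpec) -> tuple[bool, bool]:
    import numpy as np

    lats, lons = grid.lats, grid.lons
    lat_ok = bool(((lats >= box.lat_min) & (lats <= box.lat_max)).any())
    lon = np.mod(lons, 360.0)
    if box.lon_min <= box.lon_max:
        lon_ok = bool(((lon >= box.lon_min) & (lon <= box.lon_max)).any())
    else:
        lon_ok = bool(((lon >= box.lon_min) | (lon <= box.lon_max)).any())
    return lat_ok, lon_ok


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end analysis settings (all defaults follow the study design)."""

    sim: SimConfig = dfield(default_factory=SimConfig)
    window_quarters: int = 27
    climatology_period: tuple[int, int] | None = None  # None = full record
    sm_lead_quarters: int = 1
    enso_sm_lead_months: int = 4
    enso_crop_lead_months: int = 7
    confidence: float = 0.90
    display_mask: float = 0.3
    n_eff_national: int = 30
    warming_targets: tuple[float, ...] = (2.0, 4.0)
    histogram_bin_width: float = 0.5
    envelope_threshold_c: float = 28.0
    envelope_rescale: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        self.sim.validate()
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")
        if self.sm_lead_quarters < 0 or self.enso_sm_lead_months < 0:
            raise ValueError("leads must be >= 0")
        if any(t <= 0 for t in self.warming_targets):
            raise ValueError("warming targets must be positive")
        if self.window_quarters % 2 == 0:
            raise ValueError("running-mean window must be odd")


def load_pipeline_config(path) -> PipelineConfig:
    """Read a PipelineConfig from a YAML file (flat overrides of the defaults).

    Only scalar pipeline-level settings and a few common simulation knobs
    (``n_years``, ``seed``, crop couplings, missing fraction) are exposed in
    YAML; anything else is configured in Python.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("sim", {}) or {}
    sim_kwargs = {}
    if "n_years" in sim_raw:
        sim_kwargs["n_years"] = int(sim_raw["n_years"])
    if "seed" in sim_raw:
        sim_kwargs["seed"] = int(sim_raw["seed"])
    crops_raw = sim_raw.get("crops", {}) or {}
    if crops_raw:
        systems = _default_crop_systems()
        from dataclasses import replace

        for system, overrides in (crops_raw.get("systems") or {}).items():
            systems[system] = replace(systems[system], **overrides)
        sim_kwargs["crops"] = CropParams(
            systems=systems,
            missing_fraction=float(
                crops_raw.get("missing_fraction", CropParams().missing_fraction)
            ),
        )
    sim = SimConfig(**sim_kwargs)
    if "climatology_period" in raw and raw["climatology_period"] is not None:
        raw["climatology_period"] = tuple(raw["climatology_period"])
    if "warming_targets" in raw:
        raw["warming_targets"] = tuple(raw["warming_targets"])
    cfg = PipelineConfig(sim=sim, **raw)
    cfg.validate()
    return cfg
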