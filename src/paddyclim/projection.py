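"""Pattern-scaled warming projections.

A per-model canonical warming pattern is the (future − present) monthly
climatology difference normalized by the area-weighted global annual-mean
change, so its global annual mean is exactly 1 (°C per °C of global warming).
A scenario at a target ΔT adds target × pattern(month) to the observed
history, preserving present-day interannual variability; the ensemble axis is
kept model-by-model so inter-model spread survives into the histograms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .fields import BoundingBox

__all__ = [
    "canonical_pattern",
    "pattern_box_series",
    "project_scenario",
    "make_bins",
    "histogram_counts",
    "exceedance_stats",
    "crossing_year",
]


def _cos_weights(da: xr.DataArray) -> xr.DataArray:
    w = np.cos(np.deg2rad(da.lat))
    return w.broadcast_like(da.isel({d: 0 for d in da.dims if d not in ("lat", "lon")}, drop=True))


def canonical_pattern(present: xr.DataArray, future: xr.DataArray) -> xr.DataArray:
    """Normalized warming pattern (…, month, lat, lon), global annual mean = 1.

    Works on a single model or on arrays with a leading ``model`` dimension
    (each model normalized by its own global annual-mean change).
    """
    if present.dims != future.dims or present.shape != future.shape:
        raise ValueError("present and future climatologies have mismatched geometry")
    delta = future - present
    weights = np.cos(np.deg2rad(delta.lat))
    gm = delta.weighted(weights).mean(dim=("month", "lat", "lon"))
    if bool((np.abs(gm) < 1e-12).any()):
        raise ValueError("global annual-mean temperature change is zero; "
                         "pattern normalization undefined")
    pattern = delta / gm
    pattern.name = "warming_pattern"
    pattern.attrs["units"] = "K K-1"
    return pattern


def pattern_box_series(pattern: xr.DataArray, box: BoundingBox) -> pd.DataFrame:
    """cos-weighted box average of a pattern: DataFrame month (1–12) × model."""
    lat2d, lon2d = np.meshgrid(pattern.lat.values, pattern.lon.values, indexing="ij")
    mask = box.contains(lat2d, lon2d)
    if not mask.any():
        raise ValueError("no grid cells inside the bounding box")
    w = xr.DataArray(
        np.cos(np.deg2rad(lat2d)) * mask,
        dims=("lat", "lon"),
        coords={"lat": pattern.lat, "lon": pattern.lon},
    )
    mean = pattern.weighted(w).mean(dim=("lat", "lon"))
    if "model" in mean.dims:
        return mean.transpose("month", "model").to_pandas()
    return mean.to_pandas().to_frame(name="model_01")


def project_scenario_gridded(
    observed: xr.DataArray, pattern: xr.DataArray, target: float
) -> xr.DataArray:
    """Gridded scenario: observed(t, lat, lon) + target × pattern(month(t)).

    ``pattern`` has dims (…, month, lat, lon) on the observed grid (regrid
    first if needed); a leading ``model`` dimension is broadcast into the
    output ensemble axis.
    """
    if not np.array_equal(observed.lat.values, pattern.lat.values) or not (
        np.array_equal(observed.lon.values, pattern.lon.values)
    ):
        raise ValueError("pattern grid does not match the observed-history grid")
    offsets = pattern.sel(month=observed.time.dt.month) * float(target)
    out = observed + offsets.rename({"month": "time"}) if "month" in offsets.dims else (
        observed + offsets
    )
    out.attrs.update(observed.attrs)
    out.attrs["target_deg_c"] = float(target)
    return out


def project_scenario(
    observed: pd.Series, pattern_monthly: pd.DataFrame, target: float
) -> pd.DataFrame:
    """Scenario series per model: observed(t) + target × pattern(month(t)).

    ``observed`` is a monthly Series (PeriodIndex or DatetimeIndex);
    ``pattern_monthly`` is indexed by calendar month 1–12 with one column per
    model. target = 0 returns the observed history bit-for-bit in every column.
    The box-averaged series form is the default analysis mode; see
    :func:`project_scenario_gridded` for whole-field scenarios.
    """
    idx = observed.index
    months = idx.month
    if set(np.unique(months)) - set(pattern_monthly.index):
        raise ValueError("pattern is not defined for every calendar month used")
    offsets = pattern_monthly.reindex(np.asarray(months)).to_numpy() * float(target)
    values = observed.to_numpy(dtype=float)[:, None] + offsets
    out = pd.DataFrame(values, index=idx, columns=pattern_monthly.columns)
    out.attrs["target_deg_c"] = float(target)
    return out


def make_bins(*value_sets, width: float = 0.5) -> np.ndarray:
    """Shared histogram bin edges aligned to integer °C, covering all inputs."""
    allv = np.concatenate([np.asarray(v, dtype=float).ravel() for v in value_sets])
    allv = allv[np.isfinite(allv)]
    if allv.size == 0:
        raise ValueError("no finite values to bin")
    lo = np.floor(allv.min())
    hi = np.ceil(allv.max())
    n = int(round((hi - lo) / width))
    return lo + width * np.arange(n + 1)


def histogram_counts(values, edges: np.ndarray) -> np.ndarray:
    counts, _ = np.histogram(np.asarray(values, dtype=float), bins=edges)
    return counts


def exceedance_stats(
    series: pd.Series, threshold: float, bin_width: float = 0.5,
    edges: np.ndarray | None = None,
) -> dict:
    """Threshold exceedance and distribution summary of a quarterly series.

    Returns pooled statistics (fraction above threshold, max, median, histogram)
    plus the same per calendar quarter when the index is quarterly.
    """
    values = series.dropna()
    if values.empty:
        raise ValueError("empty series")
    if edges is None:
        edges = make_bins(values.values, width=bin_width)

    def _stats(v: np.ndarray) -> dict:
        return {
            "fraction_above": float((v > threshold).mean()),
            "max": float(v.max()),
            "median": float(np.median(v)),
            "counts": histogram_counts(v, edges),
        }

    out = {"pooled": _stats(values.to_numpy(dtype=float)), "edges": edges,
           "threshold": float(threshold)}
    idx = values.index
    if hasattr(idx, "quarter"):
        out["by_quarter"] = {
            q: _stats(values[idx.quarter == q].to_numpy(dtype=float))
            for q in sorted(np.unique(idx.quarter))
        }
    return out


def crossing_year(
    global_anomaly: pd.DataFrame,
    target: float,
    window: int = 21,
    base_period: tuple[int, int] | None = None,
) -> dict:
    """First year each model's smoothed global-mean anomaly reaches ``target``.

    The anomaly (optionally re-baselined to the mean over ``base_period``) is
    smoothed with a centered running mean of ``window`` years (odd; only full
    windows count, so the running mean of a linear ramp equals its center
    value). Models that never cross are reported as None.

    Returns per-model years plus an earliest/median/latest summary over the
    models that cross.
    """
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd (centered)")
    anom = global_anomaly.astype(float)
    if base_period is not None:
        y0, y1 = base_period
        base = anom.loc[(anom.index >= y0) & (anom.index <= y1)].mean()
        anom = anom - base
    smooth = anom.rolling(window, center=True, min_periods=window).mean()

    per_model: dict[str, int | None] = {}
    for model in smooth.columns:
        hit = smooth.index[smooth[model] >= target]
        per_model[model] = int(hit[0]) if len(hit) else None
    crossed = sorted(y for y in per_model.values() if y is not None)
    summary = {
        "earliest": crossed[0] if crossed else None,
        "median": int(np.median(crossed)) if crossed else None,
        "latest": crossed[-1] if crossed else None,
        "n_crossed": len(crossed),
        "n_models": len(per_model),
    }
    return {"per_model": per_model, "summary": summary, "target": float(target)}
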