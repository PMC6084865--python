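"""Anomaly construction.

All correlation analysis downstream operates on anomalies: departures from a
slow technology/warming trend and from the mean annual cycle. Crop series are
detrended with a centered running mean (default 27 quarters ≈ 7 years, the
life cycle of a rice genotype in farming), climate series by removing a
monthly climatology and a linear trend.

Functions accept and return :class:`pandas.Series` with a monthly or quarterly
:class:`pandas.PeriodIndex`; provenance is recorded in ``Series.attrs``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "running_mean_detrend",
    "remove_annual_cycle",
    "remove_linear_trend",
    "standardize",
]


def _calendar_slot(index: pd.PeriodIndex) -> np.ndarray:
    """Calendar month (monthly series) or quarter (quarterly series) per entry."""
    if not isinstance(index, pd.PeriodIndex):
        raise TypeError("series must carry a PeriodIndex")
    f = index.freqstr[0].upper()
    if f == "M":
        return index.month.values
    if f == "Q":
        return index.quarter.values
    raise TypeError(f"unsupported frequency {index.freqstr!r}; need monthly or quarterly")


def running_mean_detrend(
    series: pd.Series, window: int = 27, edges: str = "truncate"
) -> pd.Series:
    """Remove a centered running mean, then the residual total mean.

    anomaly(t) = value(t) − runmean(t), with the residual mean subtracted
    afterwards so the output has exactly zero mean.

    Parameters
    ----------
    window
        Odd window length in time steps (default 27 quarters ≈ 7 years).
    edges
        ``"truncate"`` (default): near the series ends the window is clipped to
        the available points, preserving the full record length.
        ``"trim"``: drop the half-window at each end instead.
    """
    if window % 2 == 0:
        raise ValueError("running-mean window must be odd")
    if len(series) < window:
        raise ValueError(f"series length {len(series)} shorter than window {window}")
    if series.isna().any():
        raise ValueError("series contains missing values; interpolate first")
    smooth = series.rolling(window, center=True, min_periods=1).mean()
    resid = series - smooth
    if edges == "trim":
        half = window // 2
        resid = resid.iloc[half : len(resid) - half]
    elif edges != "truncate":
        raise ValueError(f"unknown edge mode {edges!r}")
    out = resid - resid.mean()
    out.attrs.update(series.attrs)
    out.attrs["detrend"] = {"method": "running_mean", "window": window, "edges": edges}
    return out


def remove_annual_cycle(
    series: pd.Series, climatology_period: tuple[int, int] | None = None
) -> pd.Series:
    """Subtract the mean annual cycle (per calendar month or quarter).

    The climatology is computed over ``climatology_period`` (inclusive year
    range; default: the full series).
    """
    idx = series.index
    if isinstance(idx, pd.DatetimeIndex):
        idx = pd.PeriodIndex(idx, freq="M")
        series = pd.Series(series.values, index=idx, name=series.name)
    slots = _calendar_slot(series.index)
    years = series.index.year.values
    if climatology_period is None:
        climatology_period = (int(years.min()), int(years.max()))
    y0, y1 = climatology_period
    in_base = (years >= y0) & (years <= y1)
    if not in_base.any():
        raise ValueError("climatology period lies outside the series")
    clim = series[in_base].groupby(slots[in_base]).mean()
    missing = set(np.unique(slots)) - set(clim.index)
    if missing:
        raise ValueError(f"climatology period does not cover calendar slots {sorted(missing)}")
    out = series - pd.Series(clim[slots].values, index=series.index)
    out.attrs.update(series.attrs)
    out.attrs["climatology_period"] = (y0, y1)
    return out


def remove_linear_trend(series: pd.Series) -> pd.Series:
    """Subtract the OLS straight line in the time index."""
    if len(series) < 3:
        raise ValueError("need at least 3 points to detrend")
    t = np.arange(len(series), dtype=float)
    slope, intercept = np.polyfit(t, series.values.astype(float), 1)
    out = series - (intercept + slope * t)
    out.attrs.update(series.attrs)
    out.attrs["linear_detrend"] = {"slope_per_step": float(slope)}
    return out


def standardize(series: pd.Series) -> pd.Series:
    """Divide by the n−1 sample standard deviation (unit variance output)."""
    sd = float(series.std(ddof=1))
    if not np.isfinite(sd) or sd == 0.0:
        raise ValueError("cannot standardize a series with zero variance")
    out = series / sd
    out.attrs.update(series.attrs)
    out.attrs["standardized"] = True
    return out
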