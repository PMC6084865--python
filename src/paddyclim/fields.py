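"""Gridded-field geometry: grids, boxes, regridding, area averaging, indices.

Fields are :class:`xarray.DataArray` objects with dimensions ``(time, lat, lon)``,
a monthly-contiguous ``time`` coordinate (datetime64, month starts), ``lat``
strictly increasing, ``lon`` normalized to ``[0, 360)``, and a ``units`` attribute.
Scalar monthly series derived from fields are :class:`pandas.Series` with a
monthly :class:`pandas.PeriodIndex`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from . import anomalies

__all__ = [
    "GridSpec",
    "BoundingBox",
    "NINO34_BOX",
    "PHILIPPINES_BOX",
    "make_field",
    "regrid_bilinear",
    "area_average",
    "nino34_index",
    "monthly_to_seasonal",
]

#: Niño3.4 region, 170°W–120°W and 5°S–5°N (longitudes in [0, 360)).
NINO34_BOX: "BoundingBox"
#: The Philippines, 117°E–128°E and 4°N–22°N.
PHILIPPINES_BOX: "BoundingBox"


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid defined by its bounds and step, in degrees.

    Cell *centers* are at ``min + step/2, min + 3*step/2, ...``; the bounds must
    be an integer number of steps apart.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    step: float

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        if self.lat_min >= self.lat_max or self.lon_min >= self.lon_max:
            raise ValueError("grid bounds must satisfy min < max")
        for lo, hi, name in (
            (self.lat_min, self.lat_max, "lat"),
            (self.lon_min, self.lon_max, "lon"),
        ):
            n = (hi - lo) / self.step
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"grid step does not divide {name} bounds evenly")

    @property
    def lats(self) -> np.ndarray:
        n = int(round((self.lat_max - self.lat_min) / self.step))
        return self.lat_min + self.step * (np.arange(n) + 0.5)

    @property
    def lons(self) -> np.ndarray:
        n = int(round((self.lon_max - self.lon_min) / self.step))
        return np.mod(self.lon_min + self.step * (np.arange(n) + 0.5), 360.0)


def _norm_lon(lon):
    return np.mod(lon, 360.0)


@dataclass(frozen=True)
class BoundingBox:
    """Lat/lon box; longitudes live on [0, 360) and may wrap across 0°.

    A box with ``lon_min > lon_max`` (after normalization) is interpreted as
    wrapping across the 0°/360° meridian.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float

    def __post_init__(self) -> None:
        if self.lat_min >= self.lat_max:
            raise ValueError("lat_min must be < lat_max")
        object.__setattr__(self, "lon_min", float(_norm_lon(self.lon_min)))
        object.__setattr__(self, "lon_max", float(_norm_lon(self.lon_max)))

    def contains(self, lat, lon) -> np.ndarray:
        """Vectorized point-in-box test (cell-center membership)."""
        lat = np.asarray(lat, dtype=float)
        lon = _norm_lon(np.asarray(lon, dtype=float))
        in_lat = (lat >= self.lat_min) & (lat <= self.lat_max)
        if self.lon_min <= self.lon_max:
            in_lon = (lon >= self.lon_min) & (lon <= self.lon_max)
        else:  # wrap-around
            in_lon = (lon >= self.lon_min) | (lon <= self.lon_max)
        return in_lat & in_lon


NINO34_BOX = BoundingBox(lon_min=190.0, lon_max=240.0, lat_min=-5.0, lat_max=5.0)
PHILIPPINES_BOX = BoundingBox(lon_min=117.0, lon_max=128.0, lat_min=4.0, lat_max=22.0)


def month_index(start_year: int, n_months: int) -> pd.DatetimeIndex:
    """Monthly time axis (month starts) beginning in January of ``start_year``."""
    return pd.date_range(f"{start_year}-01-01", periods=n_months, freq="MS")


def make_field(
    values: np.ndarray,
    grid: GridSpec,
    time: pd.DatetimeIndex,
    name: str,
    units: str,
) -> xr.DataArray:
    """Assemble a CF-style (time, lat, lon) DataArray on ``grid``."""
    values = np.asarray(values, dtype=float)
    if values.shape != (len(time), grid.lats.size, grid.lons.size):
        raise ValueError(
            f"values shape {values.shape} does not match (time, lat, lon) = "
            f"({len(time)}, {grid.lats.size}, {grid.lons.size})"
        )
    da = xr.DataArray(
        values,
        dims=("time", "lat", "lon"),
        coords={"time": time, "lat": grid.lats, "lon": grid.lons},
        name=name,
        attrs={"units": units},
    )
    da.lat.attrs.update(units="degrees_north", standard_name="latitude")
    da.lon.attrs.update(units="degrees_east", standard_name="longitude")
    return da


def regrid_bilinear(field: xr.DataArray, target: GridSpec) -> xr.DataArray:
    """Bilinear interpolation of each time slice onto the target grid.

    The target grid must lie inside the source cell-center hull; no
    extrapolation is performed.
    """
    src_lat, src_lon = field.lat.values, field.lon.values
    tgt_lat, tgt_lon = target.lats, target.lons
    if tgt_lat.min() < src_lat.min() or tgt_lat.max() > src_lat.max():
        raise ValueError("target latitudes outside source domain")
    if tgt_lon.min() < src_lon.min() or tgt_lon.max() > src_lon.max():
        raise ValueError("target longitudes outside source domain")
    out = field.interp(lat=tgt_lat, lon=tgt_lon, method="linear")
    out.attrs.update(field.attrs)
    return out


def area_average(field: xr.DataArray, box: BoundingBox) -> pd.Series:
    """cos(latitude)-weighted spatial mean over cells whose centers fall in ``box``.

    Cells with missing values are excluded month-wise with the weights
    renormalized over the remaining cells.

    Returns a monthly Series (PeriodIndex) carrying the field units.
    """
    lat2d, lon2d = np.meshgrid(field.lat.values, field.lon.values, indexing="ij")
    mask = box.contains(lat2d, lon2d)
    if not mask.any():
        raise ValueError("no grid cells inside the bounding box")
    mask_da = xr.DataArray(mask, dims=("lat", "lon"),
                           coords={"lat": field.lat, "lon": field.lon})
    weights = xr.DataArray(
        np.cos(np.deg2rad(lat2d)) * mask,
        dims=("lat", "lon"),
        coords={"lat": field.lat, "lon": field.lon},
    )
    mean = field.where(mask_da).weighted(weights).mean(dim=("lat", "lon"), skipna=True)
    series = pd.Series(
        mean.values,
        index=pd.PeriodIndex(pd.DatetimeIndex(field.time.values), freq="M"),
    )
    series.attrs["units"] = field.attrs.get("units", "")
    series.attrs["box"] = (box.lon_min, box.lon_max, box.lat_min, box.lat_max)
    return series


def nino34_index(sst: xr.DataArray, base_period: tuple[int, int]) -> pd.Series:
    """Niño3.4 index: SST area-averaged over 170°W–120°W, 5°S–5°N, converted to
    anomalies (annual cycle removed over ``base_period``) and linearly detrended.
    """
    box_mean = area_average(sst, NINO34_BOX)
    anom = anomalies.remove_annual_cycle(box_mean, climatology_period=base_period)
    anom = anomalies.remove_linear_trend(anom)
    anom.attrs["index"] = "nino34"
    anom.attrs["base_period"] = base_period
    return anom


def monthly_to_seasonal(
    series: pd.Series, season_start_month: int, length: int = 3
) -> pd.Series:
    """Collapse a monthly series to one seasonal mean per year.

    The season is the ``length`` consecutive months starting at calendar month
    ``season_start_month``; a season that straddles a year boundary (e.g. DJF)
    is labeled by the year of its *final* month. Incomplete seasons at the
    series edges are dropped.
    """
    if not 1 <= season_start_month <= 12:
        raise ValueError("season_start_month must be in 1..12")
    if length < 1:
        raise ValueError("season length must be >= 1")
    idx = series.index
    if isinstance(idx, pd.DatetimeIndex):
        idx = pd.PeriodIndex(idx, freq="M")
        series = pd.Series(series.values, index=idx)
    if not isinstance(idx, pd.PeriodIndex) or idx.freqstr[0] != "M":
        raise TypeError("monthly_to_seasonal requires a monthly series")

    end_month = (season_start_month - 1 + length - 1) % 12 + 1
    rolled = series.rolling(length).mean()  # labeled by final month
    sel = rolled[(rolled.index.month == end_month) & rolled.notna()]
    if sel.empty:
        raise ValueError("series contains no complete season")
    out = pd.Series(sel.values, index=sel.index.year.astype(int))
    out.attrs.update(series.attrs)
    out.attrs["season_start_month"] = season_start_month
    out.attrs["season_length"] = length
    return out
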