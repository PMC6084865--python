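"""Quarterly crop statistics: loading, validation, repair, yield, aggregation.

The canonical in-memory form is a tidy DataFrame ("panel") with columns
``region, system, year, quarter, area_ha, production_t``; single series are
:class:`pandas.Series` with a quarterly :class:`pandas.PeriodIndex` and
``attrs`` metadata (region, system, variable, units).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "load_crop_table",
    "write_crop_table",
    "extract_series",
    "interpolate_missing",
    "compute_yield",
    "aggregate_annual",
    "national_aggregate",
    "NATIONAL",
]

PANEL_COLUMNS = ["region", "system", "year", "quarter", "area_ha", "production_t"]
NATIONAL = "NATIONAL"
_KEY = ["region", "system", "year", "quarter"]


def write_crop_table(panel: pd.DataFrame, path) -> None:
    """CSV dialect shared with the generator: missing values as empty cells."""
    panel[PANEL_COLUMNS].to_csv(path, index=False, na_rep="")


def load_crop_table(path) -> pd.DataFrame:
    """Read and validate a quarterly crop panel CSV.

    Rows with malformed keys (unparseable year/quarter, quarter outside 1–4,
    empty region/system) are dropped with a warning listing their row numbers;
    duplicate (region, system, year, quarter) keys are a hard error. Missing
    numeric cells are kept as missing markers (NaN), never coerced to zero.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = set(PANEL_COLUMNS) - set(raw.columns)
    if missing_cols:
        raise ValueError(f"crop table is missing columns {sorted(missing_cols)}")

    year = pd.to_numeric(raw["year"], errors="coerce")
    quarter = pd.to_numeric(raw["quarter"], errors="coerce")
    bad = (
        year.isna()
        | quarter.isna()
        | ~quarter.isin([1, 2, 3, 4])
        | (raw["region"].str.strip() == "")
        | (raw["system"].str.strip() == "")
    )
    if bad.any():
        rows = (raw.index[bad] + 2).tolist()  # 1-based, after the header line
        warnings.warn(f"dropped {bad.sum()} rows with malformed keys (file rows {rows})")
    panel = raw[~bad].copy()
    panel["year"] = year[~bad].astype(int)
    panel["quarter"] = quarter[~bad].astype(int)
    for col in ("area_ha", "production_t"):
        panel[col] = pd.to_numeric(panel[col].replace("", np.nan), errors="coerce")
        if (panel[col] < 0).any():
            raise ValueError(f"negative values in column {col!r}")

    dup = panel.duplicated(_KEY, keep=False)
    if dup.any():
        key = panel.loc[dup, _KEY].iloc[0].tolist()
        raise ValueError(f"duplicate (region, system, year, quarter) key: {key}")
    return panel[PANEL_COLUMNS].reset_index(drop=True)


def extract_series(
    panel: pd.DataFrame, region: str, system: str, variable: str
) -> pd.Series:
    """One (region, system) series as a quarterly-PeriodIndex Series.

    ``variable`` is a panel column (``production_t``/``area_ha``) or ``yield``
    (computed on the fly).
    """
    sub = panel[(panel["region"] == region) & (panel["system"] == system)]
    if sub.empty:
        raise KeyError(f"no records for region={region!r}, system={system!r}")
    sub = sub.sort_values(["year", "quarter"])
    idx = pd.PeriodIndex.from_fields(year=sub["year"], quarter=sub["quarter"], freq="Q")
    if idx.has_duplicates:
        raise ValueError("duplicate quarters in series")
    units = {"production_t": "t", "area_ha": "ha", "yield": "t/ha"}
    if variable == "yield":
        prod = pd.Series(sub["production_t"].values, index=idx)
        area = pd.Series(sub["area_ha"].values, index=idx)
        series = compute_yield(prod, area)
    else:
        series = pd.Series(sub[variable].values.astype(float), index=idx)
    series.attrs.update(
        region=region, system=system, variable=variable, units=units[variable]
    )
    return series


def interpolate_missing(series: pd.Series) -> pd.Series:
    """Fill missing quarters: linear interpolation inside, nearest value at ends.

    The filled fraction is recorded in ``attrs['fraction_filled']``.
    """
    n_missing = int(series.isna().sum())
    if (len(series) - n_missing) < 2:
        raise ValueError("need at least 2 observed values to interpolate")
    out = series.interpolate(method="linear", limit_area="inside")
    out = out.ffill().bfill()
    out.attrs.update(series.attrs)
    out.attrs["fraction_filled"] = n_missing / len(series)
    return out


def compute_yield(production: pd.Series, area: pd.Series) -> pd.Series:
    """Yield [t/ha] = production / area; zero-area quarters become missing."""
    if not production.index.equals(area.index):
        raise ValueError("production and area time indices are not aligned")
    zero = area == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-area quarters set to missing yield")
    out = production / area.where(~zero)
    out.attrs.update(production.attrs)
    out.attrs["variable"] = "yield"
    out.attrs["units"] = "t/ha"
    return out


def aggregate_annual(panel: pd.DataFrame) -> pd.DataFrame:
    """Annual panel: production and harvested area summed over quarters.

    Harvested area counts crop cycles (several per year), so it is summed like
    production; annual yield = annual production / annual area. Years without
    complete quarterly coverage are excluded and reported via a warning.
    """
    def _year(group: pd.DataFrame):
        if len(group) != 4 or group[["area_ha", "production_t"]].isna().any().any():
            return None
        return pd.Series(
            {
                "area_ha": group["area_ha"].sum(),
                "production_t": group["production_t"].sum(),
            }
        )

    out, dropped = [], []
    for (region, system, year), group in panel.groupby(["region", "system", "year"]):
        agg = _year(group)
        if agg is None:
            dropped.append((region, system, int(year)))
            continue
        out.append({"region": region, "system": system, "year": int(year), **agg})
    if dropped:
        warnings.warn(f"excluded {len(dropped)} incomplete year(s): {dropped[:5]}")
    annual = pd.DataFrame(out)
    if not annual.empty:
        annual["yield_t_ha"] = annual["production_t"] / annual["area_ha"]
    return annual


def national_aggregate(panel: pd.DataFrame) -> pd.DataFrame:
    """Append NATIONAL rows: sums over regions per (system, year, quarter).

    A national quarter is missing if any contributing regional record is
    missing (sums of incomplete surveys are not comparable across time).
    """
    regional = panel[panel["region"] != NATIONAL]
    grouped = regional.groupby(["system", "year", "quarter"], as_index=False).agg(
        area_ha=("area_ha", lambda v: v.sum(min_count=len(v)) if v.notna().all() else np.nan),
        production_t=(
            "production_t",
            lambda v: v.sum(min_count=len(v)) if v.notna().all() else np.nan,
        ),
    )
    grouped.insert(0, "region", NATIONAL)
    return pd.concat([regional, grouped[PANEL_COLUMNS]], ignore_index=True)
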