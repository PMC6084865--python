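"""Climatic envelope of rice occurrence points vs projected temperatures.

Quarterly temperatures are extracted at each occurrence point from the
containing grid cell of a monthly climatology (nearest-cell rather than
bilinear: occurrence coordinates are imprecise at grid scale). The envelope is
compared to present and pattern-scaled quarterly temperature distributions on
shared histogram bins; the scalar overlap statistic (histogram intersection)
is an addition of this package — the original comparison was visual.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr

from .projection import histogram_counts

__all__ = ["accession_quarterly_temps", "envelope_summary", "overlap_coefficient"]

_QUARTER_MONTHS = {1: (1, 2, 3), 2: (4, 5, 6), 3: (7, 8, 9), 4: (10, 11, 12)}


def _containing_cell(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Index of the cell whose center is nearest (= containing cell on a
    regular grid); -1 where the point lies outside the outer cell edges."""
    step = np.diff(centers).mean() if centers.size > 1 else np.inf
    idx = np.abs(points[:, None] - centers[None, :]).argmin(axis=1)
    dist = np.abs(points - centers[idx])
    idx[dist > step / 2 + 1e-9] = -1
    return idx


def accession_quarterly_temps(
    accessions: pd.DataFrame, climatology: xr.DataArray
) -> pd.DataFrame:
    """Attach q1..q4 mean temperatures of each point's containing grid cell.

    ``climatology`` has dims (month, lat, lon). Points outside the grid domain
    or over missing cells are dropped with a warning (not fatal).
    """
    if accessions.empty:
        return accessions.assign(**{f"q{q}": pd.Series(dtype=float) for q in range(1, 5)})
    lats = climatology.lat.values
    lons = climatology.lon.values
    ilat = _containing_cell(accessions["lat"].to_numpy(float), lats)
    ilon = _containing_cell(np.mod(accessions["lon"].to_numpy(float), 360.0), lons)
    inside = (ilat >= 0) & (ilon >= 0)

    clim = climatology.transpose("month", "lat", "lon").values
    out = accessions.loc[inside].copy()
    for q, months in _QUARTER_MONTHS.items():
        qmean = clim[[m - 1 for m in months]].mean(axis=0)
        out[f"q{q}"] = qmean[ilat[inside], ilon[inside]]
    finite = out[[f"q{q}" for q in range(1, 5)]].notna().all(axis=1)
    dropped = int((~inside).sum() + (~finite).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} accession(s) outside the grid or over missing cells")
    return out[finite].reset_index(drop=True)


def overlap_coefficient(counts_a, counts_b) -> float:
    """Histogram intersection of two count vectors on identical bins, in [0, 1].

    Each histogram is normalized to unit mass first, so the statistic is
    symmetric and insensitive to any display rescaling of counts.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("histograms have different numbers of bins")
    if a.sum() == 0 or b.sum() == 0:
        return 0.0
    return float(np.minimum(a / a.sum(), b / b.sum()).sum())


def envelope_summary(
    accessions: pd.DataFrame,
    scenario_histograms: dict,
    edges: np.ndarray,
    threshold: float = 28.0,
    rescale: float = 4.0,
) -> dict:
    """Occurrence envelope vs scenario temperature distributions, per quarter.

    ``scenario_histograms`` maps a scenario label to {quarter: counts} on the
    same ``edges`` (bin mismatch is an error). Returns, per quarter: the
    occurrence histogram (raw and display-rescaled counts), the fraction of
    accession–quarter values below ``threshold``, and the overlap coefficient
    against every scenario. All accession–quarter values are pooled (each
    accession contributes its four quarterly temperatures).
    """
    qcols = [f"q{q}" for q in range(1, 5)]
    if accessions.empty or not set(qcols) <= set(accessions.columns):
        raise ValueError("accessions must carry extracted quarterly temperatures")
    edges = np.asarray(edges, dtype=float)
    n_bins = edges.size - 1
    for label, per_quarter in scenario_histograms.items():
        for q, counts in per_quarter.items():
            if np.asarray(counts).size != n_bins:
                raise ValueError(f"scenario {label!r} quarter {q}: bin count mismatch")

    pooled = accessions[qcols].to_numpy(dtype=float).ravel()
    result = {
        "edges": edges,
        "rescale": float(rescale),
        "fraction_below_threshold": float((pooled < threshold).mean()),
        "threshold": float(threshold),
        "by_quarter": {},
    }
    for q in range(1, 5):
        vals = accessions[f"q{q}"].to_numpy(dtype=float)
        counts = histogram_counts(vals, edges)
        entry = {
            "counts": counts,
            "display_counts": counts * rescale,
            "fraction_below_threshold": float((vals < threshold).mean()),
            "overlap": {
                label: overlap_coefficient(counts, per_quarter[q])
                for label, per_quarter in scenario_histograms.items()
                if q in per_quarter
            },
        }
        result["by_quarter"][q] = entry
    return result
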