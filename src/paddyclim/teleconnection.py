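"""Lagged, season-stratified Pearson correlation with the study's significance
convention.

Significance treats seasonal anomalies as independent between years, giving an
effective sample size equal to the number of years (30 for a 30-year record;
df = 28). Two-tailed t-test; correlation maps mask |r| < 0.3 for display, just
below the 90%-confidence threshold critical_r(0.90, 28) ≈ 0.31.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "critical_r",
    "lagged_seasonal_correlation",
    "correlation_map",
    "null_confidence_fraction",
    "variance_explained",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    lead: int
    n_eff: int
    df: int
    p_value: float
    significant: bool
    confidence: float = 0.90


def critical_r(confidence: float, df: int) -> float:
    """Smallest |r| significant at ``confidence`` under a two-tailed t-test.

    r* = t* / sqrt(t*² + df) with t* the two-tailed critical t value.
    critical_r(0.90, 28) ≈ 0.306, the "~0.31" masking threshold of the maps.
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    t_star = stats.t.ppf(1.0 - (1.0 - confidence) / 2.0, df)
    return float(t_star / np.sqrt(t_star**2 + df))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero variance in a correlated series")
    return float(np.corrcoef(x, y)[0, 1])


def lagged_seasonal_correlation(
    a,
    b,
    n_eff: int | None = None,
    lead: int = 0,
    confidence: float = 0.90,
) -> CorrelationResult:
    """Pearson correlation of two aligned per-year seasonal series.

    ``a`` and ``b`` must already be aligned at the stated lead (pairs lost to
    the lag dropped by the caller; no wrap-around). Pairs with a missing member
    are dropped. ``n_eff`` defaults to the number of complete pairs; the
    p-value uses df = n_eff − 2.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series lengths differ after lag alignment")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {x.size}")
    r = _pearson(x, y)
    if n_eff is None:
        n_eff = int(x.size)
    df = n_eff - 2
    if df < 1:
        raise ValueError("effective sample size leaves no degrees of freedom")
    if 1.0 - r**2 < 1e-15:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(
        r=r, lead=lead, n_eff=n_eff, df=df, p_value=p,
        significant=p <= (1.0 - confidence), confidence=confidence,
    )


def _quarter_values(series: pd.Series, quarter: int) -> pd.Series:
    """Values of one calendar quarter indexed by year."""
    sel = series[series.index.quarter == quarter]
    return pd.Series(sel.values, index=sel.index.year.astype(int))


def correlation_map(
    crop_anomalies: dict[tuple[str, str], pd.Series],
    climate_anomalies: dict[str, pd.Series],
    variable: str,
    lead_quarters: int = 1,
    n_eff: int | None = None,
    confidence: float = 0.90,
    display_mask: float = 0.3,
) -> pd.DataFrame:
    """Region × quarter × system map of lagged correlations (tidy table).

    The crop anomaly in quarter q of each year is correlated with the regional
    climate anomaly ``lead_quarters`` earlier; the alignment crosses year
    boundaries (Q1 pairs with the previous year's Q4). Cells with |r| below
    ``display_mask`` are flagged ``masked`` (white shading in map renderings).

    ``crop_anomalies`` maps (region, system) to quarterly anomaly Series;
    ``climate_anomalies`` maps region to quarterly anomaly Series.
    """
    crop_regions = {region for region, _ in crop_anomalies}
    missing = sorted(crop_regions - set(climate_anomalies))
    if missing:
        raise ValueError(f"regions missing from climate anomalies: {missing}")

    rows = []
    for (region, system), crop in crop_anomalies.items():
        climate = climate_anomalies[region]
        lagged = climate.copy()
        lagged.index = lagged.index + lead_quarters  # climate leads
        for quarter in (1, 2, 3, 4):
            c = _quarter_values(crop, quarter)
            s = _quarter_values(lagged, quarter)
            years = c.index.intersection(s.index)
            res = lagged_seasonal_correlation(
                c[years], s[years], n_eff=n_eff, lead=lead_quarters,
                confidence=confidence,
            )
            rows.append(
                {
                    "region": region,
                    "quarter": quarter,
                    "system": system,
                    "variable": variable,
                    "r": res.r,
                    "n_pairs": len(years),
                    "df": res.df,
                    "p_value": res.p_value,
                    f"significant_{int(round(confidence * 100))}": res.significant,
                    "masked": abs(res.r) < display_mask,
                }
            )
    return pd.DataFrame(rows).sort_values(["variable", "region", "system", "quarter"]).reset_index(drop=True)


def null_confidence_fraction(
    n: int = 30,
    n_replicates: int = 100_000,
    seed: int = 0,
    confidence: float = 0.90,
    threshold: float | None = None,
) -> float:
    """Monte-Carlo check of the significance threshold's confidence level.

    Draws ``n_replicates`` pairs of independent standard-normal series of
    length ``n`` and returns the fraction whose |r| falls below ``threshold``
    (default: the exact critical_r at ``confidence`` and df = n − 2, the value
    the maps print as ~0.31 for n = 30). Under the null this fraction is the
    confidence level itself.
    """
    if threshold is None:
        threshold = critical_r(confidence, n - 2)
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_replicates, n))
    y = rng.standard_normal((n_replicates, n))
    x -= x.mean(axis=1, keepdims=True)
    y -= y.mean(axis=1, keepdims=True)
    num = (x * y).sum(axis=1)
    den = np.sqrt((x**2).sum(axis=1) * (y**2).sum(axis=1))
    r = num / den
    return float((np.abs(r) < threshold).mean())


def variance_explained(r: float) -> float:
    """Shared variance r² of a correlation (0.33 → ≈0.11, 'about 10%')."""
    if abs(r) > 1.0:
        raise ValueError("|r| must be <= 1")
    return float(r) ** 2
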