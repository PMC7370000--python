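"""Temporal and spatial analysis of counterfactual differences.

Covers the daily regional series, the turning-point/delay rule (when does the
observed series fall persistently below both counterfactuals?) and the
cell-level / land-use-stratified spatial summary.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import ANALYSIS_HOURS, DelayEstimate

log = logging.getLogger("deweather")


def daily_series(
    results: pd.DataFrame,
    region: str | None = None,
    per_hour: bool = False,
) -> pd.DataFrame:
    """Daily regional means of observed and counterfactual PM2.5.

    By default all four hour classes are pooled per date; ``per_hour=True``
    keeps them separate.  ``region=None`` returns every region.
    """
    df = results
    if region is not None:
        df = df[df["region"] == region]
        if df.empty:
            raise ValueError(f"no samples for region {region!r}")
    keys = ["region", "date"] + (["hour"] if per_hour else [])
    out = (
        df.groupby(keys, as_index=False)
        .agg(
            obs=("pm_obs", "mean"),
            cf_nsf=("pm_nsf", "mean"),
            cf_nc=("pm_nc", "mean"),
            n=("pm_obs", "size"),
        )
        .sort_values(keys)
        .reset_index(drop=True)
    )
    return out


def detect_turning_point(
    series: pd.DataFrame,
    q: float = 0.75,
    margin: float = 0.0,
    start=None,
) -> DelayEstimate:
    """Earliest date from which the observed series stays below both
    counterfactuals.

    A date qualifies when ``obs < min(cf_nsf, cf_nc) - margin``.  The turning
    point t* is the earliest date that qualifies itself *and* for which at
    least a fraction q of all dates from t* through the period end qualify.
    ``delay_days`` counts calendar days from the period start (day 0).
    """
    if not (0.0 < q <= 1.0):
        raise ValueError("q must be in (0, 1]")
    regions = series["region"].unique()
    if len(regions) != 1:
        raise ValueError("detect_turning_point expects a single-region series")
    s = series.sort_values("date")
    dates = pd.DatetimeIndex(s["date"])
    qualifies = (
        s["obs"].to_numpy() < np.minimum(s["cf_nsf"], s["cf_nc"]).to_numpy() - margin
    )
    start_date = pd.Timestamp(start) if start is not None else dates[0]
    n = len(qualifies)
    t_star = None
    # suffix fractions: fraction of qualifying dates from i through the end
    suffix = np.cumsum(qualifies[::-1])[::-1]
    for i in range(n):
        if qualifies[i] and suffix[i] / (n - i) >= q:
            t_star = dates[i]
            break
    if t_star is None:
        return DelayEstimate(region=regions[0], turning_point=None,
                             delay_days=None, q=q, margin=margin)
    delay = int((t_star.normalize() - start_date.normalize()).days)
    return DelayEstimate(
        region=regions[0],
        turning_point=t_star.date(),
        delay_days=delay,
        q=q,
        margin=margin,
    )


def detect_delays(
    results: pd.DataFrame,
    q: float = 0.75,
    margin: float = 0.0,
    start=None,
) -> pd.DataFrame:
    """Run turning-point detection on the pooled daily series of each region."""
    series = daily_series(results)
    rows = []
    for region in sorted(series["region"].unique()):
        est = detect_turning_point(
            series[series["region"] == region], q=q, margin=margin, start=start
        )
        rows.append(
            {
                "region": region,
                "turning_point": est.turning_point,
                "delay_days": est.delay_days,
                "detected": est.detected,
                "q": q,
                "margin": margin,
            }
        )
    return pd.DataFrame(rows)


def spatial_summary(
    results: pd.DataFrame,
    landuse_map: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell period means and land-use-stratified averages.

    The relative difference follows ``100 * (PMsd - PM̂sd|nsf) / PM̂sd|nsf``
    on the cell's period means; it is undefined (NaN, logged) when the
    counterfactual mean is 0 and such cells are excluded from category means
    of the relative difference.
    """
    cells = (
        results.groupby("cell_id", as_index=False)
        .agg(
            lat=("lat", "first"),
            lon=("lon", "first"),
            region=("region", "first"),
            landuse=("landuse", "first"),
            obs_mean=("pm_obs", "mean"),
            nsf_mean=("pm_nsf", "mean"),
            nc_mean=("pm_nc", "mean"),
            n=("pm_obs", "size"),
        )
    )
    if landuse_map is not None:
        cells["landuse"] = cells["cell_id"].map(landuse_map).fillna("unknown")
    cells["diff_nsf"] = cells["obs_mean"] - cells["nsf_mean"]
    cells["diff_nc"] = cells["obs_mean"] - cells["nc_mean"]
    denom = cells["nsf_mean"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = 100.0 * cells["diff_nsf"].to_numpy() / denom
    rel[denom == 0] = np.nan
    n_undef = int(np.sum(denom == 0))
    if n_undef:
        log.warning("relative difference undefined for %d cells (zero denominator)",
                    n_undef)
    cells["rel_diff_nsf"] = rel
    categories = (
        cells.groupby("landuse", as_index=False)
        .agg(
            n_cells=("cell_id", "size"),
            mean_diff_nsf=("diff_nsf", "mean"),
            mean_diff_nc=("diff_nc", "mean"),
            mean_rel_diff_nsf=("rel_diff_nsf", "mean"),  # NaN cells excluded
        )
        .sort_values("landuse")
        .reset_index(drop=True)
    )
    return cells, categories
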