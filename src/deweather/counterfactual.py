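"""Observed-minus-counterfactual difference statistics.

The target (intervention) period's meteorology is pushed through reference-
scenario models to obtain the PM2.5 expected under the *same weather but
reference emissions*; differences between observation and counterfactual then
quantify the emission-regime change, free of meteorological interference.

Conventions: a region's "All" cell is the unweighted mean of its four hourly
cells (this reproduces the printed regional means of the source analyses); the
cross-region "All" row is sample-weighted and labelled as such.  A cell is
flagged significant when its magnitude exceeds the corresponding model's
cross-validated MAE.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .strf import SpatioTemporalRandomForest
from .types import ANALYSIS_HOURS, FEATURES

#: column names for the two counterfactual comparisons
COMPARISONS = ("nsf", "nc")


def build_counterfactuals(
    target_samples: pd.DataFrame,
    models_nsf: dict[int, SpatioTemporalRandomForest],
    models_nc: dict[int, SpatioTemporalRandomForest],
) -> pd.DataFrame:
    """Predict both counterfactuals for every target-period matched sample.

    Each sample is routed to the reference model of its hour class; features
    are standardized inside each model with its own training parameters.
    Returns the target samples augmented with ``pm_obs``, ``pm_nsf``,
    ``pm_nc``.
    """
    hours = sorted(target_samples["hour"].unique())
    for h in hours:
        for name, models in (("nsf", models_nsf), ("nc", models_nc)):
            if h not in models:
                raise ValueError(f"no {name} model for hour class {h:02d}")
    out = target_samples.copy()
    out["pm_obs"] = out["pm25_mean"]
    out["pm_nsf"] = np.nan
    out["pm_nc"] = np.nan
    for h in hours:
        mask = out["hour"] == h
        X = out.loc[mask, list(FEATURES)]
        out.loc[mask, "pm_nsf"] = models_nsf[h].predict(X)
        out.loc[mask, "pm_nc"] = models_nc[h].predict(X)
    return out


def aggregate_all(hour_values) -> float:
    """A region's "All" summary: unweighted mean of its four hourly means."""
    vals = np.asarray(list(hour_values), dtype=float)
    if len(vals) != len(ANALYSIS_HOURS):
        raise ValueError(f"expected {len(ANALYSIS_HOURS)} hourly cells, got {len(vals)}")
    return float(vals.mean())


def _mae_lookup(cv_reports: pd.DataFrame | None):
    if cv_reports is None:
        return lambda scenario, region, hour: np.nan

    def lookup(scenario: str, region: str, hour) -> float:
        mask = (
            (cv_reports["scenario"] == scenario)
            & (cv_reports["region"] == region)
            & (cv_reports["hour"] == hour)
        )
        if not mask.any():
            raise ValueError(
                f"region {region!r} / hour {hour} absent from CV report for {scenario}"
            )
        return float(cv_reports.loc[mask, "mae"].iloc[0])

    return lookup


def difference_table(
    results: pd.DataFrame,
    cv_reports: pd.DataFrame | None = None,
    scenario_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Mean observed-minus-counterfactual differences per region and hour.

    Returns a long table with one row per (region, comparison, hour-or-"All");
    ``value`` is the arithmetic mean of per-sample differences for hourly
    cells and the unweighted mean of the four hourly cells for a region's
    "All".  The bottom cross-region "All" rows are sample-weighted means.
    ``significant`` flags cells whose magnitude exceeds the matching model MAE
    from ``cv_reports`` (NaN when no report is given).
    """
    scenario_names = scenario_names or {"nsf": "NSF", "nc": "NC"}
    lookup = _mae_lookup(cv_reports)
    rows = []
    regions = sorted(results["region"].unique())
    for comp in COMPARISONS:
        diff = results["pm_obs"] - results[f"pm_{comp}"]
        for region in regions:
            rmask = results["region"] == region
            hour_cells = {}
            for h in ANALYSIS_HOURS:
                mask = rmask & (results["hour"] == h)
                if not mask.any():
                    raise ValueError(f"region {region}: no samples at hour {h:02d}")
                val = float(diff[mask].mean())
                mae = lookup(scenario_names[comp], region, h)
                rows.append(
                    {
                        "region": region,
                        "comparison": comp,
                        "hour": str(h).zfill(2),
                        "value": val,
                        "mae": mae,
                        "significant": bool(abs(val) > mae) if np.isfinite(mae) else None,
                        "n": int(mask.sum()),
                    }
                )
                hour_cells[h] = (val, mae)
            all_val = aggregate_all(v for v, _ in hour_cells.values())
            maes = [m for _, m in hour_cells.values()]
            all_mae = float(np.mean(maes)) if np.all(np.isfinite(maes)) else np.nan
            rows.append(
                {
                    "region": region,
                    "comparison": comp,
                    "hour": "All",
                    "value": all_val,
                    "mae": all_mae,
                    "significant": bool(abs(all_val) > all_mae) if np.isfinite(all_mae) else None,
                    "n": int(rmask.sum()),
                }
            )
        # cross-region bottom row: sample-weighted
        for h in ANALYSIS_HOURS:
            mask = results["hour"] == h
            rows.append(
                {
                    "region": "All (sample-weighted)",
                    "comparison": comp,
                    "hour": str(h).zfill(2),
                    "value": float(diff[mask].mean()),
                    "mae": np.nan,
                    "significant": None,
                    "n": int(mask.sum()),
                }
            )
    table = pd.DataFrame(rows)
    key = table[["region", "comparison", "hour"]]
    if key.duplicated().any():
        raise AssertionError("duplicate (region, comparison, hour) keys")
    return table


def pivot_difference_table(table: pd.DataFrame) -> pd.DataFrame:
    """Wide layout (region x hour x comparison) for reporting."""
    wide = table.pivot_table(
        index="region", columns=["comparison", "hour"], values="value", sort=False
    )
    order = [str(h).zfill(2) for h in ANALYSIS_HOURS] + ["All"]
    cols = [
        (c, h) for c in COMPARISONS for h in order if (c, h) in wide.columns
    ]
    return wide[cols]


def firework_effect(table: pd.DataFrame) -> pd.Series:
    """Firework contribution per region (µg/m³), positive = fireworks raise PM2.5.

    Computed as the difference of the two regional "All" cells:
    ``All(PMsd − PM̂sd|nc) − All(PMsd − PM̂sd|nsf)``, i.e. the effect that
    remains once the factory/vehicle shutdown common to both comparisons
    cancels.
    """
    sub = table[
        (table["hour"] == "All") & ~table["region"].str.startswith("All")
    ]
    got = set(sub["comparison"].unique())
    if not {"nsf", "nc"} <= got:
        raise ValueError(f"difference table lacks comparison columns: have {sorted(got)}")
    nc = sub[sub["comparison"] == "nc"].set_index("region")["value"]
    nsf = sub[sub["comparison"] == "nsf"].set_index("region")["value"]
    return (nc - nsf).rename("firework_effect")
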