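"""End-to-end orchestration: preprocess -> train -> counterfactual -> analyze.

Every stage writes plain CSV (plus one JSON manifest) into the run's output
directory so results are inspectable and diffable; a rerun with the same
config and seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import logging
import zlib
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import io as dio
from . import preprocessing as prep
from .analysis import daily_series, detect_delays, spatial_summary
from .counterfactual import (
    build_counterfactuals,
    difference_table,
    firework_effect,
    pivot_difference_table,
)
from .strf import cross_validate, train_strf
from .types import ANALYSIS_HOURS, RunConfig, ScenarioDataset

log = logging.getLogger("deweather")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _model_seed(base_seed: int, scenario: str, hour: int) -> int:
    """One independent RNG stream per (scenario, hour) model, derived from the
    run seed so adding a model does not perturb the others."""
    label = zlib.crc32(scenario.encode()) % (2**16)  # stable across processes
    ss = np.random.SeedSequence([base_seed, label, hour])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def preprocess(config: RunConfig, run_cv: bool = True):
    """Filter stations, fill gaps (with optional interpolation CV), match the
    grid and split scenarios.  Returns (scenario -> samples, reports dict)."""
    obs = dio.read_station_csv(config.stations_path)
    meteo = dio.read_meteo(config.meteo_path)
    landuse = dio.read_landuse(config.landuse_path) if config.landuse_path else None
    regions = dio.read_regions(config.regions_path) if config.regions_path else None

    retained, station_report = prep.filter_stations(
        obs, config.periods, threshold=config.missing_threshold
    )
    filled, interp_report = prep.interpolate(retained, config.periods)
    if run_cv:
        interp_report = prep.cross_validate_interpolation(
            retained, config.periods, k=config.cv_folds, seed=config.seed
        )
    samples, grid, cell_of = prep.match_grid(
        filled, meteo, spacing=config.grid_spacing,
        region_map=regions, landuse_map=landuse,
    )
    by_scenario = prep.split_scenarios(samples, config.periods)
    reports = {
        "stations": station_report,
        "interpolation": interp_report.to_frame(),
        "station_cells": cell_of.rename("cell_id").reset_index(),
    }
    return by_scenario, reports


def train_models(config: RunConfig, by_scenario: dict[str, pd.DataFrame], run_cv: bool = True):
    """Train one model per (reference scenario, hour class); optional k-fold CV."""
    models: dict[str, dict[int, object]] = {}
    cv_rows = []
    for scenario in config.reference_scenarios:
        datasets = prep.stratify_hours(by_scenario[scenario], scenario)
        models[scenario] = {}
        for hour in ANALYSIS_HOURS:
            seed = _model_seed(config.seed, scenario, hour)
            models[scenario][hour] = train_strf(
                datasets[hour],
                ntree=config.ntree,
                mtry=config.mtry,
                min_node_size=config.min_node_size,
                random_state=seed,
            )
            if run_cv:
                cv_rows.append(
                    cross_validate(
                        datasets[hour],
                        ntree=config.ntree,
                        mtry=config.mtry,
                        min_node_size=config.min_node_size,
                        k=config.cv_folds,
                        seed=seed,
                    )
                )
    cv_report = pd.concat(cv_rows, ignore_index=True) if cv_rows else None
    return models, cv_report


def run_counterfactual(config: RunConfig, by_scenario, models, cv_report=None):
    """Predict both counterfactuals for the target period and tabulate."""
    target = by_scenario[config.target_scenario]
    if target.empty:
        raise ValueError(f"no samples in target scenario {config.target_scenario!r}")
    ref_a, ref_b = config.reference_scenarios
    results = build_counterfactuals(target, models[ref_a], models[ref_b])
    table = difference_table(
        results,
        cv_reports=cv_report,
        scenario_names={"nsf": ref_a, "nc": ref_b},
    )
    fireworks = firework_effect(table)
    return results, table, fireworks


def run_pipeline(config: RunConfig, run_cv: bool = True) -> dict:
    """Run the whole pipeline, writing the result bundle under config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        by_scenario, reports = preprocess(config, run_cv=run_cv)
    except Exception as exc:  # noqa: BLE001
        raise StageError("preprocess", exc) from exc
    reports["stations"].to_csv(outdir / "retained_stations.csv", index=False)
    reports["interpolation"].to_csv(outdir / "interpolation_report.csv", index=False)
    pd.concat(
        [df.assign(scenario=label) for label, df in by_scenario.items()],
        ignore_index=True,
    ).to_csv(outdir / "matched_samples.csv", index=False)

    try:
        models, cv_report = train_models(config, by_scenario, run_cv=run_cv)
    except Exception as exc:  # noqa: BLE001
        raise StageError("train", exc) from exc
    if cv_report is not None:
        cv_report.to_csv(outdir / "cv_report.csv", index=False)
    joblib.dump(models, outdir / "models.joblib")

    try:
        results, table, fireworks = run_counterfactual(
            config, by_scenario, models, cv_report
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("counterfactual", exc) from exc
    results.to_csv(outdir / "counterfactual.csv", index=False)
    table.to_csv(outdir / "difference_table.csv", index=False)
    pivot_difference_table(table).to_csv(outdir / "difference_table_wide.csv")
    fireworks.reset_index().to_csv(outdir / "firework_effect.csv", index=False)

    try:
        series = daily_series(results)
        series_hourly = daily_series(results, per_hour=True)
        target_period = next(
            p for p in config.periods if p.label == config.target_scenario
        )
        delays = detect_delays(
            results, q=config.turning_q, margin=config.turning_margin,
            start=target_period.start,
        )
        cell_summary, landuse_summary = spatial_summary(results)
    except Exception as exc:  # noqa: BLE001
        raise StageError("analyze", exc) from exc
    series.to_csv(outdir / "daily_series.csv", index=False)
    series_hourly.to_csv(outdir / "daily_series_hourly.csv", index=False)
    delays.to_csv(outdir / "delay_estimates.csv", index=False)
    cell_summary.to_csv(outdir / "spatial_summary_cells.csv", index=False)
    landuse_summary.to_csv(outdir / "spatial_summary_landuse.csv", index=False)

    dio.write_manifest(outdir / "manifest.json", config, extra={
        "outputs": sorted(p.name for p in outdir.iterdir() if p.suffix == ".csv"),
    })
    log.info("pipeline complete: %s", outdir)
    return {
        "by_scenario": by_scenario,
        "models": models,
        "cv_report": cv_report,
        "results": results,
        "difference_table": table,
        "firework_effect": fireworks,
        "daily_series": series,
        "delays": delays,
        "spatial_cells": cell_summary,
        "spatial_landuse": landuse_summary,
        "reports": reports,
    }
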