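"""Core domain types shared across the pipeline.

Timestamps are Beijing Time (BJT, UTC+8) throughout and stored as naive
``datetime64`` values; readers convert on ingest.  Missing PM2.5 is an explicit
``NaN`` marker, never a sentinel 0, since 0 µg/m³ is a legal concentration.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: The four analysis hours (BJT) at which gridded meteorology is available.
ANALYSIS_HOURS: tuple[int, ...] = (2, 8, 14, 20)

#: The five meteorological predictor variables.
MET_VARS: tuple[str, ...] = ("u_wind", "v_wind", "msl", "d2m", "t2m")

#: Full model feature set: meteorology plus grid-cell centre coordinates.
FEATURES: tuple[str, ...] = MET_VARS + ("lat", "lon")

#: Recognised land-use categories; anything else is mapped to "unknown".
LANDUSE_CATEGORIES: tuple[str, ...] = (
    "cultivated", "urban", "rural", "forest", "grass", "water", "other",
)


@dataclass(frozen=True)
class ScenarioPeriod:
    """A labelled study period with a characteristic emission regime.

    Parameters
    ----------
    label
        Scenario label, conventionally ``SD`` (factories/vehicles shut down),
        ``NC`` (normal commute, no fireworks) or ``NSF`` (normal Spring
        Festival, fireworks); user-defined labels are allowed.
    start, end
        Inclusive calendar dates of the period.
    emission_descriptor
        Free-text flags describing the regime, e.g.
        ``{"fireworks": "yes", "factories_vehicles": "shut"}``.
    """

    label: str
    start: dt.date
    end: dt.date
    emission_descriptor: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"period {self.label!r}: start {self.start} after end {self.end}"
            )

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")

    def timestamps(self) -> pd.DatetimeIndex:
        """All analysis-hour timestamps inside the period."""
        days = self.dates()
        out = [d + pd.Timedelta(hours=h) for d in days for h in ANALYSIS_HOURS]
        return pd.DatetimeIndex(sorted(out))

    def contains(self, ts) -> np.ndarray:
        d = pd.DatetimeIndex(ts).normalize()
        return (d >= pd.Timestamp(self.start)) & (d <= pd.Timestamp(self.end))


def check_unique_labels(periods: list[ScenarioPeriod]) -> None:
    labels = [p.label for p in periods]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate scenario labels: {labels}")


@dataclass(frozen=True)
class StandardizationParams:
    """Per-variable centring/scaling parameters (population convention)."""

    names: tuple[str, ...]
    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.std) <= 0):
            bad = [n for n, s in zip(self.names, self.std) if s <= 0]
            raise ValueError(f"zero/negative standard deviation for {bad}")

    def transform(self, values: pd.DataFrame | np.ndarray) -> np.ndarray:
        x = np.asarray(
            values[list(self.names)] if isinstance(values, pd.DataFrame) else values,
            dtype=float,
        )
        return (x - self.mean) / self.std

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.std + self.mean


@dataclass
class ScenarioDataset:
    """Matched grid-cell samples for one scenario period and hour class."""

    label: str
    hour: int
    samples: pd.DataFrame  # columns: cell_id, region, landuse, date, hour, features..., pm25_mean
    params: StandardizationParams | None = None

    def __post_init__(self) -> None:
        if self.hour not in ANALYSIS_HOURS:
            raise ValueError(f"hour_class {self.hour} not in {ANALYSIS_HOURS}")
        if len(self.samples) and (self.samples["hour"] != self.hour).any():
            raise ValueError("samples with mismatching hour_class")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class InterpolationReport:
    """Accounting of the gap-filling pass plus its cross-validated accuracy."""

    n_missing: int
    n_temporal: int
    n_spatial: int
    n_unfilled: int
    cv_mae: float | None = None
    cv_fold_maes: tuple[float, ...] = ()
    n_folds: int = 0

    def __post_init__(self) -> None:
        if self.n_temporal + self.n_spatial + self.n_unfilled != self.n_missing:
            raise ValueError("interpolation counts do not sum to missing count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_missing": [self.n_missing],
                "n_temporal": [self.n_temporal],
                "n_spatial": [self.n_spatial],
                "n_unfilled": [self.n_unfilled],
                "cv_mae": [self.cv_mae],
                "n_folds": [self.n_folds],
            }
        )


@dataclass(frozen=True)
class DelayEstimate:
    """Turning point of a daily series and its delay from the period start.

    ``delay_days`` counts calendar days with the period start as day 0, so a
    start of 21 Jan plus a 17-day delay lands on 7 Feb.
    """

    region: str
    turning_point: dt.date | None
    delay_days: int | None
    q: float
    margin: float

    @property
    def detected(self) -> bool:
        return self.turning_point is not None


@dataclass
class RunConfig:
    """Run-level configuration mirrored by the config file and manifest."""

    seed: int = 0
    grid_spacing: float = 0.05
    ntree: int = 200
    mtry: int = 2
    min_node_size: int = 5
    cv_folds: int = 10
    missing_threshold: float = 0.2
    turning_q: float = 0.75
    turning_margin: float = 0.0
    target_scenario: str = "SD"
    reference_scenarios: tuple[str, str] = ("NSF", "NC")
    stations_path: str | None = None
    meteo_path: str | None = None
    landuse_path: str | None = None
    regions_path: str | None = None
    outdir: str = "out"
    periods: list[ScenarioPeriod] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if not (1 <= self.mtry <= len(FEATURES)):
            raise ValueError(f"mtry must be in [1, {len(FEATURES)}]")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if not (0.0 < self.missing_threshold < 1.0):
            raise ValueError("missing_threshold must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not (0.0 < self.turning_q <= 1.0):
            raise ValueError("turning_q must be in (0, 1]")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.periods:
            check_unique_labels(self.periods)
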