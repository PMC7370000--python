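"""Synthetic multi-scenario worlds for end-to-end testing.

The generator emits everything the pipeline reads — station CSV, gridded
meteorology, land-use and region maps, scenario periods — together with the
ground truth needed for recovery tests: the noiseless PM2.5 response, the
injected per-region shutdown reductions (with their cumulative-emission delay
ramp), and the festival firework pulses.

The true meteorology-to-PM2.5 response ``g`` is a fixed, documented smooth
nonlinear function (stagnation-like: high pressure and low wind raise PM2.5);
only the meteorological fields, the noise and the missingness vary with the
seed, so failures are reproducible.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .preprocessing import Grid
from .types import ANALYSIS_HOURS, MET_VARS, RunConfig, ScenarioPeriod

#: additive PM2.5 base level per land-use category (µg/m³)
BASE_LEVEL = {
    "cultivated": 16.0, "urban": 22.0, "rural": 18.0, "forest": 8.0,
    "grass": 10.0, "water": 6.0, "other": 12.0,
}

#: hour-of-day PM2.5 offset (µg/m³): night higher than afternoon
HOUR_PROFILE = {2: 6.0, 8: 2.0, 14: -6.0, 20: 4.0}

#: anthropogenic emission intensity per land-use category (µg/m³)
EMISSION_INTENSITY = {
    "cultivated": 44.0, "urban": 52.0, "rural": 46.0, "forest": 36.0,
    "grass": 37.0, "water": 36.0, "other": 40.0,
}

#: hour-of-day multiplier on the emission term
EMISSION_HOUR_FACTOR = {2: 0.9, 8: 1.05, 14: 1.15, 20: 0.95}

LANDUSE_PROBS = {
    "cultivated": 0.30, "urban": 0.15, "rural": 0.15, "forest": 0.20,
    "grass": 0.10, "water": 0.05, "other": 0.05,
}

#: per-variable meteorology process parameters:
#: (mean, bump amplitude, AR(1) innovation sd, diurnal amplitude, peak hour)
MET_PROCESS = {
    "u_wind": (0.5, 2.0, 1.2, 0.8, 14),
    "v_wind": (-0.5, 2.0, 1.2, 0.8, 16),
    "msl": (101800.0, 300.0, 220.0, 80.0, 8),
    "d2m": (272.0, 3.0, 1.8, 1.5, 16),
    "t2m": (277.0, 3.0, 1.8, 3.0, 14),
}

DEFAULT_PERIODS = [
    ScenarioPeriod("SD", dt.date(2020, 1, 21), dt.date(2020, 2, 20),
                   {"fireworks": "yes", "factories_vehicles": "shut", "heating": "normal"}),
    ScenarioPeriod("NC", dt.date(2019, 12, 21), dt.date(2020, 1, 20),
                   {"fireworks": "none", "factories_vehicles": "normal", "heating": "normal"}),
    ScenarioPeriod("NSF", dt.date(2019, 2, 1), dt.date(2019, 3, 3),
                   {"fireworks": "yes", "factories_vehicles": "normal", "heating": "normal"}),
]


def true_response(u, v, msl, d2m, t2m, lat, lon,
                  lat0: float = 30.0, lon0: float = 114.0) -> np.ndarray:
    """Fixed noiseless meteorology/location -> PM2.5 response g (µg/m³).

    Low wind speed and high pressure (stagnation) raise PM2.5; humidity and
    temperature interact; a smooth spatial pattern stands in for unresolved
    geography.  Inputs are raw physical units.
    """
    ws = np.hypot(u, v)
    zp = (msl - 101800.0) / 300.0
    zd = (d2m - 272.0) / 3.0
    zt = (t2m - 277.0) / 3.0
    return (
        12.0
        - 10.0 * np.tanh((ws - 2.5) / 1.5)
        + 6.0 * zp
        + 4.0 * zd
        - 3.0 * zt
        + 2.5 * zd * zt
        + 5.0 * np.sin(2.5 * (np.asarray(lat) - lat0))
        + 4.0 * np.cos(2.5 * (np.asarray(lon) - lon0))
    )


@dataclass
class SyntheticWorldConfig:
    """Stated world for the synthetic generator (defaults mirror the study
    design: three 31-day scenario periods, four analysis hours, region
    reductions of 8/23/27 µg/m³ with a 17-day ramp, festival fireworks)."""

    seed: int = 0
    n_lat: int = 20
    n_lon: int = 20
    spacing: float = 0.05
    lat0: float = 30.0
    lon0: float = 114.0
    n_stations: int = 430
    periods: list[ScenarioPeriod] = field(default_factory=lambda: list(DEFAULT_PERIODS))
    rho: float = 0.7
    length_scale: float = 0.3
    n_bumps: int = 6
    shutdown_delta: dict = field(
        default_factory=lambda: {"BTH": 8.0, "YRD": 23.0, "Hubei": 27.0}
    )
    ramp_days: int = 17
    firework_amp: float = 100.0
    festival_offsets: tuple[int, ...] = (4, 5, 6)
    noise_sd: float = 5.0
    missing_rate: float = 0.035
    n_high_missing: int = 30
    high_missing_rate: float = 0.4

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.shutdown_delta.values()):
            raise ValueError("shutdown reductions must be >= 0")
        if self.ramp_days < 0 or self.firework_amp < 0 or self.noise_sd < 0:
            raise ValueError("ramp_days, firework_amp and noise_sd must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        min_term = min(EMISSION_INTENSITY.values()) * min(EMISSION_HOUR_FACTOR.values())
        if self.shutdown_delta and max(self.shutdown_delta.values()) > min_term:
            raise ValueError(
                f"shutdown reduction exceeds the minimum emission term ({min_term:.1f}): "
                "would force systematic clamping at 0"
            )

    def period(self, label: str) -> ScenarioPeriod:
        for p in self.periods:
            if p.label == label:
                return p
        raise KeyError(label)


@dataclass
class SyntheticWorld:
    """A generated world: pipeline inputs plus exact ground truth."""

    config: SyntheticWorldConfig
    grid: Grid
    cells: pd.DataFrame            # cell_id, lat, lon, region, landuse
    stations: pd.DataFrame         # station_id, lat, lon, cell_id
    observations: pd.DataFrame     # station CSV format, NaN = missing
    meteo: pd.DataFrame            # long format, all scenario timestamps
    truth: pd.DataFrame            # scenario, cell_id, date, hour, noiseless, reduction, firework
    regions: pd.Series
    landuse: pd.Series


def _ramp(day_offsets: np.ndarray, ramp_days: int) -> np.ndarray:
    """Cumulative-emission decay: 0 at day 0 rising linearly to 1 at day D."""
    if ramp_days == 0:
        return np.ones_like(day_offsets, dtype=float)
    return np.minimum(day_offsets / float(ramp_days), 1.0)


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Generate a complete synthetic multi-scenario world (seeded)."""
    rng = np.random.default_rng(config.seed)
    grid = Grid.from_bounds(
        config.lat0,
        config.lat0 + (config.n_lat - 1) * config.spacing,
        config.lon0,
        config.lon0 + (config.n_lon - 1) * config.spacing,
        config.spacing,
    )
    cells = grid.cell_frame()
    n_cells = len(cells)

    # regions: three latitude bands (labels only)
    lat = cells["lat"].to_numpy()
    edges = np.quantile(lat, [1 / 3, 2 / 3])
    region = np.where(lat <= edges[0], "Hubei", np.where(lat <= edges[1], "YRD", "BTH"))
    cells["region"] = region
    cats = list(LANDUSE_PROBS)
    cells["landuse"] = rng.choice(cats, size=n_cells, p=[LANDUSE_PROBS[c] for c in cats])

    # static spatial patterns: sums of seeded Gaussian bumps, shared across scenarios
    lon = cells["lon"].to_numpy()
    spatial = {}
    for var, (mean, bump_amp, _, _, _) in MET_PROCESS.items():
        f = np.zeros(n_cells)
        for _ in range(config.n_bumps):
            clat = rng.uniform(lat.min(), lat.max())
            clon = rng.uniform(lon.min(), lon.max())
            amp = rng.uniform(-bump_amp, bump_amp)
            f += amp * np.exp(
                -((lat - clat) ** 2 + (lon - clon) ** 2) / (2 * config.length_scale**2)
            )
        spatial[var] = f

    met_frames = []
    truth_frames = []
    intensity = cells["landuse"].map(EMISSION_INTENSITY).to_numpy()
    base = cells["landuse"].map(BASE_LEVEL).to_numpy()
    delta = (
        cells["region"].map(config.shutdown_delta).fillna(0.0).to_numpy()
        if config.shutdown_delta
        else np.zeros(n_cells)
    )
    for period in config.periods:
        dates = period.dates()
        n_days = len(dates)
        hours = np.array(ANALYSIS_HOURS)
        # AR(1) daily anomaly per variable
        anomalies = {}
        for var, (_, _, ar_sd, _, _) in MET_PROCESS.items():
            a = np.empty(n_days)
            a[0] = rng.normal(0.0, ar_sd / np.sqrt(1.0 - config.rho**2))
            eps = rng.normal(0.0, ar_sd, size=n_days - 1)
            for d in range(1, n_days):
                a[d] = config.rho * a[d - 1] + eps[d - 1]
            anomalies[var] = a
        # met value arrays (day, hour, cell)
        met = {}
        for var, (mean, _, _, diur_amp, peak) in MET_PROCESS.items():
            diurnal = diur_amp * np.cos(2 * np.pi * (hours - peak) / 24.0)
            met[var] = (
                mean
                + spatial[var][None, None, :]
                + anomalies[var][:, None, None]
                + diurnal[None, :, None]
            )
        g = true_response(
            met["u_wind"], met["v_wind"], met["msl"], met["d2m"], met["t2m"],
            lat[None, None, :], lon[None, None, :],
            lat0=config.lat0, lon0=config.lon0,
        )
        hour_prof = np.array([HOUR_PROFILE[h] for h in ANALYSIS_HOURS])
        e_factor = np.array([EMISSION_HOUR_FACTOR[h] for h in ANALYSIS_HOURS])
        emission0 = intensity[None, None, :] * e_factor[None, :, None]
        day_off = np.arange(n_days, dtype=float)
        if period.label == "SD":
            reduction = delta[None, None, :] * _ramp(day_off, config.ramp_days)[:, None, None]
            reduction = np.broadcast_to(reduction, (n_days, len(hours), n_cells)).copy()
        else:
            reduction = np.zeros((n_days, len(hours), n_cells))
        if period.label in {"SD", "NSF"} and "yes" in str(
            period.emission_descriptor.get("fireworks", "yes")
        ):
            fire_day = np.isin(np.arange(n_days), list(config.festival_offsets))
            firework = np.where(fire_day[:, None, None], config.firework_amp, 0.0)
            firework = np.broadcast_to(firework, (n_days, len(hours), n_cells)).copy()
        else:
            firework = np.zeros((n_days, len(hours), n_cells))
        noiseless = (
            base[None, None, :]
            + hour_prof[None, :, None]
            + g
            + emission0
            - reduction
            + firework
        )
        noise = (
            rng.normal(0.0, config.noise_sd, size=noiseless.shape)
            if config.noise_sd > 0
            else np.zeros_like(noiseless)
        )
        pm_obs = np.maximum(noiseless + noise, 0.0)

        ts = pd.DatetimeIndex(
            [pd.Timestamp(d) + pd.Timedelta(hours=int(h)) for d in dates for h in hours]
        )
        flat = lambda a: a.reshape(n_days * len(hours), n_cells)  # noqa: E731
        met_df = pd.DataFrame(
            {
                "timestamp": np.repeat(ts, n_cells),
                "lat": np.tile(lat, len(ts)),
                "lon": np.tile(lon, len(ts)),
                **{var: flat(met[var]).ravel() for var in MET_VARS},
            }
        )
        met_frames.append(met_df)
        truth_frames.append(
            pd.DataFrame(
                {
                    "scenario": period.label,
                    "cell_id": np.tile(cells["cell_id"].to_numpy(), len(ts)),
                    "timestamp": np.repeat(ts, n_cells),
                    "noiseless": flat(noiseless).ravel(),
                    "reduction": flat(reduction).ravel(),
                    "firework": flat(firework).ravel(),
                    "pm": flat(pm_obs).ravel(),
                }
            )
        )

    meteo = pd.concat(met_frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    truth["date"] = truth["timestamp"].dt.normalize()
    truth["hour"] = truth["timestamp"].dt.hour

    # stations: quasi-uniform (one per cell while they last, extras random)
    order = rng.permutation(n_cells)
    cell_idx = np.concatenate(
        [
            order[: min(config.n_stations, n_cells)],
            rng.integers(0, n_cells, size=max(0, config.n_stations - n_cells)),
        ]
    )
    jitter = rng.uniform(-0.49, 0.49, size=(len(cell_idx), 2)) * config.spacing
    stations = pd.DataFrame(
        {
            "station_id": [f"s{i:04d}" for i in range(len(cell_idx))],
            "lat": cells["lat"].to_numpy()[cell_idx] + jitter[:, 0],
            "lon": cells["lon"].to_numpy()[cell_idx] + jitter[:, 1],
            "cell_id": cells["cell_id"].to_numpy()[cell_idx],
        }
    )

    # station observations sample their cell's value
    pm_by_cell = truth.pivot_table(index="timestamp", columns="cell_id", values="pm")
    obs_mat = pm_by_cell[stations["cell_id"]].to_numpy()
    n_slots = obs_mat.shape[0]
    miss = rng.random(obs_mat.shape) < config.missing_rate
    high = rng.choice(len(stations), size=min(config.n_high_missing, len(stations)),
                      replace=False)
    n_force = int(np.ceil(config.high_missing_rate * n_slots))
    for j in high:
        miss[rng.choice(n_slots, size=n_force, replace=False), j] = True
    obs_mat = np.where(miss, np.nan, obs_mat)
    observations = pd.DataFrame(
        {
            "station_id": np.tile(stations["station_id"].to_numpy(), n_slots),
            "lat": np.tile(stations["lat"].to_numpy(), n_slots),
            "lon": np.tile(stations["lon"].to_numpy(), n_slots),
            "timestamp": np.repeat(pm_by_cell.index.to_numpy(), len(stations)),
            "pm25": obs_mat.ravel(),
        }
    )

    return SyntheticWorld(
        config=config,
        grid=grid,
        cells=cells,
        stations=stations,
        observations=observations,
        meteo=meteo,
        truth=truth,
        regions=cells.set_index("cell_id")["region"],
        landuse=cells.set_index("cell_id")["landuse"],
    )


def ground_truth_report(world: SyntheticWorld) -> pd.DataFrame:
    """True injected effects, computed numerically from the truth arrays.

    Per region: the mean shutdown reduction over the post-ramp window and over
    the whole target period, the mean firework contribution over the target
    period, and the ramp-completion delay in days.
    """
    cfg = world.config
    sd = cfg.period("SD")
    t = world.truth[world.truth["scenario"] == "SD"].merge(
        world.regions.rename("region"), left_on="cell_id", right_index=True
    )
    post = t["date"] >= pd.Timestamp(sd.start) + pd.Timedelta(days=cfg.ramp_days)
    rows = []
    for region, sub in t.groupby("region"):
        rows.append(
            {
                "region": region,
                "true_reduction_postramp": float(sub.loc[post[sub.index], "reduction"].mean()),
                "true_reduction_period": float(sub["reduction"].mean()),
                "true_firework_mean": float(sub["firework"].mean()),
                "true_delay_days": cfg.ramp_days,
            }
        )
    return pd.DataFrame(rows).sort_values("region").reset_index(drop=True)


def write_world(world: SyntheticWorld, outdir: str | Path) -> RunConfig:
    """Write the world in exactly the formats the readers consume; returns a
    ready RunConfig pointing at the files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dio.write_station_csv(world.observations, outdir / "stations.csv")
    dio.write_meteo_netcdf(world.meteo, outdir / "meteo.nc")
    world.landuse.rename("landuse").reset_index().to_csv(
        outdir / "landuse.csv", index=False
    )
    world.regions.rename("region").reset_index().to_csv(
        outdir / "regions.csv", index=False
    )
    ground_truth_report(world).to_csv(outdir / "ground_truth.csv", index=False)
    config = RunConfig(
        seed=world.config.seed,
        grid_spacing=world.config.spacing,
        stations_path=str(outdir / "stations.csv"),
        meteo_path=str(outdir / "meteo.nc"),
        landuse_path=str(outdir / "landuse.csv"),
        regions_path=str(outdir / "regions.csv"),
        outdir=str(outdir / "results"),
        periods=list(world.config.periods),
    )
    dio.save_config(config, outdir / "config.yaml")
    return config
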