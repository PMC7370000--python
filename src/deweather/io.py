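"""Readers and writers for the pipeline's plain-text interfaces.

Station observations travel as CSV (``station_id,lat,lon,timestamp,pm25``,
blank pm25 = missing), meteorology as CF-style NetCDF (dims ``time, lat, lon``)
or an equivalent long CSV, land use / regions as ``cell_id,<category>`` CSVs,
and the run configuration as a single YAML file.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .types import LANDUSE_CATEGORIES, MET_VARS, RunConfig, ScenarioPeriod

log = logging.getLogger("deweather")

STATION_COLUMNS = ["station_id", "lat", "lon", "timestamp", "pm25"]


def read_station_csv(path: str | Path) -> pd.DataFrame:
    """Read hourly station PM2.5 observations.

    Missing pm25 values (blank fields) are preserved as NaN, never coerced to
    0.  Malformed rows raise with the offending line number (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"station_id": str})
    missing_cols = [c for c in STATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    df = df[STATION_COLUMNS]
    if df.empty:
        warnings.warn(f"{path}: no observation rows", stacklevel=2)
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        return df

    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    for col in ("lat", "lon", "pm25"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    def _bad(mask: pd.Series, why: str) -> None:
        if mask.any():
            line = int(mask.idxmax()) + 2  # header is line 1
            raise ValueError(f"{path}: line {line}: {why}")

    _bad(ts.isna(), "unparseable timestamp")
    _bad(ts.dt.minute.ne(0) | ts.dt.second.ne(0), "timestamp not a whole hour")
    _bad(df["lat"].isna() | df["lat"].abs().gt(90), "latitude missing or outside [-90, 90]")
    _bad(df["lon"].isna() | df["lon"].abs().gt(180), "longitude missing or outside [-180, 180]")
    _bad(df["pm25"].lt(0), "negative pm25")
    df["timestamp"] = ts
    return df


def write_station_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write observations in the station CSV format (NaN -> blank field)."""
    out = df[STATION_COLUMNS].copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_meteo(path: str | Path, source_tz: str = "BJT") -> pd.DataFrame:
    """Read gridded meteorology into a long DataFrame.

    Accepts NetCDF (dims ``time, lat, lon``; variables u_wind, v_wind, msl,
    d2m, t2m) or a long CSV with columns ``timestamp, lat, lon`` plus the five
    variables.  ``source_tz="UTC"`` declares UTC-stamped input; timestamps are
    then shifted +8 h onto Beijing Time.  Returns columns ``timestamp, lat,
    lon, u_wind, v_wind, msl, d2m, t2m``.
    """
    path = Path(path)
    if path.suffix in {".nc", ".nc4", ".cdf"}:
        with xr.open_dataset(path) as ds:
            missing = [v for v in MET_VARS if v not in ds.data_vars]
            if missing:
                raise ValueError(f"{path}: missing variable {', '.join(missing)}")
            df = ds[list(MET_VARS)].to_dataframe().reset_index()
        df = df.rename(columns={"time": "timestamp"})
    else:
        df = pd.read_csv(path)
        missing = [v for v in MET_VARS if v not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing variable {', '.join(missing)}")
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    if source_tz.upper() == "UTC":
        df["timestamp"] = pd.DatetimeIndex(df["timestamp"]) + pd.Timedelta(hours=8)
    elif source_tz.upper() not in {"BJT", "LOCAL"}:
        raise ValueError(f"unknown source_tz {source_tz!r} (use 'BJT' or 'UTC')")
    if (df["msl"] <= 0).any():
        raise ValueError(f"{path}: non-positive mean sea-level pressure")
    cols = ["timestamp", "lat", "lon", *MET_VARS]
    return df[cols].sort_values(["timestamp", "lat", "lon"]).reset_index(drop=True)


def write_meteo_netcdf(df: pd.DataFrame, path: str | Path) -> None:
    """Write long-format meteorology to a CF-style NetCDF file."""
    ds = (
        df.set_index(["timestamp", "lat", "lon"])
        .to_xarray()
        .rename({"timestamp": "time"})
    )
    ds.to_netcdf(path)


def read_cell_map(path: str | Path, value_col: str) -> pd.Series:
    """Read a ``cell_id,<value_col>`` CSV into a Series indexed by cell_id."""
    df = pd.read_csv(path, dtype=str)
    for col in ("cell_id", value_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df.set_index("cell_id")[value_col]


def read_landuse(path: str | Path) -> pd.Series:
    lu = read_cell_map(path, "landuse")
    bad = sorted(set(lu.unique()) - set(LANDUSE_CATEGORIES) - {"unknown"})
    if bad:
        raise ValueError(f"{path}: unknown land-use categories {bad}")
    return lu


def read_regions(path: str | Path) -> pd.Series:
    return read_cell_map(path, "region")


def _parse_period(entry: dict) -> ScenarioPeriod:
    return ScenarioPeriod(
        label=str(entry["label"]),
        start=_as_date(entry["start"]),
        end=_as_date(entry["end"]),
        emission_descriptor=dict(entry.get("emission_descriptor", {})),
    )


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration (keys mirror :class:`RunConfig`)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    periods = [_parse_period(p) for p in raw.pop("periods", [])]
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "reference_scenarios" in raw:
        raw["reference_scenarios"] = tuple(raw["reference_scenarios"])
    return RunConfig(periods=periods, **raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    data = {
        k: v
        for k, v in config.__dict__.items()
        if k != "periods" and v is not None
    }
    data["reference_scenarios"] = list(config.reference_scenarios)
    data["periods"] = [
        {
            "label": p.label,
            "start": p.start.isoformat(),
            "end": p.end.isoformat(),
            "emission_descriptor": dict(p.emission_descriptor),
        }
        for p in config.periods
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def write_manifest(path: str | Path, config: RunConfig, extra: dict | None = None) -> None:
    """Write the machine-readable run manifest (seed, config, conventions)."""
    manifest = {
        "seed": config.seed,
        "config": json.loads(json.dumps(_config_dict(config), default=str)),
        "conventions": {
            "timezone": "BJT (UTC+8), naive timestamps",
            "standardization": "population sd, fit per training scenario dataset",
            "latlon_standardized": True,
            "distance_metric": "haversine (WGS84 mean radius)",
            "all_cell_aggregation": "unweighted mean of the four hourly means",
        },
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _config_dict(config: RunConfig) -> dict:
    d = dict(config.__dict__)
    d["periods"] = [
        {"label": p.label, "start": p.start, "end": p.end,
         "emission_descriptor": dict(p.emission_descriptor)}
        for p in config.periods
    ]
    return d
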