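"""Station screening, gap filling, standardization and grid matching.

The observational pre-processing follows a fixed order: stations with too many
missing hours over the study months are dropped; remaining gaps are filled
temporally (linear midpoint of the two adjacent candidate hours, only when both
are themselves observed) and then spatially (inverse-distance-squared over
co-temporal observed stations); stations are matched to their nearest analysis
grid cell and cell-hour mean PM2.5 is paired with that cell's meteorology.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .types import (
    ANALYSIS_HOURS,
    FEATURES,
    MET_VARS,
    InterpolationReport,
    ScenarioDataset,
    ScenarioPeriod,
    StandardizationParams,
)

log = logging.getLogger("deweather")

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on the WGS84 mean sphere."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


# ---------------------------------------------------------------------------
# Station filtering
# ---------------------------------------------------------------------------

def expected_timestamps(periods: list[ScenarioPeriod]) -> pd.DatetimeIndex:
    """Union of analysis-hour timestamps over all study periods."""
    if not periods:
        raise ValueError("no study periods configured")
    idx = periods[0].timestamps()
    for p in periods[1:]:
        idx = idx.union(p.timestamps())
    return idx


def _station_matrix(obs: pd.DataFrame, periods: list[ScenarioPeriod]):
    """Pivot long observations to a (timestamp x station) value matrix.

    The matrix is reindexed onto the complete candidate-hour grid so absent
    rows and blank values are both treated as missing.
    """
    slots = expected_timestamps(periods)
    if len(slots) == 0:
        raise ValueError("study periods contain zero expected hours")
    meta = (
        obs.groupby("station_id", sort=True)[["lat", "lon"]]
        .first()
        .astype(float)
    )
    mat = obs.pivot_table(
        index="timestamp", columns="station_id", values="pm25", aggfunc="mean"
    )
    mat = mat.reindex(index=slots, columns=meta.index)
    mat.index.name = "timestamp"
    return mat, meta


def filter_stations(
    obs: pd.DataFrame,
    periods: list[ScenarioPeriod],
    threshold: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop stations whose missing fraction over the study months is > threshold.

    The comparison is strict ("over 20% missing"), so a station at exactly the
    threshold is retained.  Returns the retained observations (still long
    format, restricted to candidate hours) and a per-station report with the
    missing fraction and retention flag.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    mat, meta = _station_matrix(obs, periods)
    n_expected = len(mat.index)
    frac = mat.isna().sum(axis=0) / n_expected
    report = pd.DataFrame(
        {
            "station_id": frac.index,
            "lat": meta["lat"].values,
            "lon": meta["lon"].values,
            "missing_fraction": frac.values,
            "retained": (frac.values <= threshold),
        }
    ).reset_index(drop=True)
    kept = report.loc[report["retained"], "station_id"]
    long = (
        mat.loc[:, kept]
        .reset_index()
        .melt(id_vars="timestamp", var_name="station_id", value_name="pm25")
        .merge(meta.reset_index(), on="station_id")
    )
    long = long[["station_id", "lat", "lon", "timestamp", "pm25"]]
    dropped = report.loc[~report["retained"], "station_id"].tolist()
    if dropped:
        log.info("filter_stations dropped %d/%d stations", len(dropped), len(report))
    return long.sort_values(["station_id", "timestamp"]).reset_index(drop=True), report


# ---------------------------------------------------------------------------
# Gap filling
# ---------------------------------------------------------------------------

def interpolate_temporal(series: pd.Series, observed: pd.Series | None = None) -> pd.Series:
    """Fill gaps with the midpoint of the two adjacent candidate hours.

    A missing value is filled only when both the immediately previous and next
    candidate hours are *observed* (present in ``observed``, not themselves
    interpolated).  ``observed`` defaults to the series' own non-NaN mask.
    """
    if observed is None:
        observed = series.notna()
    prev_ok = observed.shift(1, fill_value=False)
    next_ok = observed.shift(-1, fill_value=False)
    fill = ~observed & prev_ok & next_ok
    out = series.copy()
    out[fill] = (series.shift(1)[fill] + series.shift(-1)[fill]) / 2.0
    return out


def idw2_weights(distances_km: np.ndarray) -> np.ndarray:
    """Normalized inverse-distance-squared weights; a coincident donor (d=0)
    takes all the weight (shared equally among coincident donors)."""
    d = np.asarray(distances_km, dtype=float)
    zero = d == 0.0
    if zero.any():
        w = zero.astype(float)
    else:
        w = 1.0 / d**2
    return w / w.sum()


def interpolate_spatial(
    lat: float,
    lon: float,
    donor_lats: np.ndarray,
    donor_lons: np.ndarray,
    donor_values: np.ndarray,
) -> float:
    """IDW² estimate at (lat, lon) from co-temporal donor stations."""
    donor_values = np.asarray(donor_values, dtype=float)
    if donor_values.size == 0:
        raise ValueError("no co-temporal donor observations")
    d = haversine_km(lat, lon, np.asarray(donor_lats), np.asarray(donor_lons))
    return float(idw2_weights(d) @ donor_values)


def _fill_matrix(
    mat: pd.DataFrame,
    meta: pd.DataFrame,
    observed: pd.DataFrame,
    periods: list[ScenarioPeriod],
    targets: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, int, int, int]:
    """Temporal-then-spatial fill of a station matrix.

    ``observed`` marks values usable as interpolation sources (originally
    observed, not masked).  ``targets`` optionally restricts which missing
    entries are filled (used by the interpolation cross-validation).  Temporal
    adjacency never crosses a period boundary.  Returns the filled matrix and
    the (temporal, spatial, unfilled) counts.
    """
    if targets is None:
        targets = ~observed
    work = mat.where(observed)
    filled = work.copy()

    # temporal pass, per period so months-apart slots are never neighbours
    for p in periods:
        rows = work.index[p.contains(work.index)]
        sub = work.loc[rows]
        obs_sub = observed.loc[rows]
        prev_ok = obs_sub.shift(1, fill_value=False)
        next_ok = obs_sub.shift(-1, fill_value=False)
        can = targets.loc[rows] & ~obs_sub & prev_ok & next_ok
        filled.loc[rows] = sub.where(~can, (sub.shift(1) + sub.shift(-1)) / 2.0)
    n_temporal = int((filled.notna() & ~observed).to_numpy().sum())

    # spatial pass on what remains
    remaining = targets & filled.isna()
    n_spatial = 0
    n_unfilled = 0
    if remaining.to_numpy().any():
        lats = meta["lat"].to_numpy()
        lons = meta["lon"].to_numpy()
        dist = haversine_km(lats[:, None], lons[:, None], lats[None, :], lons[None, :])
        with np.errstate(divide="ignore"):
            w_all = 1.0 / dist**2
        coincident = dist == 0.0
        np.fill_diagonal(coincident, False)
        vals = work.to_numpy()
        obs_np = observed.to_numpy()
        out = filled.to_numpy()
        rem_np = remaining.to_numpy()
        for t in np.nonzero(rem_np.any(axis=1))[0]:
            donors = obs_np[t]
            miss = np.nonzero(rem_np[t])[0]
            if not donors.any():
                n_unfilled += len(miss)
                continue
            y = vals[t, donors]
            for j in miss:
                co = coincident[j] & donors
                if co.any():
                    out[t, j] = vals[t, co].mean()
                else:
                    w = w_all[j, donors]
                    out[t, j] = (w @ y) / w.sum()
                n_spatial += 1
        filled = pd.DataFrame(out, index=mat.index, columns=mat.columns)
    else:
        n_unfilled = 0
    n_unfilled = int(targets.to_numpy().sum()) - n_temporal - n_spatial
    return filled, n_temporal, n_spatial, n_unfilled


def interpolate(
    obs: pd.DataFrame, periods: list[ScenarioPeriod]
) -> tuple[pd.DataFrame, InterpolationReport]:
    """Run the temporal-then-spatial fill over the full observation set."""
    mat, meta = _station_matrix(obs, periods)
    observed = mat.notna()
    n_missing = int((~observed).to_numpy().sum())
    filled, n_t, n_s, n_u = _fill_matrix(mat, meta, observed, periods)
    report = InterpolationReport(
        n_missing=n_missing, n_temporal=n_t, n_spatial=n_s, n_unfilled=n_u
    )
    long = (
        filled.reset_index()
        .melt(id_vars="timestamp", var_name="station_id", value_name="pm25")
        .merge(meta.reset_index(), on="station_id")
    )[["station_id", "lat", "lon", "timestamp", "pm25"]]
    if n_u:
        log.warning("%d missing values could not be interpolated", n_u)
    return long.sort_values(["station_id", "timestamp"]).reset_index(drop=True), report


def cross_validate_interpolation(
    obs: pd.DataFrame,
    periods: list[ScenarioPeriod],
    k: int = 10,
    seed: int = 0,
) -> InterpolationReport:
    """k-fold cross-validation of the gap-filling rule.

    Originally observed values are partitioned into k random folds; each fold
    is masked in turn and reconstructed from the remaining observed values by
    the temporal-then-spatial rule; the report averages the per-fold MAEs.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    mat, meta = _station_matrix(obs, periods)
    observed = mat.notna()
    obs_idx = np.argwhere(observed.to_numpy())
    if k > len(obs_idx):
        raise ValueError(f"k={k} exceeds number of observed values ({len(obs_idx)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(obs_idx))
    fold_maes = []
    truth = mat.to_numpy()
    for fold in range(k):
        take = obs_idx[order[fold::k]]
        fold_mask = np.zeros(mat.shape, dtype=bool)
        fold_mask[take[:, 0], take[:, 1]] = True
        usable = observed & ~pd.DataFrame(fold_mask, index=mat.index, columns=mat.columns)
        filled, _, _, _ = _fill_matrix(
            mat, meta, usable, periods,
            targets=pd.DataFrame(fold_mask, index=mat.index, columns=mat.columns),
        )
        rec = filled.to_numpy()[take[:, 0], take[:, 1]]
        true = truth[take[:, 0], take[:, 1]]
        ok = ~np.isnan(rec)
        if ok.any():
            fold_maes.append(float(np.mean(np.abs(rec[ok] - true[ok]))))
    _, full_report = interpolate(obs, periods)
    return InterpolationReport(
        n_missing=full_report.n_missing,
        n_temporal=full_report.n_temporal,
        n_spatial=full_report.n_spatial,
        n_unfilled=full_report.n_unfilled,
        cv_mae=float(np.mean(fold_maes)) if fold_maes else None,
        cv_fold_maes=tuple(fold_maes),
        n_folds=k,
    )


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

class Standardizer(TransformerMixin, BaseEstimator):
    """Centre and scale to zero mean / unit population standard deviation.

    Unlike a per-call z-score, fitted parameters are stored so data predicted
    by a model are transformed with that model's *training* parameters.
    """

    def fit(self, X, y=None):
        names = (
            tuple(X.columns) if isinstance(X, pd.DataFrame)
            else tuple(f"x{i}" for i in range(np.shape(X)[1]))
        )
        arr = np.asarray(X, dtype=float)
        if arr.shape[0] < 2:
            raise ValueError("need at least 2 values to standardize")
        mean = arr.mean(axis=0)
        std = arr.std(axis=0, ddof=0)
        if np.any(std == 0):
            bad = [n for n, s in zip(names, std) if s == 0]
            raise ValueError(f"constant variable(s) {bad}: standard deviation is 0")
        self.params_ = StandardizationParams(names=names, mean=mean, std=std)
        return self

    def transform(self, X) -> np.ndarray:
        return self.params_.transform(X)

    def inverse_transform(self, Z) -> np.ndarray:
        return self.params_.inverse(Z)


def standardize(values) -> tuple[np.ndarray, StandardizationParams]:
    """Standardize a 1-D sequence; returns (z-scores, fitted params)."""
    arr = np.asarray(values, dtype=float).reshape(-1, 1)
    s = Standardizer().fit(arr)
    return s.transform(arr).ravel(), s.params_


# ---------------------------------------------------------------------------
# Grid construction and matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid:
    """Regular lat/lon analysis grid addressed by cell ids ``g{i}-{j}``."""

    lat_centers: np.ndarray
    lon_centers: np.ndarray
    spacing: float

    @classmethod
    def from_bounds(cls, lat_min, lat_max, lon_min, lon_max, spacing) -> "Grid":
        n_lat = int(round((lat_max - lat_min) / spacing)) + 1
        n_lon = int(round((lon_max - lon_min) / spacing)) + 1
        return cls(
            lat_centers=lat_min + spacing * np.arange(n_lat),
            lon_centers=lon_min + spacing * np.arange(n_lon),
            spacing=spacing,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.lat_centers), len(self.lon_centers)

    def cell_id(self, i, j):
        i = np.asarray(i)
        j = np.asarray(j)
        flat = np.char.add(
            np.char.add("g", i.astype(str)), np.char.add("-", j.astype(str))
        )
        return flat

    def cell_frame(self) -> pd.DataFrame:
        ii, jj = np.meshgrid(
            np.arange(len(self.lat_centers)), np.arange(len(self.lon_centers)),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "cell_id": self.cell_id(ii.ravel(), jj.ravel()),
                "lat": self.lat_centers[ii.ravel()],
                "lon": self.lon_centers[jj.ravel()],
            }
        )

    def nearest_cell(self, lats, lons, ids=None) -> np.ndarray:
        """Nearest grid cell per point (equivalent to haversine nearest on a
        regular lat/lon grid); raises for points outside the bounding box."""
        lats = np.asarray(lats, dtype=float)
        lons = np.asarray(lons, dtype=float)
        i = np.round((lats - self.lat_centers[0]) / self.spacing).astype(int)
        j = np.round((lons - self.lon_centers[0]) / self.spacing).astype(int)
        bad = (i < 0) | (i >= len(self.lat_centers)) | (j < 0) | (j >= len(self.lon_centers))
        if bad.any():
            which = (
                list(np.asarray(ids)[bad]) if ids is not None else np.nonzero(bad)[0].tolist()
            )
            raise ValueError(f"stations outside grid bounding box: {which}")
        return self.cell_id(i, j)


def _nearest_index(targets: np.ndarray, sources: np.ndarray) -> np.ndarray:
    pos = np.searchsorted(sources, targets)
    pos = np.clip(pos, 1, len(sources) - 1) if len(sources) > 1 else np.zeros_like(pos)
    left = sources[pos - 1] if len(sources) > 1 else sources[pos]
    right = sources[pos] if len(sources) > 1 else sources[pos]
    if len(sources) == 1:
        return np.zeros(len(targets), dtype=int)
    use_right = np.abs(targets - right) < np.abs(targets - left)
    return np.where(use_right, pos, pos - 1)


def resample_meteo(meteo: pd.DataFrame, spacing: float) -> tuple[Grid, pd.DataFrame]:
    """Resample source meteorology to the analysis grid by nearest source cell.

    No smoothing is applied; each analysis cell takes the values of its
    nearest source cell (axis-wise nearest on a regular grid).
    """
    src_lat = np.sort(meteo["lat"].unique())
    src_lon = np.sort(meteo["lon"].unique())
    grid = Grid.from_bounds(src_lat[0], src_lat[-1], src_lon[0], src_lon[-1], spacing)
    times = np.sort(meteo["timestamp"].unique())
    pivots = {}
    for var in MET_VARS:
        pv = meteo.pivot_table(index="timestamp", columns=["lat", "lon"], values=var)
        pv = pv.reindex(
            index=times, columns=pd.MultiIndex.from_product([src_lat, src_lon])
        )
        if pv.isna().to_numpy().any():
            raise ValueError(f"meteorology incomplete over its grid for {var}")
        pivots[var] = pv.to_numpy().reshape(len(times), len(src_lat), len(src_lon))
    li = _nearest_index(grid.lat_centers, src_lat)
    lj = _nearest_index(grid.lon_centers, src_lon)
    n_lat, n_lon = grid.shape
    cells = grid.cell_frame()
    frames = []
    for t_idx, t in enumerate(times):
        block = {"timestamp": np.repeat(t, n_lat * n_lon)}
        for var in MET_VARS:
            block[var] = pivots[var][t_idx][np.ix_(li, lj)].ravel()
        frames.append(pd.DataFrame(block).assign(
            cell_id=cells["cell_id"].values,
            lat=cells["lat"].values,
            lon=cells["lon"].values,
        ))
    out = pd.concat(frames, ignore_index=True)
    return grid, out[["cell_id", "lat", "lon", "timestamp", *MET_VARS]]


def match_grid(
    obs_filled: pd.DataFrame,
    meteo: pd.DataFrame,
    spacing: float = 0.05,
    region_map: pd.Series | None = None,
    landuse_map: pd.Series | None = None,
) -> tuple[pd.DataFrame, Grid, pd.Series]:
    """Match stations to nearest analysis cells and build model samples.

    Each cell containing at least one station emits one sample per candidate
    timestamp with ``pm25_mean`` = arithmetic mean of its stations' values and
    the cell's (raw) meteorology + centre coordinates as features.  Returns
    (samples, grid, station->cell assignment).
    """
    grid, met = resample_meteo(meteo, spacing)
    meta = obs_filled.groupby("station_id", sort=True)[["lat", "lon"]].first()
    cell_of = pd.Series(
        grid.nearest_cell(meta["lat"].values, meta["lon"].values, ids=meta.index),
        index=meta.index,
        name="cell_id",
    )
    obs = obs_filled.merge(cell_of.rename("cell_id"), left_on="station_id", right_index=True)
    cellmean = (
        obs.dropna(subset=["pm25"])
        .groupby(["cell_id", "timestamp"], as_index=False)
        .agg(pm25_mean=("pm25", "mean"), n_stations=("pm25", "size"))
    )
    samples = cellmean.merge(met, on=["cell_id", "timestamp"], how="inner")
    samples["date"] = samples["timestamp"].dt.normalize()
    samples["hour"] = samples["timestamp"].dt.hour
    samples = samples[samples["hour"].isin(ANALYSIS_HOURS)]
    samples["region"] = (
        samples["cell_id"].map(region_map).fillna("all") if region_map is not None else "all"
    )
    samples["landuse"] = (
        samples["cell_id"].map(landuse_map).fillna("unknown")
        if landuse_map is not None
        else "unknown"
    )
    cols = ["cell_id", "region", "landuse", "date", "hour", "timestamp",
            *FEATURES, "pm25_mean", "n_stations"]
    return samples[cols].reset_index(drop=True), grid, cell_of


def split_scenarios(
    samples: pd.DataFrame, periods: list[ScenarioPeriod]
) -> dict[str, pd.DataFrame]:
    """Partition matched samples by scenario date range."""
    out = {}
    for p in periods:
        mask = p.contains(samples["date"])
        out[p.label] = samples.loc[mask].reset_index(drop=True)
    return out


def stratify_hours(samples: pd.DataFrame, label: str) -> dict[int, ScenarioDataset]:
    """Split one scenario's samples into the four hour-class datasets."""
    bad = set(samples["hour"].unique()) - set(ANALYSIS_HOURS)
    if bad:
        raise ValueError(f"samples at unexpected hour(s) {sorted(bad)}")
    if samples.empty:
        warnings.warn(f"scenario {label}: no samples to stratify", stacklevel=2)
    return {
        h: ScenarioDataset(
            label=label,
            hour=h,
            samples=samples[samples["hour"] == h].reset_index(drop=True),
        )
        for h in ANALYSIS_HOURS
    }
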