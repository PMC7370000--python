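"""Hour-stratified spatiotemporal random-forest regression of PM2.5.

One forest is trained per (reference scenario, hour class) on the seven
features — five meteorological variables plus the grid-cell centre latitude
and longitude — so the model captures the meteorology-to-PM2.5 relationship
*under that scenario's emission regime*.  Predictions are clamped at 0 because
a concentration cannot be negative.

The estimator follows the scikit-learn contract (``fit`` / ``predict`` /
``get_params``) and standardizes its inputs internally with parameters fitted
on the training data, so counterfactual inputs are always transformed with the
training-scenario parameters.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .preprocessing import Standardizer
from .types import FEATURES, ScenarioDataset

log = logging.getLogger("deweather")


class SpatioTemporalRandomForest(RegressorMixin, BaseEstimator):
    """Clamped regression forest over meteorology + location features.

    Parameters
    ----------
    ntree
        Number of trees; each is grown on a bootstrap resample of size n.
    mtry
        Number of candidate split features drawn (without replacement) at each
        node; the best axis-aligned split minimises the summed within-child
        squared deviation of the target.
    min_node_size
        Minimum samples per leaf (regression-forest convention, default 5).
    bootstrap
        Grow each tree on a bootstrap resample (disable for deterministic
        single-tree analyses).
    random_state
        Seed for bootstrap and feature subsampling.
    """

    def __init__(
        self,
        ntree: int = 200,
        mtry: int = 2,
        min_node_size: int = 5,
        bootstrap: bool = True,
        random_state: int | None = None,
    ):
        self.ntree = ntree
        self.mtry = mtry
        self.min_node_size = min_node_size
        self.bootstrap = bootstrap
        self.random_state = random_state

    def _as_array(self, X, fitted: bool) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            cols = [c for c in FEATURES if c in X.columns]
            X = X[cols] if len(cols) == len(FEATURES) else X
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if fitted and arr.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {arr.shape[1]}"
            )
        return arr

    def fit(self, X, y):
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        arr = self._as_array(X, fitted=False)
        y = np.asarray(y, dtype=float)
        if len(y) != len(arr):
            raise ValueError("X and y length mismatch")
        if len(y) < self.min_node_size:
            raise ValueError(
                f"dataset of {len(y)} samples smaller than min_node_size={self.min_node_size}"
            )
        if not (1 <= self.mtry <= arr.shape[1]):
            raise ValueError(f"mtry must be in [1, {arr.shape[1]}]")
        self.n_features_in_ = arr.shape[1]
        if np.ptp(y) == 0:
            warnings.warn("constant training target: model predicts a constant",
                          stacklevel=2)
        self.scaler_ = Standardizer().fit(arr)
        z = self.scaler_.transform(arr)
        self.forest_ = RandomForestRegressor(
            n_estimators=self.ntree,
            max_features=self.mtry,
            min_samples_leaf=self.min_node_size,
            bootstrap=self.bootstrap,
            random_state=self.random_state,
            n_jobs=1,
        )
        self.forest_.fit(z, y)
        self.y_min_ = float(y.min())
        self.y_max_ = float(y.max())
        return self

    def predict(self, X) -> np.ndarray:
        """Forest-mean prediction clamped at 0 (a concentration is >= 0)."""
        arr = self._as_array(X, fitted=True)
        raw = self.forest_.predict(self.scaler_.transform(arr))
        return np.maximum(raw, 0.0)

    def predict_raw(self, X) -> np.ndarray:
        """Unclamped forest mean (diagnostics only)."""
        arr = self._as_array(X, fitted=True)
        return self.forest_.predict(self.scaler_.transform(arr))


def train_strf(
    dataset: ScenarioDataset,
    ntree: int = 200,
    mtry: int = 2,
    min_node_size: int = 5,
    random_state: int | None = None,
) -> SpatioTemporalRandomForest:
    """Fit one hour-class model on a scenario dataset's matched samples."""
    if len(dataset) == 0:
        raise ValueError(f"empty dataset for {dataset.label} hour {dataset.hour:02d}")
    model = SpatioTemporalRandomForest(
        ntree=ntree, mtry=mtry, min_node_size=min_node_size, random_state=random_state
    )
    model.fit(dataset.samples[list(FEATURES)], dataset.samples["pm25_mean"].to_numpy())
    dataset.params = model.scaler_.params_
    return model


def compute_metrics(observed, predicted) -> dict[str, float]:
    """RMSE, MAE and R² (squared Pearson correlation, as a fraction).

    R² is reported as a fraction in [0, 1]; the ``r2_percent`` entry carries
    the same quantity on the x100 scale.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted must have equal length")
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if np.var(y) == 0 or np.var(yhat) == 0:
        raise ValueError("R^2 undefined for a constant sequence")
    err = y - yhat
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    r = float(np.corrcoef(y, yhat)[0, 1])
    return {"rmse": rmse, "mae": mae, "r2": r**2, "r2_percent": 100.0 * r**2}


def cross_validate(
    dataset: ScenarioDataset,
    ntree: int = 200,
    mtry: int = 2,
    min_node_size: int = 5,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """k-fold cross-validation of one hour-class model, overall and per region.

    Samples are randomly partitioned into k seeded folds; each fold is held
    out, a model is trained on the remainder (fold model seeded ``seed+fold``)
    and metrics are computed on the held-out predictions.  Region rows average
    each fold's held-out samples of that region; folds where a region has too
    few held-out samples (or a constant sequence) contribute nothing for that
    region.  Returns one row per region plus an "All" row.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(dataset)
    if n < k:
        raise ValueError(f"dataset of {n} samples smaller than k={k}")
    X = dataset.samples[list(FEATURES)]
    y = dataset.samples["pm25_mean"].to_numpy()
    regions = dataset.samples["region"].to_numpy()
    folds = KFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold: dict[str, list[dict]] = {}
    for fold, (tr, te) in enumerate(folds.split(X)):
        model = SpatioTemporalRandomForest(
            ntree=ntree, mtry=mtry, min_node_size=min_node_size,
            random_state=seed + fold,
        )
        model.fit(X.iloc[tr], y[tr])
        pred = model.predict(X.iloc[te])
        groups = [("All", np.ones(len(te), dtype=bool))] + [
            (r, regions[te] == r) for r in np.unique(regions)
        ]
        for name, mask in groups:
            if mask.sum() < 2:
                log.debug("cv fold %d: region %s too small, skipped", fold, name)
                continue
            try:
                m = compute_metrics(y[te][mask], pred[mask])
            except ValueError:
                log.debug("cv fold %d: region %s metrics undefined, skipped", fold, name)
                continue
            per_fold.setdefault(name, []).append(m)
    rows = []
    for name, ms in per_fold.items():
        obs_mean = (
            float(y.mean()) if name == "All" else float(y[regions == name].mean())
        )
        rows.append(
            {
                "scenario": dataset.label,
                "hour": dataset.hour,
                "region": name,
                "obs_mean": obs_mean,
                "rmse": float(np.mean([m["rmse"] for m in ms])),
                "mae": float(np.mean([m["mae"] for m in ms])),
                "r2": float(np.mean([m["r2"] for m in ms])),
                "n_folds": len(ms),
            }
        )
    columns = ["scenario", "hour", "region", "obs_mean", "rmse", "mae", "r2", "n_folds"]
    if not rows:  # e.g. leave-one-out: metrics undefined on 1-sample folds
        log.warning("cross_validate: no fold produced defined metrics")
        return pd.DataFrame(columns=columns)
    out = pd.DataFrame(rows)[columns].sort_values("region").reset_index(drop=True)
    return out
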