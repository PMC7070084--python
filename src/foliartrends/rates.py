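"""Per-tree robust rate estimation and ensemble rate mapping.

Rates of change of foliar concentrations and of climate/deposition drivers
are estimated per tree with the Theil-Sen estimator (median of all pairwise
slopes; trees need more than five measurements).  A replicated train/test
ensemble of nonlinear regressors then maps nutrient rate-of-change from the
driver rates, mirroring the 1000-replicate, 80/20-split neural-network
procedure; predictions on a covariate grid are averaged over replicates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LinearRegression
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.metrics import r2_score

logger = logging.getLogger("foliartrends")

__all__ = [
    "theil_sen",
    "per_entity_rates",
    "RegressorSpec",
    "EnsembleModel",
    "fit_rate_ensemble",
    "predict_rate_grid",
]

RATE_COVARIATES = ("mat_rate", "map_rate", "ndep_ox_rate", "ndep_red_rate", "sdep_rate")


def theil_sen(times, values, even_median: str = "mean") -> float:
    """Median of all pairwise slopes (value difference / time difference).

    ``even_median``: with an even number of pairwise slopes, "mean" (default)
    returns the midpoint of the two central slopes, "lower" the lower one.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two points")
    i, j = np.triu_indices(t.size, k=1)
    dt = t[j] - t[i]
    ok = dt != 0
    if not ok.any():
        raise ValueError("all time points identical")
    slopes = np.sort((v[j] - v[i])[ok] / dt[ok])
    m = slopes.size
    if m % 2 == 1:
        return float(slopes[m // 2])
    lo, hi = slopes[m // 2 - 1], slopes[m // 2]
    if even_median == "lower":
        return float(lo)
    if even_median == "mean":
        return float(0.5 * (lo + hi))
    raise ValueError("even_median must be 'mean' or 'lower'")


def per_entity_rates(
    panel: pd.DataFrame,
    drivers: pd.DataFrame,
    element: str,
    min_obs: int = 6,
) -> pd.DataFrame:
    """Theil-Sen rate per tree series with >= min_obs measurements.

    For each eligible entity the element rate (mg g-1 yr-1) and the rates of
    MAT, MAP and N/S deposition over the same site-years are returned.
    Ineligible entities are excluded; the count is logged and stored in
    ``result.attrs['n_excluded']``.
    """
    keys = [k for k in ("country", "plot", "species", "tree") if k in panel.columns]
    drv = drivers.set_index(["site_id", "year"])
    rows = []
    n_excluded = 0
    for ent, g in panel.groupby(keys, sort=True):
        if len(g) < min_obs:
            n_excluded += 1
            continue
        yrs = g["year"].to_numpy(float)
        rec = {
            "entity_id": "/".join(map(str, ent)),
            "element": element,
            "rate": theil_sen(yrs, g[element].to_numpy()),
            "n_obs": len(g),
            "latitude": float(g["latitude"].iloc[0]),
            "longitude": float(g["longitude"].iloc[0]),
        }
        sid = g["site_id"].iloc[0]
        sub = drv.loc[sid].reindex(g["year"].astype(int).to_numpy())
        for name, col in (
            ("mat_rate", "mat"),
            ("map_rate", "map"),
            ("ndep_ox_rate", "ndep_ox"),
            ("ndep_red_rate", "ndep_red"),
            ("sdep_rate", "sdep"),
        ):
            rec[name] = theil_sen(yrs, sub[col].to_numpy())
        rows.append(rec)
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = n_excluded
    logger.info("per_entity_rates: %d entities kept, %d excluded (<%d obs)",
                len(out), n_excluded, min_obs)
    return out


@dataclass
class RegressorSpec:
    """Pluggable regressor behind the ensemble.

    kind "mlp" is the reference architecture (two hidden layers of 128
    rectified-linear units); "linear" and "gbm" are fast alternatives used
    where the architecture itself is not under study.
    """

    kind: str = "mlp"
    hidden: tuple = (128, 128)
    max_iter: int = 500
    params: dict = field(default_factory=dict)

    def build(self, seed: int):
        if self.kind == "mlp":
            return MLPRegressor(
                hidden_layer_sizes=self.hidden,
                activation="relu",
                max_iter=self.max_iter,
                random_state=seed,
                **self.params,
            )
        if self.kind == "linear":
            return LinearRegression(**self.params)
        if self.kind == "gbm":
            return HistGradientBoostingRegressor(random_state=seed, **self.params)
        raise ValueError(f"unknown regressor kind {self.kind!r}")


@dataclass
class EnsembleModel:
    covariates: list
    models: list
    scores: list  # held-out R^2 per replicate
    split: float
    train_min: np.ndarray
    train_max: np.ndarray
    n_dropped: int = 0

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        preds = np.stack([m.predict(X) for m in self.models], axis=0)
        return preds.mean(axis=0)


def fit_rate_ensemble(
    rates: pd.DataFrame,
    covariates=RATE_COVARIATES,
    target: str = "rate",
    replicates: int = 1000,
    split: float = 0.8,
    regressor: RegressorSpec | None = None,
    seed: int = 0,
) -> EnsembleModel:
    """Replicated split/fit/score ensemble over rate records.

    Each replicate draws a random ``split`` training fraction, fits the
    regressor, and scores R^2 on the held-out fraction.  Replicates whose
    regressor fails to converge are dropped and logged; more than 20%
    dropped is an error.  The aggregate predictor averages replicate
    predictions.
    """
    if not (0.0 < split < 1.0):
        raise ValueError("split must lie in (0, 1)")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if len(rates) < 10:
        raise ValueError("need at least 10 rate records")
    covariates = list(covariates)
    X = rates[covariates].to_numpy(float)
    y = rates[target].to_numpy(float)
    spec = regressor or RegressorSpec()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    n = len(y)
    n_train = max(int(round(split * n)), 1)
    models, scores = [], []
    n_dropped = 0
    for r in range(replicates):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        est = spec.build(int(rng.integers(0, 2**31 - 1)))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            est.fit(X[tr], y[tr])
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            n_dropped += 1
            logger.warning("replicate %d dropped: regressor did not converge", r)
            continue
        models.append(est)
        if te.size:
            scores.append(float(r2_score(y[te], est.predict(X[te]))))
    if n_dropped > 0.2 * replicates or not models:
        raise RuntimeError(
            f"{n_dropped}/{replicates} replicates failed to converge (> 20%)"
        )
    return EnsembleModel(
        covariates=covariates,
        models=models,
        scores=scores,
        split=split,
        train_min=X.min(axis=0),
        train_max=X.max(axis=0),
        n_dropped=n_dropped,
    )


def predict_rate_grid(model: EnsembleModel, grid: pd.DataFrame) -> pd.DataFrame:
    """Averaged ensemble prediction per grid cell.

    Cells outside the training covariate bounding box are flagged as
    extrapolation.  Output is sorted by (lon, lat) when those columns exist.
    """
    missing = [c for c in model.covariates if c not in grid.columns]
    if missing:
        raise ValueError(f"grid is missing covariates: {missing}")
    out = grid.copy()
    if len(out) == 0:
        out["predicted_rate"] = np.zeros(0)
        out["extrapolation"] = np.zeros(0, dtype=bool)
        return out
    X = out[model.covariates].to_numpy(float)
    out["predicted_rate"] = model.predict(X)
    out["extrapolation"] = ((X < model.train_min) | (X > model.train_max)).any(axis=1)
    if {"lon", "lat"}.issubset(out.columns):
        out = out.sort_values(["lon", "lat"], kind="mergesort").reset_index(drop=True)
    return out
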