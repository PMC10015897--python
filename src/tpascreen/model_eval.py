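"""Repeated random-split cross-validation of pluggable regressors.

The evaluation protocol of record is 240 independent random 85:15
train/test splits; metrics (MSE, MAE, R^2) are computed on each held-out
set in lg(TPACS) units and averaged.  Per-sample prediction scatter across
the runs in which a sample was held out doubles as an ensemble uncertainty
for screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CVProtocol",
    "EvalResult",
    "RegressorSpec",
    "REGRESSOR_REGISTRY",
    "make_regressor",
    "split",
    "evaluate",
    "fit_ensemble",
    "predict_ensemble",
]


@dataclass(frozen=True)
class CVProtocol:
    """Repeated random-split protocol (defaults: 240 runs at 85:15)."""

    n_runs: int = 240
    test_fraction: float = 0.15
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class EvalResult:
    """Per-run and aggregate test metrics plus per-sample prediction spread."""

    mse_runs: np.ndarray
    mae_runs: np.ndarray
    r2_runs: np.ndarray
    pred_mean: np.ndarray   # per-sample mean held-out prediction (NaN if never held out)
    pred_sd: np.ndarray
    n_failed: int = 0

    @property
    def mse(self) -> float:
        return float(np.mean(self.mse_runs))

    @property
    def mae(self) -> float:
        return float(np.mean(self.mae_runs))

    @property
    def r2(self) -> float:
        return float(np.mean(self.r2_runs))


@dataclass(frozen=True)
class RegressorSpec:
    """Named entry of the regressor registry."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    deterministic_given_seed: bool = True


# Pinned default hyperparameters.  The reference regressor for selection and
# interpretation is gradient-boosted trees (xgboost flavor).
_DEFAULTS: dict[str, dict] = {
    "xgboost": dict(n_estimators=500, learning_rate=0.05, max_depth=6,
                    tree_method="hist", n_jobs=1, verbosity=0),
    "gbrt": dict(n_estimators=500, learning_rate=0.05, max_depth=6),
    "lasso": dict(alpha=0.01, max_iter=10000),
    "elasticnet": dict(alpha=0.01, l1_ratio=0.5, max_iter=10000),
    "random_forest": dict(n_estimators=300, n_jobs=1),
    "decision_tree": dict(max_depth=8),
    "knn": dict(n_neighbors=5),
    "adaboost": dict(n_estimators=200),
    "mlp": dict(hidden_layer_sizes=(64, 64), max_iter=2000),
}


def _factory(name: str, seed: int, hyper: dict):
    from sklearn.ensemble import (
        AdaBoostRegressor,
        GradientBoostingRegressor,
        RandomForestRegressor,
    )
    from sklearn.linear_model import ElasticNet, Lasso
    from sklearn.neighbors import KNeighborsRegressor
    from sklearn.neural_network import MLPRegressor
    from sklearn.tree import DecisionTreeRegressor
    from xgboost import XGBRegressor

    params = dict(_DEFAULTS[name])
    params.update(hyper)
    if name == "xgboost":
        return XGBRegressor(random_state=seed, **params)
    if name == "gbrt":
        return GradientBoostingRegressor(random_state=seed, **params)
    if name == "lasso":
        return Lasso(random_state=seed, **params)
    if name == "elasticnet":
        return ElasticNet(random_state=seed, **params)
    if name == "random_forest":
        return RandomForestRegressor(random_state=seed, **params)
    if name == "decision_tree":
        return DecisionTreeRegressor(random_state=seed, **params)
    if name == "knn":
        return KNeighborsRegressor(**params)
    if name == "adaboost":
        return AdaBoostRegressor(random_state=seed, **params)
    if name == "mlp":
        return MLPRegressor(random_state=seed, **params)
    raise KeyError(name)


REGRESSOR_REGISTRY: dict[str, RegressorSpec] = {
    name: RegressorSpec(name=name, hyperparameters=dict(params))
    for name, params in _DEFAULTS.items()
}


def make_regressor(spec: RegressorSpec | str, seed: int = 0):
    """Instantiate a registry regressor with its pinned hyperparameters."""
    if isinstance(spec, str):
        spec = REGRESSOR_REGISTRY[spec]
    extra = {
        k: v for k, v in spec.hyperparameters.items()
        if k not in _DEFAULTS[spec.name] or _DEFAULTS[spec.name][k] != v
    }
    return _factory(spec.name, seed, extra)


def split(n: int, protocol: CVProtocol, run_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index split for one CV run.

    Train size is round(n * (1 - f)); seeded by base_seed + run_index so
    every run is reproducible independently.
    """
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = int(np.floor(n * (1.0 - protocol.test_fraction) + 0.5))
    n_test = n - n_train
    if n_test < 1:
        raise ValueError(
            f"test fraction {protocol.test_fraction} yields an empty test set at n={n}"
        )
    rng = np.random.default_rng(protocol.base_seed + run_index)
    perm = rng.permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    err = y_true - y_pred
    mse = float(np.mean(err**2))
    mae = float(np.mean(np.abs(err)))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / sst if sst > 0 else float("nan")
    return mse, mae, r2


def evaluate(
    X: np.ndarray,
    y: np.ndarray,
    regressor: RegressorSpec | str,
    protocol: CVProtocol = CVProtocol(),
) -> EvalResult:
    """Run the repeated-split protocol for one regressor.

    A run on which the regressor raises is excluded from the averages with
    a warning rather than aborting the protocol.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    mses, maes, r2s = [], [], []
    pred_sum = np.zeros(n)
    pred_sumsq = np.zeros(n)
    pred_count = np.zeros(n)
    n_failed = 0
    for run in range(protocol.n_runs):
        tr, te = split(n, protocol, run)
        try:
            model = make_regressor(regressor, seed=protocol.base_seed + run)
            model.fit(X[tr], y[tr])
            pred = np.asarray(model.predict(X[te]), dtype=float)
        except Exception as exc:  # noqa: BLE001 - exclude-and-warn policy
            warnings.warn(f"CV run {run} failed: {exc!r}; excluded from averages")
            n_failed += 1
            continue
        mse, mae, r2 = _metrics(y[te], pred)
        mses.append(mse)
        maes.append(mae)
        r2s.append(r2)
        pred_sum[te] += pred
        pred_sumsq[te] += pred**2
        pred_count[te] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = pred_sum / pred_count
        var = pred_sumsq / pred_count - mean**2
        sd = np.sqrt(np.clip(var, 0.0, None))
    return EvalResult(
        mse_runs=np.array(mses),
        mae_runs=np.array(maes),
        r2_runs=np.array(r2s),
        pred_mean=mean,
        pred_sd=sd,
        n_failed=n_failed,
    )


def fit_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    regressor: RegressorSpec | str,
    protocol: CVProtocol = CVProtocol(),
) -> list:
    """Fit one model per CV run (on that run's training fold)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    models = []
    for run in range(protocol.n_runs):
        tr, _ = split(len(y), protocol, run)
        model = make_regressor(regressor, seed=protocol.base_seed + run)
        model.fit(X[tr], y[tr])
        models.append(model)
    return models


def predict_ensemble(models: Sequence, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard deviation of predictions across an ensemble."""
    if not models:
        raise ValueError("empty model ensemble")
    X = np.asarray(X, dtype=float)
    preds = np.stack([np.asarray(m.predict(X), dtype=float) for m in models])
    return preds.mean(axis=0), preds.std(axis=0)
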