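"""Feature-selection cascade: combined importance, backward and forward steps.

Three regressor families vote on feature importance across repeated CV
splits: a shrinkage linear model (|coefficient| on z-scored features) and
two gradient-boosted tree flavors (mean |SHAP| on the held-out fold).  Each
method's averaged vector is normalized to sum 1 and the combined index is
their unweighted mean.

Backward elimination removes the least important feature one at a time
(recomputing the combined index every ``refresh_every`` removals) and
records held-out MSE along the trace.  Forward stepwise selection starts
from a seed feature -- by default the conjugation length, the most
important single descriptor -- and greedily adds the candidate with the
largest CV performance gain until the gain falls below tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .featurization import FeatureMatrix
from .interpret import shap_values
from .model_eval import CVProtocol, make_regressor, split

__all__ = [
    "ImportanceReport",
    "SelectionTrace",
    "combined_importance",
    "backward_eliminate",
    "forward_stepwise",
]

#: Lighter tree settings for the inner selection loops; selection needs
#: stable rankings, not final-model precision.
SELECTION_TREE_PARAMS = dict(n_estimators=100, learning_rate=0.1, max_depth=3)


@dataclass
class ImportanceReport:
    """Per-method normalized importances and their combined mean."""

    feature_names: list[str]
    per_method: dict[str, np.ndarray]
    combined: np.ndarray
    n_cv_runs: int

    def ranking(self) -> list[str]:
        order = np.argsort(-self.combined, kind="stable")
        return [self.feature_names[i] for i in order]

    def as_series(self) -> pd.Series:
        return pd.Series(self.combined, index=self.feature_names)


@dataclass
class SelectionTrace:
    """Ordered record of one elimination/addition path."""

    steps: list[dict] = field(default_factory=list)

    def record(self, size: int, feature: str | None, action: str,
               mse_mean: float, mse_sd: float) -> None:
        self.steps.append(
            {"size": size, "feature": feature, "action": action,
             "mse_mean": mse_mean, "mse_sd": mse_sd}
        )

    def features_at(self, size: int) -> list[str] | None:
        for step in self.steps:
            if step["size"] == size:
                return step.get("active")
        return None

    @property
    def selected(self) -> list[str]:
        return list(self.steps[-1]["active"]) if self.steps else []

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _as_df(matrix) -> pd.DataFrame:
    if isinstance(matrix, FeatureMatrix):
        return matrix.df
    if isinstance(matrix, pd.DataFrame):
        return matrix
    arr = np.asarray(matrix, dtype=float)
    return pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])


def _zscore_train(train: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (other - mu) / sd


def combined_importance(
    matrix,
    targets: np.ndarray,
    n_runs: int = 24,
    seed: int = 0,
    protocol: CVProtocol | None = None,
) -> ImportanceReport:
    """Average per-method importances over repeated CV splits and combine.

    Per split: a LASSO on z-scored training features contributes
    |coefficient|; the two boosted-tree models contribute mean |SHAP| over
    the held-out fold.  Method vectors are averaged over runs, normalized
    to sum 1, and combined as an unweighted mean.  A method whose vector
    sums to zero is excluded with a warning.
    """
    df = _as_df(matrix)
    y = np.asarray(targets, dtype=float)
    names = list(df.columns)
    X = df.to_numpy(dtype=float)
    if protocol is None:
        protocol = CVProtocol(n_runs=n_runs, base_seed=seed)

    acc = {m: np.zeros(len(names)) for m in ("lasso", "gbrt", "xgboost")}
    for run in range(protocol.n_runs):
        tr, te = split(len(y), protocol, run)
        run_seed = protocol.base_seed + run

        Xtr_z, Xte_z = _zscore_train(X[tr], X[te])
        lasso = make_regressor("lasso", seed=run_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lasso.fit(Xtr_z, y[tr])
        acc["lasso"] += np.abs(lasso.coef_)

        for method in ("gbrt", "xgboost"):
            model = make_regressor(method, seed=run_seed)
            model.set_params(**SELECTION_TREE_PARAMS)
            model.fit(X[tr], y[tr])
            expl = shap_values(model, pd.DataFrame(X[te], columns=names))
            acc[method] += expl.mean_abs().to_numpy()

    per_method: dict[str, np.ndarray] = {}
    for method, vec in acc.items():
        total = vec.sum()
        if total <= 0:
            warnings.warn(
                f"importance method {method!r} returned an all-zero vector; excluded"
            )
            continue
        per_method[method] = vec / total
    if not per_method:
        raise RuntimeError("all importance methods returned zero vectors")
    combined = np.mean(np.stack(list(per_method.values())), axis=0)
    return ImportanceReport(
        feature_names=names,
        per_method=per_method,
        combined=combined,
        n_cv_runs=protocol.n_runs,
    )


def _cv_mse(df: pd.DataFrame, y: np.ndarray, protocol: CVProtocol) -> tuple[float, float]:
    """Held-out MSE (mean, sd) of the reference boosted regressor."""
    X = df.to_numpy(dtype=float)
    mses = []
    for run in range(protocol.n_runs):
        tr, te = split(len(y), protocol, run)
        model = make_regressor("xgboost", seed=protocol.base_seed + run)
        model.set_params(**SELECTION_TREE_PARAMS)
        model.fit(X[tr], y[tr])
        err = y[te] - model.predict(X[te])
        mses.append(float(np.mean(err**2)))
    return float(np.mean(mses)), float(np.std(mses))


def backward_eliminate(
    matrix,
    targets: np.ndarray,
    refresh_every: int = 10,
    stop_size: int = 1,
    n_runs: int = 24,
    seed: int = 0,
) -> SelectionTrace:
    """Remove the least important feature one at a time down to stop_size.

    The combined importance is recomputed every ``refresh_every`` removals
    (1 = strict one-at-a-time refresh).  Ties on equal importance remove
    the later column (stable order).  Each step records the held-out MSE of
    the reference regressor on the remaining features.
    """
    if stop_size < 1:
        raise ValueError("stop_size must be >= 1")
    df = _as_df(matrix).copy()
    y = np.asarray(targets, dtype=float)
    protocol = CVProtocol(n_runs=n_runs, base_seed=seed)

    trace = SelectionTrace()
    mse, sd = _cv_mse(df, y, protocol)
    step0 = {"size": df.shape[1], "feature": None, "action": "initial",
             "mse_mean": mse, "mse_sd": sd, "active": list(df.columns)}
    trace.steps.append(step0)

    since_refresh = 0
    importance: pd.Series | None = None
    while df.shape[1] > stop_size:
        if importance is None or since_refresh >= refresh_every:
            report = combined_importance(df, y, n_runs=n_runs, seed=seed)
            importance = report.as_series()
            since_refresh = 0
        # later column loses the tie: reverse order, stable argmin on reversed
        current = importance[df.columns]
        min_val = current.min()
        candidates = [c for c in df.columns if current[c] == min_val]
        victim = candidates[-1]
        df = df.drop(columns=[victim])
        importance = importance.drop(victim)
        since_refresh += 1
        mse, sd = _cv_mse(df, y, protocol)
        trace.steps.append(
            {"size": df.shape[1], "feature": victim, "action": "removed",
             "mse_mean": mse, "mse_sd": sd, "active": list(df.columns)}
        )
    return trace


def forward_stepwise(
    matrix,
    targets: np.ndarray,
    seed_features: list[str] | tuple[str, ...] = ("Conju-Max-Distance",),
    candidate_pool: list[str] | None = None,
    tolerance: float = 1e-3,
    n_runs: int = 24,
    seed: int = 0,
    full_matrix_mse: float | None = None,
    max_corr: float | None = None,
) -> SelectionTrace:
    """Greedy forward selection from a seed feature set.

    At each step every candidate is scored by the CV MSE of the reference
    boosted regressor on current + candidate; the best is added while its
    gain exceeds ``tolerance``.  When ``full_matrix_mse`` is given,
    selection also stops once the current MSE is within tolerance of it.

    ``max_corr`` activates a collinearity guard: a candidate whose absolute
    Pearson correlation with any already-selected feature exceeds the
    threshold is skipped.  Redundant near-duplicates of selected features
    add no information but split attribution credit, so pruning them keeps
    the downstream explanation stable.
    """
    df = _as_df(matrix)
    y = np.asarray(targets, dtype=float)
    protocol = CVProtocol(n_runs=n_runs, base_seed=seed)

    missing = [f for f in seed_features if f not in df.columns]
    if missing:
        raise KeyError(f"seed features not in matrix: {missing}")
    current = list(seed_features)
    pool = [
        f for f in (candidate_pool if candidate_pool is not None else df.columns)
        if f not in current
    ]

    trace = SelectionTrace()
    mse, sd = _cv_mse(df[current], y, protocol)
    trace.steps.append(
        {"size": len(current), "feature": None, "action": "seed",
         "mse_mean": mse, "mse_sd": sd, "active": list(current)}
    )
    while pool:
        if full_matrix_mse is not None and mse <= full_matrix_mse + tolerance:
            break
        if max_corr is not None:
            kept = []
            with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                for cand in pool:
                    r = df[current].corrwith(df[cand]).abs().max()
                    if not r > max_corr:  # NaN-safe (constant columns)
                        kept.append(cand)
            pool = kept
            if not pool:
                break
        scores = []
        for cand in pool:
            c_mse, c_sd = _cv_mse(df[current + [cand]], y, protocol)
            scores.append((c_mse, c_sd, cand))
        best_mse, best_sd, best = min(scores, key=lambda t: t[0])
        # 1-SE stability rule: among candidates statistically tied with the
        # best, add the one least correlated with the current set -- a
        # redundant near-tie splits attribution without predictive benefit.
        se = best_sd / np.sqrt(max(protocol.n_runs, 1))
        tied = [(c_mse, cand) for c_mse, _, cand in scores if c_mse <= best_mse + se]
        if len(tied) > 1:
            with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                redundancy = {}
                for _, cand in tied:
                    r = df[current].corrwith(df[cand]).abs().max()
                    redundancy[cand] = 0.0 if pd.isna(r) else float(r)
            best = min(tied, key=lambda t: (redundancy[t[1]], t[0]))[1]
            best_mse, best_sd = next(
                (m, s) for m, s, c in scores if c == best
            )
        if mse - best_mse < tolerance:
            break
        current.append(best)
        pool.remove(best)
        mse, sd = best_mse, best_sd
        trace.steps.append(
            {"size": len(current), "feature": best, "action": "added",
             "mse_mean": mse, "mse_sd": sd, "active": list(current)}
        )
    return trace
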