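"""Model interpretation: SHAP attributions, power-law extraction, ALE.

All attribution here is exact tree-path Shapley: the per-sample, per-feature
contributions phi satisfy ``base_value + sum_f phi_f = prediction`` to
floating-point precision.  Because the model is trained on lg(TPACS), the
SHAP value of a feature lives in lg units, so an ordinary least-squares fit
of phi against the *logarithm* of a feature reads off the exponent of a
power law ``TPACS proportional to feature^b``.

A feature outside the selected set is analyzed by appending its column,
refitting the reference model and reading off the new column's
attributions (add-one-feature protocol).  Accumulated local effects (ALE)
give a SHAP-independent cross-check of a feature's marginal slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._treeshap import tree_shap, trees_from_sklearn
from .featurization import FeatureMatrix
from .model_eval import RegressorSpec, make_regressor

__all__ = [
    "ShapExplanation",
    "PowerLawFit",
    "ALEProfile",
    "shap_values",
    "fit_power_law",
    "add_feature_and_refit",
    "ale_profile",
]


class UnsupportedModelError(TypeError):
    """Exact tree attribution requires a (supported) tree ensemble."""


@dataclass
class ShapExplanation:
    """Per-sample per-feature attributions with the model's base value."""

    base_value: float
    values: pd.DataFrame          # samples x features, lg units
    feature_values: pd.DataFrame  # matching feature values

    def additivity_error(self, predictions: np.ndarray) -> float:
        """Max |base + sum(phi) - prediction| over samples."""
        total = self.base_value + self.values.to_numpy().sum(axis=1)
        return float(np.abs(total - np.asarray(predictions)).max())

    def mean_abs(self) -> pd.Series:
        """Mean |phi| per feature -- the SHAP importance index."""
        return self.values.abs().mean(axis=0)

    def to_csv(self, path) -> None:
        long = self.values.stack().rename("phi").reset_index()
        long.columns = ["sample", "feature", "phi"]
        long["feature_value"] = self.feature_values.stack().to_numpy()
        long.to_csv(path, index=False)


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of SHAP values against lg(feature): exponent of the power law."""

    exponent: float
    intercept: float
    stderr: float
    r2: float
    n: int

    def to_dict(self) -> dict:
        return {
            "exponent": self.exponent,
            "intercept": self.intercept,
            "stderr": self.stderr,
            "r2": self.r2,
            "n": self.n,
        }


@dataclass
class ALEProfile:
    """First-order accumulated local effects on quantile bins."""

    bin_edges: np.ndarray
    local_effects: np.ndarray  # mean local difference per bin
    curve: np.ndarray          # centred cumulative effect at bin edges

    @property
    def slope(self) -> float:
        """Overall least-squares slope of the centred ALE curve."""
        res = stats.linregress(self.bin_edges, self.curve)
        return float(res.slope)


def _as_frame(X, feature_names=None) -> pd.DataFrame:
    if isinstance(X, FeatureMatrix):
        return X.df
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=list(feature_names))


def shap_values(model, X, feature_names=None) -> ShapExplanation:
    """Exact tree-path Shapley attributions for a fitted tree ensemble.

    Supports xgboost regressors (native exact contributions) and sklearn
    decision-tree / random-forest / gradient-boosting regressors (in-package
    TreeSHAP).  Raises :class:`UnsupportedModelError` otherwise.
    """
    df = _as_frame(X, feature_names)
    arr = df.to_numpy(dtype=float)

    from xgboost import XGBRegressor

    if isinstance(model, XGBRegressor):
        import xgboost as xgb

        booster = model.get_booster()
        contribs = booster.predict(xgb.DMatrix(arr), pred_contribs=True)
        phi, base = contribs[:, :-1], float(contribs[0, -1])
    else:
        try:
            trees, offset = trees_from_sklearn(model)
        except TypeError as exc:
            raise UnsupportedModelError(str(exc)) from exc
        phi, base = tree_shap(trees, arr, offset)

    return ShapExplanation(
        base_value=base,
        values=pd.DataFrame(phi, index=df.index, columns=df.columns),
        feature_values=df.copy(),
    )


def fit_power_law(
    explanation: ShapExplanation, feature: str, log_transform: bool = True
) -> PowerLawFit:
    """OLS of a feature's SHAP values on lg(feature value).

    Because phi is in lg(TPACS) units, the slope is the exponent b of
    TPACS ~ feature^b.  Requires strictly positive feature values when
    log-transforming and at least 3 distinct abscissae.
    """
    if feature not in explanation.values.columns:
        raise KeyError(f"feature {feature!r} not in explanation")
    x = explanation.feature_values[feature].to_numpy(dtype=float)
    phi = explanation.values[feature].to_numpy(dtype=float)
    if log_transform:
        if np.any(x <= 0):
            raise ValueError(
                f"log transform requires positive values of {feature!r}"
            )
        x = np.log10(x)
    if len(np.unique(x)) < 3:
        raise ValueError(
            f"degenerate fit: fewer than 3 distinct values of {feature!r}"
        )
    res = stats.linregress(x, phi)
    return PowerLawFit(
        exponent=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
        r2=float(res.rvalue**2),
        n=len(x),
    )


def add_feature_and_refit(
    matrix: FeatureMatrix | pd.DataFrame,
    extra_name: str,
    extra_values: np.ndarray,
    targets: np.ndarray,
    regressor: RegressorSpec | str = "xgboost",
    seed: int = 0,
) -> ShapExplanation:
    """Append a feature column, refit the reference model on all samples,
    and return the SHAP explanation of the widened model.

    The caller reads the extra column of ``.values`` for the added
    feature's attribution.  Raises on a duplicate column name.
    """
    df = matrix.df if isinstance(matrix, FeatureMatrix) else matrix
    if extra_name in df.columns:
        raise ValueError(f"feature {extra_name!r} already present")
    wide = df.copy()
    wide[extra_name] = np.asarray(extra_values, dtype=float)
    model = make_regressor(regressor, seed=seed)
    model.fit(wide.to_numpy(dtype=float), np.asarray(targets, dtype=float))
    return shap_values(model, wide)


def ale_profile(model, X, feature: str, n_bins: int = 20) -> ALEProfile:
    """First-order ALE of one numeric feature on quantile bins.

    Local effects are averaged prediction differences when moving samples
    within a bin from its lower to its upper edge; the accumulated curve is
    centred so its data-weighted mean is zero.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    df = _as_frame(X)
    if feature not in df.columns:
        raise KeyError(f"feature {feature!r} not in matrix")
    x = df[feature].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError(f"feature {feature!r} is constant; ALE undefined")

    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.unique(np.quantile(x, qs))
    k = len(edges) - 1  # effective bins after dropping duplicate quantiles

    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, k - 1)
    local = np.zeros(k)
    counts = np.zeros(k)
    arr = df.to_numpy(dtype=float)
    col = df.columns.get_loc(feature)
    for b in range(k):
        members = np.where(idx == b)[0]
        if members.size == 0:
            continue
        lo = arr[members].copy()
        hi = arr[members].copy()
        lo[:, col] = edges[b]
        hi[:, col] = edges[b + 1]
        diff = model.predict(hi) - model.predict(lo)
        local[b] = float(np.mean(diff))
        counts[b] = members.size

    curve = np.concatenate([[0.0], np.cumsum(local)])
    # centre: data-weighted mean of the bin-midpoint curve values
    mid_vals = 0.5 * (curve[1:] + curve[:-1])
    total = counts.sum()
    centre = float(np.sum(mid_vals * counts) / total) if total else 0.0
    return ALEProfile(bin_edges=edges, local_effects=local, curve=curve - centre)
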