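"""Exact tree attributions, power-law extraction, add-one-refit, ALE."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

from tpascreen._treeshap import tree_shap, trees_from_sklearn
from tpascreen.interpret import (
    ShapExplanation,
    UnsupportedModelError,
    add_feature_and_refit,
    ale_profile,
    fit_power_law,
    shap_values,
)
from tpascreen.synthetic import make_regression_fixture


def brute_force_shapley(trees, x, n_features):
    """Exhaustive-coalition Shapley under the cover-conditioned expectation."""

    def cond_exp(t, node, subset):
        if t.children_left[node] < 0:
            return t.value[node]
        f = t.feature[node]
        left, right = t.children_left[node], t.children_right[node]
        if f in subset:
            nxt = left if x[f] <= t.threshold[node] else right
            return cond_exp(t, nxt, subset)
        return (
            t.cover[left] * cond_exp(t, left, subset)
            + t.cover[right] * cond_exp(t, right, subset)
        ) / t.cover[node]

    phi = np.zeros(n_features)
    others = lambda i: [j for j in range(n_features) if j != i]
    for t in trees:
        for i in range(n_features):
            for k in range(n_features):
                for subset in itertools.combinations(others(i), k):
                    s = set(subset)
                    w = (
                        math.factorial(len(s))
                        * math.factorial(n_features - len(s) - 1)
                        / math.factorial(n_features)
                    )
                    phi[i] += w * (cond_exp(t, 0, s | {i}) - cond_exp(t, 0, s))
    return phi


class TestTreeShapExactness:
    @pytest.mark.parametrize("depth,n_features", [(2, 3), (3, 4), (3, 6)])
    def test_matches_exhaustive_shapley(self, rng, depth, n_features):
        X = rng.normal(size=(150, n_features))
        y = X[:, 0] * 2 + X[:, 1] * X[:, 2] + rng.normal(0, 0.1, 150)
        model = DecisionTreeRegressor(max_depth=depth, random_state=0).fit(X, y)
        trees, offset = trees_from_sklearn(model)
        phi, _ = tree_shap(trees, X[:8], offset)
        for s in range(8):
            expected = brute_force_shapley(trees, X[s], n_features)
            np.testing.assert_allclose(phi[s], expected, atol=1e-9)

    def test_matches_exhaustive_shapley_on_boosted_ensemble(self, rng):
        X = rng.normal(size=(150, 4))
        y = X[:, 0] - 2 * X[:, 3] + rng.normal(0, 0.1, 150)
        model = GradientBoostingRegressor(
            n_estimators=15, max_depth=3, random_state=0
        ).fit(X, y)
        trees, offset = trees_from_sklearn(model)
        phi, _ = tree_shap(trees, X[:5], offset)
        for s in range(5):
            expected = brute_force_shapley(trees, X[s], 4)
            np.testing.assert_allclose(phi[s], expected, atol=1e-9)

    @pytest.mark.parametrize(
        "factory",
        [
            lambda: DecisionTreeRegressor(max_depth=4, random_state=0),
            lambda: RandomForestRegressor(n_estimators=20, random_state=0),
            lambda: GradientBoostingRegressor(n_estimators=40, random_state=0),
        ],
    )
    def test_additivity_for_sklearn_ensembles(self, rng, factory):
        X = rng.normal(size=(200, 5))
        y = X @ np.array([1.0, -0.5, 0.3, 0.0, 2.0]) + rng.normal(0, 0.2, 200)
        model = factory().fit(X, y)
        expl = shap_values(model, X)
        assert expl.additivity_error(model.predict(X)) < 1e-6

    def test_additivity_for_xgboost_single_precision(self, rng):
        X = rng.normal(size=(200, 4))
        y = X[:, 0] * 2 + rng.normal(0, 0.2, 200)
        model = XGBRegressor(
            n_estimators=100, max_depth=4, random_state=0, n_jobs=1
        ).fit(X, y)
        expl = shap_values(model, X)
        # xgboost stores leaves in float32; additivity holds at that precision
        assert expl.additivity_error(model.predict(X)) < 5e-5

    def test_single_feature_model_attributes_everything_to_it(self, rng):
        X = rng.normal(size=(300, 3))
        y = 2.0 * X[:, 0]
        # force the model to only ever see feature 0
        model = DecisionTreeRegressor(max_depth=6, random_state=0).fit(X[:, :1], y)

        trees, offset = trees_from_sklearn(model)
        padded = np.hstack([X[:, :1], np.zeros((300, 0))])
        phi, base = tree_shap(trees, padded, offset)
        pred = model.predict(X[:, :1])
        np.testing.assert_allclose(phi[:, 0], pred - base, atol=1e-9)

    def test_target_translation_shifts_base_not_phi(self, rng):
        X = rng.normal(size=(200, 3))
        y = X[:, 0] + rng.normal(0, 0.1, 200)
        m1 = GradientBoostingRegressor(n_estimators=30, random_state=0).fit(X, y)
        m2 = GradientBoostingRegressor(n_estimators=30, random_state=0).fit(X, y + 5.0)
        e1, e2 = shap_values(m1, X), shap_values(m2, X)
        assert e2.base_value - e1.base_value == pytest.approx(5.0, abs=1e-6)
        np.testing.assert_allclose(e1.values, e2.values, atol=1e-6)

    def test_non_tree_model_rejected(self, rng):
        X = rng.normal(size=(50, 2))
        model = LinearRegression().fit(X, X[:, 0])
        with pytest.raises(UnsupportedModelError):
            shap_values(model, X)


class TestPowerLaw:
    def _explanation(self, L, phi):
        df = pd.DataFrame({"Conju-Max-Distance": L})
        vals = pd.DataFrame({"Conju-Max-Distance": phi})
        return ShapExplanation(base_value=0.0, values=vals, feature_values=df)

    def test_noiseless_line_is_fit_exactly(self):
        L = np.array([3.0, 5.0, 7.0, 9.0, 13.0, 17.0])
        phi = 1.8 * np.log10(L) - 2.0
        fit = fit_power_law(self._explanation(L, phi), "Conju-Max-Distance")
        assert fit.exponent == pytest.approx(1.8, abs=1e-12)
        assert fit.intercept == pytest.approx(-2.0, abs=1e-12)
        assert fit.stderr == pytest.approx(0.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0)

    def test_confidence_interval_covers_planted_slope(self, rng):
        cover = 0
        for trial in range(100):
            L = rng.integers(3, 20, size=400).astype(float)
            phi = 1.8 * np.log10(L) - 1.0 + rng.normal(0, 0.3, 400)
            fit = fit_power_law(self._explanation(L, phi), "Conju-Max-Distance")
            if abs(fit.exponent - 1.8) <= 2 * fit.stderr:
                cover += 1
        assert cover >= 90

    def test_degenerate_abscissa_rejected(self):
        L = np.array([5.0, 5.0, 5.0, 5.0])
        with pytest.raises(ValueError, match="degenerate"):
            fit_power_law(self._explanation(L, L), "Conju-Max-Distance")

    def test_nonpositive_values_rejected_under_log(self):
        L = np.array([0.0, 5.0, 7.0])
        with pytest.raises(ValueError, match="positive"):
            fit_power_law(self._explanation(L, L), "Conju-Max-Distance")


class TestAddFeatureAndRefit:
    def test_duplicated_feature_splits_attribution(self, rng):
        X, y = make_regression_fixture(400, 2, 1, [2.0, 1.0], sigma=0.1, seed=7)
        base_model = GradientBoostingRegressor(n_estimators=80, random_state=0)
        base_model.fit(X.to_numpy(), y)
        base_expl = shap_values(base_model, X)
        twin = add_feature_and_refit(X, "x1_twin", X["x1"].to_numpy(), y, "gbrt", seed=0)
        combined = twin.values["x1"] + twin.values["x1_twin"]
        # the twins jointly carry what x1 carried alone
        assert np.corrcoef(combined, base_expl.values["x1"])[0, 1] > 0.98
        assert combined.abs().mean() == pytest.approx(
            base_expl.values["x1"].abs().mean(), rel=0.15
        )

    def test_pure_noise_extra_feature_gets_negligible_attribution(self, rng):
        n = 3000  # in-sample noise attribution shrinks with sample size
        X, y = make_regression_fixture(n, 2, 0, [1.5, 1.0], sigma=0.3, seed=8)
        noise = rng.normal(size=n)
        expl = add_feature_and_refit(X, "noise", noise, y, "xgboost", seed=0)
        assert expl.values["noise"].abs().mean() < 0.05

    def test_planted_extra_feature_beats_noise_baseline(self, rng):
        n = 3000
        x3 = rng.normal(size=n)
        X, y0 = make_regression_fixture(n, 2, 0, [1.0, 0.5], sigma=0.2, seed=9)
        y = y0 + 0.8 * x3
        noise = rng.normal(size=n)
        causal = add_feature_and_refit(X, "extra", x3, y, "xgboost", seed=0)
        spurious = add_feature_and_refit(X, "extra", noise, y, "xgboost", seed=0)
        # the spurious run has the causal signal unexplained, which inflates
        # what the model hangs on its noise column; 3x still separates them
        assert (
            causal.values["extra"].abs().mean()
            > 3 * spurious.values["extra"].abs().mean()
        )

    def test_duplicate_name_rejected(self):
        X, y = make_regression_fixture(50, 1, 1, [1.0], sigma=0.1, seed=1)
        with pytest.raises(ValueError, match="already present"):
            add_feature_and_refit(X, "x1", X["x1"].to_numpy(), y)


class TestALE:
    def test_linear_model_slope_recovered(self, rng):
        X = pd.DataFrame(rng.normal(size=(800, 3)), columns=["a", "b", "c"])

        class Linear:
            def predict(self, arr):
                return 2.0 * arr[:, 0] + 0.5 * arr[:, 1]

        prof = ale_profile(Linear(), X, "a", n_bins=20)
        assert prof.slope == pytest.approx(2.0, rel=0.05)

    def test_ignored_feature_gives_flat_profile(self, rng):
        X = pd.DataFrame(rng.normal(size=(300, 2)), columns=["a", "b"])

        class OnlyA:
            def predict(self, arr):
                return arr[:, 0]

        prof = ale_profile(OnlyA(), X, "b", n_bins=10)
        assert np.abs(prof.curve).max() < 1e-9

    def test_curve_is_centred(self, rng):
        X, y = make_regression_fixture(500, 2, 1, [1.0, -2.0], sigma=0.2, seed=11)
        model = GradientBoostingRegressor(n_estimators=50, random_state=0)
        model.fit(X.to_numpy(), y)

        class Wrap:
            def predict(self, arr):
                return model.predict(arr)

        prof = ale_profile(Wrap(), X, "x2", n_bins=15)
        # recompute the data-weighted mean the same way the centring does
        idx = np.clip(
            np.searchsorted(prof.bin_edges, X["x2"].to_numpy(), side="right") - 1,
            0, len(prof.bin_edges) - 2,
        )
        mids = 0.5 * (prof.curve[1:] + prof.curve[:-1])
        counts = np.bincount(idx, minlength=len(mids))
        assert np.sum(mids * counts) / counts.sum() == pytest.approx(0.0, abs=1e-9)

    def test_ale_and_shap_slopes_agree_for_additive_model(self, rng):
        X, y = make_regression_fixture(600, 2, 0, [1.7, -0.8], sigma=0.1, seed=12)
        model = GradientBoostingRegressor(n_estimators=150, random_state=0)
        model.fit(X.to_numpy(), y)
        expl = shap_values(model, X)
        shap_slope = np.polyfit(X["x1"], expl.values["x1"], 1)[0]

        class Wrap:
            def predict(self, arr):
                return model.predict(arr)

        ale_slope = ale_profile(Wrap(), X, "x1", n_bins=20).slope
        assert ale_slope == pytest.approx(shap_slope, rel=0.10)

    def test_constant_feature_rejected(self):
        X = pd.DataFrame({"a": np.ones(50), "b": np.arange(50.0)})

        class Any:
            def predict(self, arr):
                return arr[:, 1]

        with pytest.raises(ValueError, match="constant"):
            ale_profile(Any(), X, "a")
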