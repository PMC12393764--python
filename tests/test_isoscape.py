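"""Quantile forest, grouped CV, importances, selection, surfaces."""

import numpy as np
import pandas as pd
import pytest

import sulfurscape as ss
from sulfurscape.isoscape import (ForestConfig, IsoscapeForest, VsurfSelector,
                                  cross_validate, partial_dependence,
                                  predict_surface, train, fit_report)
from sulfurscape.rasters import CovariateStack, RasterGrid


def toy_matrix(n=120, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 10, n)
    z = rng.uniform(0, 10, n)
    y = 2.0 * x + rng.normal(0, noise, n) if noise else 2.0 * x
    return pd.DataFrame({
        "sample_id": [f"i{k}" for k in range(n)],
        "site_id": [f"s{k % 20}" for k in range(n)],
        "d34S": y, "x": x, "z": z})


class TestForestBasics:
    def test_constant_response_degenerates_to_constant(self):
        m = toy_matrix(80)
        m["d34S"] = 7.0
        cfg = ForestConfig(n_trees=50, k_folds=5, repeats=2, seed=1)
        with pytest.warns(UserWarning, match="constant"):
            model = train(m, cfg, predictors=["x", "z"])
        assert model.cv_rmse == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(model.estimator.predict(m[["x", "z"]]), 7.0)
        q = model.estimator.predict_quantiles(m[["x", "z"]].head(5))
        assert np.allclose(q, 7.0)

    def test_noise_free_linear_signal_high_r2(self):
        m = toy_matrix(400, noise=0.0)
        cfg = ForestConfig(n_trees=100, k_folds=10, repeats=2, seed=3)
        cv = cross_validate(m, cfg, predictors=["x", "z"])
        assert cv["r2"] > 0.95

    def test_reproducible_given_seed(self):
        m = toy_matrix(150, noise=1.0)
        cfg = ForestConfig(n_trees=60, k_folds=5, repeats=2, seed=9)
        a = cross_validate(m, cfg, predictors=["x", "z"])
        b = cross_validate(m, cfg, predictors=["x", "z"])
        assert a["rmse"] == b["rmse"] and a["r2"] == b["r2"]

    def test_fewer_rows_than_folds_rejected(self):
        m = toy_matrix(8)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(m, ForestConfig(n_trees=10, k_folds=10),
                           predictors=["x", "z"])


class TestImportance:
    def test_informative_dominates_noise(self):
        m = toy_matrix(250, noise=0.5, seed=4)
        est = IsoscapeForest(n_trees=100, seed=4).fit(m[["x", "z"]], m["d34S"])
        imp = est.permutation_importance()
        by = dict(zip(imp["variable"], imp["importance"]))
        assert by["x"] > 10 * max(by["z"], 1e-9)
        purity = est.node_purity_importance()
        pb = dict(zip(purity["variable"], purity["inc_node_purity"]))
        assert pb["x"] > 10 * pb["z"]

    def test_pure_noise_importance_near_zero(self):
        """%IncMSE of a predictor unrelated to the response stays near 0
        on average over seeded forests (permutation null)."""
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame({"u": rng.normal(size=200),
                              "v": rng.normal(size=200)})
            y = rng.normal(size=200)
            est = IsoscapeForest(n_trees=60, seed=seed).fit(X, y)
            imp = est.permutation_importance()
            vals.append(float(imp.loc[imp.variable == "u", "importance"].iloc[0]))
        assert abs(np.mean(vals)) < 2.0


class TestQuantiles:
    def test_pooled_leaf_quantiles_match_bruteforce(self):
        m = toy_matrix(60, noise=2.0, seed=8)
        est = IsoscapeForest(n_trees=10, seed=8).fit(m[["x", "z"]], m["d34S"])
        Xq = m[["x", "z"]].iloc[:7]
        got = est.predict_quantiles(Xq, (0.17, 0.5, 0.83))
        q_leaves = est.forest_.apply(Xq.to_numpy())
        y = est.y_train_
        for i in range(len(Xq)):
            pooled = []
            for t in range(est.n_trees):
                in_leaf = est.train_leaves_[:, t] == q_leaves[i, t]
                reps = est.bootstrap_counts_[t][in_leaf]
                pooled.extend(np.repeat(y[in_leaf], reps))
            expect = np.quantile(pooled, (0.17, 0.5, 0.83))
            assert np.allclose(got[i], expect)

    def test_wider_quantile_pair_never_narrows_spread(self, fitted_forest,
                                                      screened_matrix):
        preds = [c for c in screened_matrix.columns if c.startswith("r.")]
        X = screened_matrix[preds].iloc[:40]
        inner = fitted_forest.predict_quantiles(X, (0.17, 0.83))
        outer = fitted_forest.predict_quantiles(X, (0.05, 0.95))
        assert np.all(inner[:, 0] <= inner[:, 1])
        assert np.all(outer[:, 1] - outer[:, 0] >= inner[:, 1] - inner[:, 0] - 1e-12)


class TestPartialDependence:
    def test_flat_for_constant_model(self):
        m = toy_matrix(60)
        m["d34S"] = 3.0
        est = IsoscapeForest(n_trees=20, seed=2).fit(m[["x", "z"]], m["d34S"])
        pd_ = partial_dependence(est, "x", np.linspace(0, 10, 5))
        assert np.allclose(pd_["pd"], 3.0)

    def test_step_function_recovered_exactly(self):
        # two flat clusters: every split lands between 4 and 5, so the
        # curve is the closed form of a stump with leaf means 2 and 8
        x = np.repeat(np.arange(10.0), 12)
        y = np.where(x < 5, 2.0, 8.0)
        X = pd.DataFrame({"x": x})
        est = IsoscapeForest(n_trees=30, seed=0).fit(X, y)
        pd_ = partial_dependence(est, "x", [0.0, 2.0, 4.0, 5.0, 7.0, 9.0])
        assert np.allclose(pd_["pd"][:3], 2.0)
        assert np.allclose(pd_["pd"][3:], 8.0)

    def test_unknown_variable_rejected(self):
        m = toy_matrix(40)
        est = IsoscapeForest(n_trees=10, seed=1).fit(m[["x", "z"]], m["d34S"])
        with pytest.raises(KeyError):
            partial_dependence(est, "nope", [1.0])

    def test_elevation_dependence_is_negative_in_default_world(self, fitted_forest):
        pd_ = partial_dependence(fitted_forest, "r.elevation",
                                 np.linspace(0, 1500, 7))
        assert pd_["pd"].iloc[-1] < pd_["pd"].iloc[0]


class TestSelection:
    def test_single_informative_predictor_selected(self):
        m = toy_matrix(200, noise=0.5, seed=6)
        sel = VsurfSelector(n_trees=60, seed=6).fit(m[["x", "z"]], m["d34S"])
        assert sel.selected_vars_[0] == "x"
        assert "z" not in sel.selected_vars_

    def test_all_eliminated_falls_back_to_top_variable(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        y = np.zeros(80)  # nothing is informative: every importance is 0
        with pytest.warns(UserWarning, match="top-importance"):
            sel = VsurfSelector(n_trees=40, n_threshold_reps=4, seed=3).fit(X, y)
        assert len(sel.selected_vars_) == 1

    def test_selector_transform_api(self):
        m = toy_matrix(150, noise=0.5, seed=5)
        sel = VsurfSelector(n_trees=50, seed=5).fit(m[["x", "z"]], m["d34S"])
        out = sel.transform(m[["x", "z"]])
        assert out.shape == (150, len(sel.selected_vars_))


class TestSurfaces:
    def make_stack(self, fitted_forest, screened_matrix, world):
        return world.stack

    def test_pseudo_sd_formula_and_nodata_propagation(self, fitted_forest,
                                                      default_world):
        surf = predict_surface(fitted_forest, default_world.stack)
        land = ~default_world.sea
        ps = surf.pseudo_sd.values[land]
        assert np.all(ps >= 0)
        assert np.allclose(ps, (surf.q83.values[land] - surf.q17.values[land]) / 2)
        assert np.all(surf.q17.values[land] <= surf.q83.values[land])
        # sea cells propagate nodata in every band
        for g in (surf.mean, surf.q17, surf.q83, surf.pseudo_sd):
            assert np.all(g.values[default_world.sea] == g.nodata)

    def test_missing_layer_rejected(self, fitted_forest, default_world):
        partial = CovariateStack({"r.elevation": default_world.stack["r.elevation"]})
        with pytest.raises(KeyError):
            predict_surface(fitted_forest, partial)


class TestFitReport:
    def test_zero_residual_model_flags_nothing(self):
        m = toy_matrix(100)
        m["d34S"] = 5.0
        cfg = ForestConfig(n_trees=30, k_folds=5, repeats=1, seed=2)
        with pytest.warns(UserWarning):
            model = train(m, cfg, predictors=["x", "z"])
        rep = fit_report(model, m)
        assert not rep["flagged"].any()

    def test_shifted_site_is_flagged(self):
        m = toy_matrix(200, noise=0.5, seed=11)
        m.loc[m.site_id == "s3", "d34S"] += 10.0
        cfg = ForestConfig(n_trees=80, k_folds=5, repeats=1, seed=11)
        model = train(m, cfg, predictors=["x", "z"])
        rep = fit_report(model, m)
        assert rep.loc[rep.site_id == "s3", "flagged"].iloc[0]
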