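"""Random-forest δ³⁴S isoscape modelling.

The estimator is a regression forest with quantile-regression-forest
semantics layered on top: every tree remembers the (bootstrap) training
responses in each leaf, so any response quantile can be read off the pooled
in-leaf distribution of a prediction point. The 17th/83rd percentile pair
yields a per-cell pseudo standard deviation, (q83 − q17)/2, which for a
normal distribution coincides with one SD.

Model assessment follows regression-forest convention: repeated k-fold
cross-validation grouped by site (all individuals of a site share a fold,
so spatial pseudo-replication does not leak into the score), out-of-bag
predictions, permutation importance (%IncMSE) and split-impurity importance
(IncNodePurity). Variable selection is a three-step procedure in the VSURF
style: a thresholding step on permutation importance, an interpretation
step keeping the nested model with minimal OOB error, and a prediction step
admitting a variable only when it buys more OOB error than noise would.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import SelectorMixin
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted

from .rasters import CovariateStack, RasterGrid

DEFAULT_SEED = 20250828
RESPONSE_COLUMN = "d34S"
NON_PREDICTOR_COLUMNS = ("sample_id", "site_id", RESPONSE_COLUMN)


@dataclass
class ForestConfig:
    """Training configuration for the isoscape forest.

    ``train_fraction=None`` requests honest repeated k-fold (each fold is
    held out once per repeat); a value in (0, 1) requests repeated grouped
    shuffle splits with that training share instead.
    """

    n_trees: int = 1000
    mtry: int | None = None          # default: floor(p / 3), regression convention
    k_folds: int = 10
    repeats: int = 5
    train_fraction: float | None = None
    seed: int = DEFAULT_SEED
    metric: str = "rmse"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.train_fraction is not None and not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")


def _weighted_pooled_quantiles(values: np.ndarray, weights: np.ndarray,
                               qs: np.ndarray) -> np.ndarray:
    """Quantiles of the multiset where values[i] occurs weights[i] times.

    Reproduces ``np.quantile`` (linear interpolation) on the expanded
    multiset without materialising it. ``weights`` are non-negative
    integers with a positive sum.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    keep = w > 0
    v, w = v[keep], w[keep]
    cum = np.cumsum(w)
    total = cum[-1]

    def order_stat(k: np.ndarray) -> np.ndarray:
        return v[np.searchsorted(cum, k, side="right")]

    pos = qs * (total - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, total - 1).astype(int)
    frac = pos - lo
    return order_stat(lo) * (1 - frac) + order_stat(hi) * frac


class IsoscapeForest(RegressorMixin, BaseEstimator):
    """Regression forest with pooled-leaf quantiles and OOB importances.

    Parameters
    ----------
    n_trees : number of bootstrap trees.
    mtry : predictors drawn at each split; default ``max(1, p // 3)``.
    min_samples_leaf : minimal leaf size (regression forests conventionally
        use 5; leaves of several responses also give the in-leaf quantile
        distribution something to work with).
    seed : random state for bootstrap and split draws.

    Fitted attributes (trailing underscore) include the per-row
    ``oob_prediction_`` and the per-tree bootstrap bookkeeping the quantile
    and importance machinery needs.
    """

    def __init__(self, n_trees: int = 1000, mtry: int | None = None,
                 min_samples_leaf: int = 5, seed: int = DEFAULT_SEED):
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_samples_leaf = min_samples_leaf
        self.seed = seed

    # -- core fit / predict ------------------------------------------------

    def _as_array(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if hasattr(self, "feature_names_in_"):
                X = X[list(self.feature_names_in_)]
            return X.to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        Xa = self._as_array(X)
        ya = np.asarray(y, dtype=float)
        if Xa.ndim != 2 or Xa.shape[0] != ya.shape[0]:
            raise ValueError("X and y have incompatible shapes")
        if Xa.shape[0] < 2:
            raise ValueError("need at least 2 training rows")
        p = Xa.shape[1]
        mtry = self.mtry if self.mtry is not None else max(1, p // 3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # sparse-OOB warning
            self.forest_ = RandomForestRegressor(
                n_estimators=self.n_trees,
                max_features=min(mtry, p),
                min_samples_leaf=self.min_samples_leaf,
                bootstrap=True,
                oob_score=True,
                random_state=self.seed,
                n_jobs=1,
            ).fit(Xa, ya)
        self.n_features_in_ = p
        self.X_train_ = Xa
        self.y_train_ = ya
        n = Xa.shape[0]
        # bootstrap multiplicity of each training row in each tree
        counts = np.zeros((self.n_trees, n), dtype=np.int32)
        for t, idx in enumerate(self.forest_.estimators_samples_):
            counts[t] = np.bincount(idx, minlength=n)
        self.bootstrap_counts_ = counts
        self.train_leaves_ = self.forest_.apply(Xa)  # (n, trees)
        self.oob_prediction_ = self._oob_prediction()
        return self

    def _oob_prediction(self) -> np.ndarray:
        n = self.X_train_.shape[0]
        pred_sum = np.zeros(n)
        pred_n = np.zeros(n)
        for t, tree in enumerate(self.forest_.estimators_):
            oob = self.bootstrap_counts_[t] == 0
            if not oob.any():
                continue
            pred_sum[oob] += tree.predict(self.X_train_[oob])
            pred_n[oob] += 1
        with np.errstate(invalid="ignore"):
            out = pred_sum / pred_n
        # rows in every bootstrap sample fall back to the ensemble mean
        missing = pred_n == 0
        if missing.any():
            out[missing] = self.forest_.predict(self.X_train_[missing])
        return out

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict(self._as_array(X))

    # -- quantile-forest machinery ----------------------------------------

    def _pooled_weights(self, Xa: np.ndarray) -> np.ndarray:
        """(m, n_train) integer weights: how often training row j shares a
        leaf (counted with bootstrap multiplicity) with query row i,
        summed over trees."""
        m = Xa.shape[0]
        n = self.X_train_.shape[0]
        W = np.zeros((m, n), dtype=np.int64)
        q_leaves = self.forest_.apply(Xa)  # (m, trees)
        for t in range(self.n_trees):
            train_lv = self.train_leaves_[:, t]
            cnt = self.bootstrap_counts_[t]
            order = np.argsort(train_lv, kind="stable")
            sorted_lv = train_lv[order]
            ql = q_leaves[:, t]
            uniq, inverse = np.unique(ql, return_inverse=True)
            starts = np.searchsorted(sorted_lv, uniq, side="left")
            stops = np.searchsorted(sorted_lv, uniq, side="right")
            for u in range(uniq.size):
                rows = np.flatnonzero(inverse == u)
                cols = order[starts[u]:stops[u]]
                W[np.ix_(rows, cols)] += cnt[cols]
        return W

    def predict_quantiles(self, X, quantiles=(0.17, 0.83)) -> np.ndarray:
        """Per-row quantiles of the pooled in-leaf training responses."""
        check_is_fitted(self, "forest_")
        Xa = self._as_array(X)
        qs = np.asarray(quantiles, dtype=float)
        W = self._pooled_weights(Xa)
        out = np.empty((Xa.shape[0], qs.size))
        for i in range(Xa.shape[0]):
            out[i] = _weighted_pooled_quantiles(self.y_train_, W[i], qs)
        return out

    # -- importances -------------------------------------------------------

    def permutation_importance(self, normalize: str = "percent",
                               seed: int | None = None) -> pd.DataFrame:
        """OOB permutation importance per predictor.

        ``normalize="percent"`` gives %IncMSE as
        100·(MSE_perm − MSE_oob)/MSE_oob averaged over trees;
        ``normalize="sd"`` gives the classical mean raw decrease divided by
        its per-tree standard error; ``normalize="raw"`` the plain mean
        decrease. Also returns the per-tree SD of the raw decrease.
        """
        check_is_fitted(self, "forest_")
        rng = np.random.default_rng(self.seed if seed is None else seed)
        p = self.X_train_.shape[1]
        raw = np.full((self.n_trees, p), np.nan)
        pct = np.full((self.n_trees, p), np.nan)
        for t, tree in enumerate(self.forest_.estimators_):
            oob = self.bootstrap_counts_[t] == 0
            if oob.sum() < 2:
                continue
            Xo = self.X_train_[oob]
            yo = self.y_train_[oob]
            base = np.mean((tree.predict(Xo) - yo) ** 2)
            for j in range(p):
                Xp = Xo.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                mse = np.mean((tree.predict(Xp) - yo) ** 2)
                raw[t, j] = mse - base
                pct[t, j] = 100.0 * (mse - base) / base if base > 0 else 0.0
        mean_raw = np.nanmean(raw, axis=0)
        sd_raw = np.nanstd(raw, axis=0, ddof=1)
        n_eff = np.sum(np.isfinite(raw), axis=0)
        if normalize == "percent":
            value = np.nanmean(pct, axis=0)
        elif normalize == "sd":
            se = sd_raw / np.sqrt(np.maximum(n_eff, 1))
            value = np.divide(mean_raw, se, out=np.zeros_like(mean_raw), where=se > 0)
        elif normalize == "raw":
            value = mean_raw
        else:
            raise ValueError(f"unknown normalize {normalize!r}")
        names = getattr(self, "feature_names_in_",
                        np.array([f"x{j}" for j in range(p)], dtype=object))
        return pd.DataFrame({"variable": names, "importance": value,
                             "raw_mean": mean_raw, "raw_sd": sd_raw})

    def node_purity_importance(self) -> pd.DataFrame:
        """Split-impurity importance: total decrease in node sum-of-squares
        attributable to splits on each variable, averaged over trees."""
        check_is_fitted(self, "forest_")
        p = self.X_train_.shape[1]
        total = np.zeros(p)
        for tree in self.forest_.estimators_:
            t = tree.tree_
            internal = t.children_left != -1
            left, right = t.children_left[internal], t.children_right[internal]
            dec = (t.weighted_n_node_samples[internal] * t.impurity[internal]
                   - t.weighted_n_node_samples[left] * t.impurity[left]
                   - t.weighted_n_node_samples[right] * t.impurity[right])
            np.add.at(total, t.feature[internal], dec)
        names = getattr(self, "feature_names_in_",
                        np.array([f"x{j}" for j in range(p)], dtype=object))
        return pd.DataFrame({"variable": names,
                             "inc_node_purity": total / self.n_trees})


# ---------------------------------------------------------------------------
# Cross-validation grouped by site
# ---------------------------------------------------------------------------

def _grouped_folds(groups: np.ndarray, k: int, rng: np.random.Generator):
    """Partition the unique groups into k folds; yields boolean test masks."""
    uniq = np.unique(groups)
    perm = rng.permutation(uniq)
    for part in np.array_split(perm, k):
        yield np.isin(groups, part)


def cross_validate(matrix: pd.DataFrame, config: ForestConfig,
                   predictors: list[str] | None = None) -> dict:
    """Repeated site-grouped cross-validation; returns pooled RMSE and R².

    Per repeat, out-of-fold predictions are pooled over folds before the
    metrics are computed; the reported numbers are means over repeats.
    """
    predictors = predictors or [c for c in matrix.columns
                                if c not in NON_PREDICTOR_COLUMNS]
    X = matrix[predictors]
    y = matrix[RESPONSE_COLUMN].to_numpy(dtype=float)
    groups = matrix["site_id"].to_numpy()
    n_groups = np.unique(groups).size
    k = min(config.k_folds, n_groups)
    if len(matrix) < config.k_folds:
        raise ValueError("fewer rows than folds")
    rng = np.random.default_rng(config.seed)
    rmses, r2s, records = [], [], []
    for rep in range(config.repeats):
        if config.train_fraction is None:
            test_masks = list(_grouped_folds(groups, k, rng))
        else:
            uniq = np.unique(groups)
            n_test = max(1, int(round((1 - config.train_fraction) * uniq.size)))
            test_masks = []
            for _ in range(k):
                held = rng.choice(uniq, size=n_test, replace=False)
                test_masks.append(np.isin(groups, held))
        pred = np.full(len(y), np.nan)
        for mask in test_masks:
            if mask.all() or not mask.any():
                continue
            est = IsoscapeForest(n_trees=config.n_trees, mtry=config.mtry,
                                 seed=int(rng.integers(2**31 - 1)))
            est.fit(X[~mask], y[~mask])
            pred[mask] = est.predict(X[mask])
        have = np.isfinite(pred)
        resid = y[have] - pred[have]
        rmse = float(np.sqrt(np.mean(resid**2)))
        ss_tot = float(np.sum((y[have] - y[have].mean()) ** 2))
        r2 = float(1 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
        rmses.append(rmse)
        r2s.append(r2)
        records.append({"repeat": rep, "rmse": rmse, "r2": r2})
    return {"rmse": float(np.mean(rmses)), "r2": float(np.mean(r2s)),
            "per_repeat": pd.DataFrame(records), "fold_unit": "site"}


@dataclass
class IsoscapeModel:
    """A trained isoscape forest with its assessment bundle."""

    estimator: IsoscapeForest
    selected_vars: list[str]
    cv_rmse: float
    cv_r2: float
    importance: pd.DataFrame
    oob_predictions: np.ndarray
    config: ForestConfig = field(default_factory=ForestConfig)


def train(matrix: pd.DataFrame, config: ForestConfig | None = None,
          predictors: list[str] | None = None) -> IsoscapeModel:
    """Fit the isoscape forest and assess it by repeated grouped CV."""
    config = config or ForestConfig()
    predictors = predictors or [c for c in matrix.columns
                                if c not in NON_PREDICTOR_COLUMNS]
    y = matrix[RESPONSE_COLUMN].to_numpy(dtype=float)
    if np.unique(y).size < 2:
        warnings.warn("constant response; model degenerates to the mean", stacklevel=2)
    cv = cross_validate(matrix, config, predictors)
    est = IsoscapeForest(n_trees=config.n_trees, mtry=config.mtry,
                         seed=config.seed)
    est.fit(matrix[predictors], y)
    imp = est.permutation_importance().merge(est.node_purity_importance(),
                                             on="variable")
    return IsoscapeModel(estimator=est, selected_vars=list(predictors),
                         cv_rmse=cv["rmse"], cv_r2=cv["r2"], importance=imp,
                         oob_predictions=est.oob_prediction_, config=config)


def importance(model: IsoscapeModel) -> pd.DataFrame:
    """Per-variable %IncMSE and IncNodePurity of a trained model."""
    return model.importance.rename(columns={"importance": "pct_inc_mse"})


# ---------------------------------------------------------------------------
# Three-step variable selection
# ---------------------------------------------------------------------------

class VsurfSelector(SelectorMixin, BaseEstimator):
    """Three-step random-forest variable selection.

    Step 1 (thresholding): rank variables by mean OOB permutation
    importance over ``n_threshold_reps`` seeded forests; a CART fit to the
    rank-ordered importance standard deviations supplies a data-driven
    threshold, below which variables are dropped (negative-importance
    variables always are).

    Step 2 (interpretation): grow nested models in rank order and keep the
    one with minimal mean OOB error (ties favour fewer variables).

    Step 3 (prediction): re-add variables stepwise, retaining one only if
    it lowers OOB error by more than the mean error fluctuation observed
    among the step-2 models beyond the optimum — the "noise jump".
    """

    def __init__(self, n_trees: int = 100, n_threshold_reps: int = 8,
                 n_nested_reps: int = 3, seed: int = DEFAULT_SEED):
        self.n_trees = n_trees
        self.n_threshold_reps = n_threshold_reps
        self.n_nested_reps = n_nested_reps
        self.seed = seed

    def _oob_mse(self, X: np.ndarray, y: np.ndarray, seed: int) -> float:
        est = IsoscapeForest(n_trees=self.n_trees, seed=seed).fit(X, y)
        return float(np.mean((est.oob_prediction_ - y) ** 2))

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            self.feature_names_in_ = np.array([f"x{j}" for j in range(Xa.shape[1])],
                                              dtype=object)
        ya = np.asarray(y, dtype=float)
        n, p = Xa.shape
        if p < 1:
            raise ValueError("need at least one predictor")
        rng = np.random.default_rng(self.seed)

        # --- step 1: thresholding on permutation importance ---------------
        vi = np.zeros((self.n_threshold_reps, p))
        for r in range(self.n_threshold_reps):
            est = IsoscapeForest(n_trees=self.n_trees,
                                 seed=int(rng.integers(2**31 - 1))).fit(Xa, ya)
            vi[r] = est.permutation_importance(
                normalize="raw", seed=int(rng.integers(2**31 - 1)))["raw_mean"]
        vi_mean = vi.mean(axis=0)
        vi_sd = vi.std(axis=0, ddof=1) if self.n_threshold_reps > 1 else np.zeros(p)
        order = np.argsort(-vi_mean, kind="stable")
        self.ranking_ = self.feature_names_in_[order]
        self.vi_mean_ = vi_mean[order]
        self.vi_sd_ = vi_sd[order]
        if p >= 2:
            cart = DecisionTreeRegressor(min_samples_leaf=max(2, p // 10),
                                         random_state=0)
            cart.fit(np.arange(p).reshape(-1, 1), self.vi_sd_)
            self.threshold_ = float(cart.predict(np.arange(p).reshape(-1, 1)).min())
        else:
            self.threshold_ = 0.0
        keep1 = (self.vi_mean_ > self.threshold_) & (self.vi_mean_ > 0)
        if not keep1.any():
            warnings.warn("thresholding eliminated every variable; "
                          "keeping the top-importance one", stacklevel=2)
            keep1[0] = True
        step1_vars = [v for v, k in zip(self.ranking_, keep1) if k]
        col_of = {v: i for i, v in enumerate(self.feature_names_in_)}

        # --- step 2: interpretation (minimal-OOB nested model) ------------
        # every nested model is scored with the same replicate seeds, so
        # successive differences are paired and forest-construction noise
        # largely cancels out of the error jumps
        rep_seeds = [int(rng.integers(2**31 - 1)) for _ in range(self.n_nested_reps)]

        def nested_err(cols):
            return float(np.mean([self._oob_mse(Xa[:, cols], ya, s)
                                  for s in rep_seeds]))

        errs = []
        for j in range(1, len(step1_vars) + 1):
            errs.append(nested_err([col_of[v] for v in step1_vars[:j]]))
        self.nested_errors_ = np.asarray(errs)
        j_star = int(np.argmin(self.nested_errors_)) + 1
        self.interp_vars_ = step1_vars[:j_star]

        # --- step 3: prediction (stepwise with noise-jump threshold) ------
        # The jump threshold is the mean OOB-error fluctuation caused by
        # adding variables that carry no signal. Preferred estimate: extend
        # the nested sequence with the top-ranked variables *eliminated* at
        # step 1 (noise by that step's judgement); fall back to the noise
        # tail of the step-2 sequence, then to the replicate spread.
        eliminated = [v for v, k in zip(self.ranking_, keep1) if not k]
        noise_errs = [self.nested_errors_[-1]]
        cols_ext = [col_of[v] for v in step1_vars]
        for v in eliminated[:3]:
            cols_ext = cols_ext + [col_of[v]]
            noise_errs.append(nested_err(cols_ext))
        noise_jumps = np.abs(np.diff(noise_errs))
        tail = np.abs(np.diff(self.nested_errors_[j_star - 1:]))
        if noise_jumps.size:
            jump = float(np.mean(noise_jumps))
        elif tail.size:
            jump = float(np.mean(tail))
        else:
            jump = 0.0
        self.noise_jump_ = jump
        selected = [self.interp_vars_[0]]
        cols = [col_of[selected[0]]]
        current = nested_err(cols)
        for v in self.interp_vars_[1:]:
            trial_cols = cols + [col_of[v]]
            e = nested_err(trial_cols)
            if current - e > jump:
                selected.append(v)
                cols = trial_cols
                current = e
        self.selected_vars_ = selected
        self.support_ = np.isin(self.feature_names_in_, selected)
        self.n_features_in_ = p
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_


def select_variables(matrix: pd.DataFrame, config: ForestConfig | None = None,
                     predictors: list[str] | None = None, **kwargs) -> list[str]:
    """Ordered selected-variable list from the three-step procedure."""
    config = config or ForestConfig()
    predictors = predictors or [c for c in matrix.columns
                                if c not in NON_PREDICTOR_COLUMNS]
    sel = VsurfSelector(seed=config.seed, **kwargs)
    sel.fit(matrix[predictors], matrix[RESPONSE_COLUMN].to_numpy(dtype=float))
    return list(sel.selected_vars_)


# ---------------------------------------------------------------------------
# Partial dependence, surfaces, fit report
# ---------------------------------------------------------------------------

def partial_dependence(model: IsoscapeModel | IsoscapeForest, variable: str,
                       grid_values) -> pd.DataFrame:
    """PD(v): mean prediction over training rows with ``variable`` set to v."""
    est = model.estimator if isinstance(model, IsoscapeModel) else model
    names = list(getattr(est, "feature_names_in_", []))
    if variable not in names:
        raise KeyError(f"variable {variable!r} not in model")
    j = names.index(variable)
    out = []
    for v in np.asarray(grid_values, dtype=float):
        X = est.X_train_.copy()
        X[:, j] = v
        out.append(float(est.forest_.predict(X).mean()))
    return pd.DataFrame({variable: np.asarray(grid_values, dtype=float),
                         "pd": out})


@dataclass
class IsoscapeSurface:
    """Mean, 17th/83rd-percentile and pseudo-SD prediction rasters."""

    mean: RasterGrid
    q17: RasterGrid
    q83: RasterGrid
    pseudo_sd: RasterGrid


def predict_surface(model: IsoscapeModel | IsoscapeForest, stack: CovariateStack,
                    quantiles: tuple[float, float] = (0.17, 0.83)) -> IsoscapeSurface:
    """Predict the isoscape over a covariate stack.

    Cells where any required layer is nodata propagate nodata to every
    output band; pseudo_sd = (upper − lower)/2.
    """
    est = model.estimator if isinstance(model, IsoscapeModel) else model
    names = list(est.feature_names_in_)
    for v in names:
        if v not in stack:
            raise KeyError(f"stack lacks layer {v!r}")
    grid = stack.grid
    valid = np.ones(grid.shape, dtype=bool)
    for v in names:
        valid &= stack[v].valid_mask()
    X = np.column_stack([stack[v].values[valid] for v in names])
    lo, hi = sorted(quantiles)
    mean_v = est.forest_.predict(X)
    qv = est.predict_quantiles(pd.DataFrame(X, columns=names), (lo, hi))

    def to_grid(vec: np.ndarray) -> RasterGrid:
        out = np.full(grid.shape, grid.nodata)
        out[valid] = vec
        return grid.copy_with(out)

    return IsoscapeSurface(
        mean=to_grid(mean_v),
        q17=to_grid(qv[:, 0]),
        q83=to_grid(qv[:, 1]),
        pseudo_sd=to_grid((qv[:, 1] - qv[:, 0]) / 2.0),
    )


def fit_report(model: IsoscapeModel, matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-site observed vs OOB-predicted δ³⁴S with outlier flags.

    A site is flagged when its mean OOB residual falls outside the central
    95% interval (2.5th–97.5th percentiles, inclusive) of the per-row OOB
    residual distribution.
    """
    obs = matrix[RESPONSE_COLUMN].to_numpy(dtype=float)
    resid = obs - model.oob_predictions
    lo, hi = np.percentile(resid, [2.5, 97.5])
    df = pd.DataFrame({"site_id": matrix["site_id"], "observed": obs,
                       "predicted": model.oob_predictions, "residual": resid})
    per_site = df.groupby("site_id").agg(
        n=("observed", "size"),
        observed_mean=("observed", "mean"),
        predicted_mean=("predicted", "mean"),
        residual_mean=("residual", "mean"),
    ).reset_index()
    per_site["flagged"] = (per_site["residual_mean"] < lo) | (per_site["residual_mean"] > hi)
    return per_site
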