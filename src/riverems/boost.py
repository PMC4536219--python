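"""Boosted regression trees with stage-wise CV tree selection.

The model is classic stochastic gradient boosting of shallow regression
trees: each stage fits a tree with a fixed number of splits to the loss
gradient on a random row subsample (the bag fraction) and adds it with a
small shrinkage (learning rate). Poisson loss (log link, Newton leaf
updates) serves count responses such as site richness; Gaussian loss
serves continuous responses such as ordination axis scores.

The number of trees is selected the way the classic ecology workflow
does it: models for every CV fold are grown in lock-step, the held-out
deviance is averaged after every step of ``step_size`` trees, and the
tree count minimising that curve is kept. Performance is reported as
percent deviance explained, 100·(null − residual)/null, on the training
data and cross-validated, plus the CV correlation between observed and
predicted values.

Per-variable relative influence apportions the total squared-error
reduction across all splits to the split variables and rescales to
percentages summing to 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "BRTConfig",
    "BRTEvaluation",
    "BoostedTreesRegressor",
    "select_n_trees_cv",
    "relative_influence",
    "deviance",
    "assemble_predictors",
]

_LEAF_CLIP = 4.0  # cap on Poisson Newton leaf steps, for numerical safety


@dataclass
class BRTConfig:
    """Fitting recipe for a boosted-regression-tree model."""

    loss: str = "gaussian"  # or "poisson"
    learning_rate: float = 0.001
    tree_complexity: int = 5  # splits per tree
    bag_fraction: float = 0.5
    n_folds: int = 10
    step_size: int = 50
    max_trees: int = 10000
    min_trees: int = 1000  # floor below which a slower learning rate is advised
    patience_steps: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if not 0 < self.bag_fraction <= 1:
            raise ValueError("bag_fraction must be in (0, 1]")
        if self.tree_complexity < 1:
            raise ValueError("tree_complexity must be >= 1")
        if self.loss not in ("gaussian", "poisson"):
            raise ValueError("loss must be 'gaussian' or 'poisson'")


@dataclass
class BRTEvaluation:
    """Model performance in the conventional reporting format."""

    n_trees: int
    training_deviance_explained: float  # percent
    training_correlation: float
    cv_deviance_explained: float  # percent
    cv_correlation: float
    cv_correlation_se: float
    mean_null_deviance: float
    mean_cv_residual_deviance: float
    cv_residual_deviance_se: float

    def as_row(self) -> dict:
        return {
            "n_trees": self.n_trees,
            "train_pct_dev_explained": self.training_deviance_explained,
            "train_correlation": self.training_correlation,
            "mean_null_deviance": self.mean_null_deviance,
            "mean_cv_residual_deviance": self.mean_cv_residual_deviance,
            "cv_residual_deviance_se": self.cv_residual_deviance_se,
            "cv_pct_dev_explained": self.cv_deviance_explained,
            "cv_correlation": self.cv_correlation,
            "cv_correlation_se": self.cv_correlation_se,
        }


def deviance(y, mu, loss: str) -> float:
    """Mean deviance of predictions ``mu`` for observations ``y``.

    Gaussian: mean squared error. Poisson: mean of
    ``2·[y·log(y/mu) − (y − mu)]`` with the ``y = 0`` term of the log set
    to zero; requires strictly positive ``mu``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if loss == "gaussian":
        return float(np.mean((y - mu) ** 2))
    if loss == "poisson":
        if np.any(mu <= 0):
            raise ValueError("Poisson deviance requires positive predictions")
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
        return float(np.mean(2.0 * (term - (y - mu))))
    raise ValueError("loss must be 'gaussian' or 'poisson'")


class BoostedTreesRegressor(BaseEstimator, RegressorMixin):
    """Stochastic gradient boosting of fixed-size regression trees.

    Parameters mirror the classic ecology defaults: 0.001 learning rate,
    trees with 5 splits, bag fraction 0.5.

    Attributes
    ----------
    trees_ : list of fitted DecisionTreeRegressor
    init_ : float
        Baseline prediction on the link scale (mean for Gaussian, log
        mean for Poisson).
    train_deviance_path_ : list of float
        Training deviance after each stage.
    """

    def __init__(
        self,
        loss: str = "gaussian",
        n_trees: int = 1000,
        learning_rate: float = 0.001,
        tree_complexity: int = 5,
        bag_fraction: float = 0.5,
        random_state: int = 0,
    ):
        self.loss = loss
        self.n_trees = n_trees
        self.learning_rate = learning_rate
        self.tree_complexity = tree_complexity
        self.bag_fraction = bag_fraction
        self.random_state = random_state

    # -- internals -----------------------------------------------------------

    def _start(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D and aligned with y")
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("missing values are not supported")
        if self.loss == "poisson":
            if np.any(y < 0) or np.any(np.mod(y, 1) != 0):
                raise ValueError("Poisson loss needs non-negative integer responses")
            self.init_ = float(np.log(max(y.mean(), 1e-12)))
        elif self.loss == "gaussian":
            self.init_ = float(y.mean())
        else:
            raise ValueError("loss must be 'gaussian' or 'poisson'")
        self._X, self._y = X, y
        self._link = np.full(len(y), self.init_)
        self._rng = np.random.default_rng(self.random_state)
        self.trees_ = []
        self.train_deviance_path_ = []
        self.n_features_in_ = X.shape[1]

    def _mu(self, link):
        return np.exp(link) if self.loss == "poisson" else link

    def _grow(self, n_stages: int):
        X, y = self._X, self._y
        n = len(y)
        n_bag = max(2, int(round(self.bag_fraction * n)))
        for _ in range(n_stages):
            mu = self._mu(self._link)
            grad = y - mu  # negative gradient for both losses (working residual)
            idx = self._rng.choice(n, size=n_bag, replace=False)
            tree = DecisionTreeRegressor(
                max_leaf_nodes=self.tree_complexity + 1,
                random_state=0,
            )
            tree.fit(X[idx], grad[idx])
            if self.loss == "poisson":
                self._newton_leaves(tree, X[idx], y[idx], mu[idx])
            self._link += self.learning_rate * tree.predict(X)
            self.trees_.append(tree)
            self.train_deviance_path_.append(deviance(y, self._mu(self._link), self.loss))

    @staticmethod
    def _newton_leaves(tree, Xb, yb, mub):
        """Replace leaf values with the Poisson Newton step log(Σy/Σμ)."""
        leaves = tree.apply(Xb)
        t = tree.tree_
        is_leaf = t.children_left == -1
        for node in np.flatnonzero(is_leaf):
            mask = leaves == node
            if not mask.any():
                t.value[node, 0, 0] = 0.0
                continue
            num, den = yb[mask].sum(), mub[mask].sum()
            step = np.log((num + 1e-12) / (den + 1e-12))
            t.value[node, 0, 0] = float(np.clip(step, -_LEAF_CLIP, _LEAF_CLIP))

    # -- sklearn API ---------------------------------------------------------

    def fit(self, X, y):
        self.feature_names_in_ = (
            np.asarray(X.columns) if isinstance(X, pd.DataFrame) else None
        )
        self._start(X, y)
        self._grow(self.n_trees)
        return self

    def predict_link(self, X) -> np.ndarray:
        check_is_fitted(self, "trees_")
        X = np.asarray(X, dtype=float)
        out = np.full(len(X), self.init_)
        for tree in self.trees_:
            out += self.learning_rate * tree.predict(X)
        return out

    def predict(self, X) -> np.ndarray:
        return self._mu(self.predict_link(X))

    @property
    def feature_importances_(self) -> np.ndarray:
        """Per-feature fraction of total split-improvement (sums to 1)."""
        check_is_fitted(self, "trees_")
        total = np.zeros(self.n_features_in_)
        for tree in self.trees_:
            total += tree.tree_.compute_feature_importances(normalize=False)
        s = total.sum()
        return total / s if s > 0 else total


def relative_influence(
    model: BoostedTreesRegressor,
    feature_names=None,
    categories: dict | None = None,
) -> pd.DataFrame:
    """Percent relative influence per predictor (and per category).

    Influence is the share of the total loss reduction attributable to
    splits on each variable, scaled to sum to 100. ``categories`` maps
    variable name → category label (physical / land use / chemical /
    spatial); when given, a ``category`` column is attached.
    """
    if feature_names is None:
        feature_names = model.feature_names_in_
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(model.n_features_in_)]
    pct = 100.0 * model.feature_importances_
    out = pd.DataFrame({"variable": list(feature_names), "influence": pct})
    out = out.sort_values("influence", ascending=False, ignore_index=True)
    if categories is not None:
        out["category"] = out["variable"].map(categories)
    return out


def _fold_assignment(y, config: BRTConfig) -> np.ndarray:
    """Seeded fold labels; stratified by response tertile for Poisson."""
    n = len(y)
    rng = np.random.default_rng(config.seed + 1)
    folds = np.empty(n, dtype=int)
    if config.loss == "poisson":
        order = np.argsort(np.asarray(y, float) + rng.uniform(0, 1e-9, n))
        strata = np.array_split(order, 3)
    else:
        strata = [np.arange(n)]
    for stratum in strata:
        stratum = np.array(stratum)
        rng.shuffle(stratum)
        for i, idx in enumerate(stratum):
            folds[idx] = i % config.n_folds
    return folds


def select_n_trees_cv(X, y, config: BRTConfig):
    """Stage-wise 10-fold CV selection of the optimal tree count.

    Grows one model per fold (plus the full-data model) in steps of
    ``config.step_size`` trees, tracking held-out deviance; stops once
    the CV curve has not improved for ``patience_steps`` consecutive
    steps (or at ``max_trees``) and keeps the minimising count.

    Returns ``(n_trees, BRTEvaluation, model)`` where ``model`` is the
    full-data model truncated to the selected number of trees.
    """
    feature_names = np.asarray(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < config.n_folds:
        raise ValueError("need at least n_folds observations")
    folds = _fold_assignment(y, config)

    def make(seed):
        return BoostedTreesRegressor(
            loss=config.loss,
            n_trees=0,
            learning_rate=config.learning_rate,
            tree_complexity=config.tree_complexity,
            bag_fraction=config.bag_fraction,
            random_state=seed,
        )

    fold_models, holdouts = [], []
    for f in range(config.n_folds):
        tr, te = folds != f, folds == f
        mdl = make(config.seed + 100 + f)
        mdl._start(X[tr], y[tr])
        fold_models.append(mdl)
        holdouts.append((X[te], y[te]))

    full = make(config.seed)
    full.feature_names_in_ = feature_names
    full._start(X, y)

    cv_curve = []  # mean held-out deviance after each step
    best, best_step, steps = np.inf, 0, 0
    while steps * config.step_size < config.max_trees:
        steps += 1
        for mdl in fold_models:
            mdl._grow(config.step_size)
        full._grow(config.step_size)
        dev = np.mean(
            [
                deviance(yt, m._mu(m.predict_link(Xt)), config.loss)
                for m, (Xt, yt) in zip(fold_models, holdouts)
            ]
        )
        cv_curve.append(dev)
        if dev < best:
            best, best_step = dev, steps
        elif steps - best_step >= config.patience_steps:
            break

    n_trees = best_step * config.step_size
    if n_trees < config.min_trees:
        warnings.warn(
            f"selected {n_trees} trees (< {config.min_trees}); consider lowering "
            f"the learning rate (e.g. {config.learning_rate / 10:g})"
        )

    # truncate every model to the selected stage
    full.trees_ = full.trees_[:n_trees]
    full.n_trees = n_trees
    full._link = full.init_ + config.learning_rate * np.sum(
        [t.predict(X) for t in full.trees_], axis=0
    ) if n_trees else np.full(len(y), full.init_)

    null_dev, resid_dev, corr = [], [], []
    for mdl, (Xt, yt) in zip(fold_models, holdouts):
        mdl.trees_ = mdl.trees_[:n_trees]
        mu0 = mdl._mu(np.full(len(yt), mdl.init_))
        null_dev.append(deviance(yt, mu0, config.loss))
        pred = mdl._mu(mdl.init_ + config.learning_rate
                       * (np.sum([t.predict(Xt) for t in mdl.trees_], axis=0)
                          if mdl.trees_ else 0.0))
        resid_dev.append(deviance(yt, pred, config.loss))
        if len(yt) > 1 and np.std(pred) > 0 and np.std(yt) > 0:
            corr.append(float(np.corrcoef(yt, pred)[0, 1]))
        else:
            corr.append(0.0)

    k = len(null_dev)
    mean_null = float(np.mean(null_dev))
    mean_resid = float(np.mean(resid_dev))
    resid_se = float(np.std(resid_dev, ddof=1) / np.sqrt(k))
    corr_mean = float(np.mean(corr))
    corr_se = float(np.std(corr, ddof=1) / np.sqrt(k))

    mu_train = full._mu(full._link)
    train_null = deviance(y, full._mu(np.full(len(y), full.init_)), config.loss)
    train_resid = deviance(y, mu_train, config.loss)
    train_corr = (
        float(np.corrcoef(y, mu_train)[0, 1])
        if np.std(mu_train) > 0 and np.std(y) > 0
        else 0.0
    )

    evaluation = BRTEvaluation(
        n_trees=n_trees,
        training_deviance_explained=100.0 * (train_null - train_resid) / train_null,
        training_correlation=train_corr,
        cv_deviance_explained=100.0 * (mean_null - mean_resid) / mean_null,
        cv_correlation=corr_mean,
        cv_correlation_se=corr_se,
        mean_null_deviance=mean_null,
        mean_cv_residual_deviance=mean_resid,
        cv_residual_deviance_se=resid_se,
    )
    return n_trees, evaluation, full


# ---------------------------------------------------------------------------
# predictor assembly

#: Table-1-style variable categories used for influence aggregation.
VARIABLE_CATEGORIES = {
    "catch_size": "physical",
    "elevation": "physical",
    "agriculture": "land use",
    "artificial": "land use",
    "forest": "land use",
    "natural_bare": "land use",
    "shrub": "land use",
    "water": "land use",
    "wetlands": "land use",
    "ammonium": "chemical",
    "chloride": "chemical",
    "max_ph": "chemical",
    "max_temp": "chemical",
    "min_do": "chemical",
    "min_ph": "chemical",
    "op": "chemical",
    "toc": "chemical",
    "tp": "chemical",
    "PCo1": "spatial",
    "PCo2": "spatial",
    "drainage": "spatial",
}

_NON_PREDICTORS = {"x", "y", "site_id", "section"}


def assemble_predictors(
    site_table: pd.DataFrame,
    pcoa_vectors: pd.DataFrame | None = None,
    section: str = "all",
    include_drainage: bool = False,
    drainage: pd.Series | None = None,
) -> pd.DataFrame:
    """Build the predictor table for one BRT model.

    Catchment size is a predictor only for the all-sites model (the
    section subsets are themselves defined by catchment-size ranges);
    spatial PCo1/PCo2 columns are appended when ``pcoa_vectors`` is
    given; an optional two-level drainage factor (0/1) can be added.
    """
    cols = [c for c in site_table.columns if c not in _NON_PREDICTORS]
    X = site_table[cols].copy()
    if section != "all":
        X = X.drop(columns=["catch_size"], errors="ignore")
    elif "catch_size" not in X.columns:
        raise ValueError("site table lacks 'catch_size'")
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing values in predictor columns {bad}")
    if pcoa_vectors is not None:
        X = X.join(pcoa_vectors[["PCo1", "PCo2"]])
    if include_drainage:
        if drainage is None:
            raise ValueError("include_drainage=True needs a drainage series")
        X["drainage"] = drainage.reindex(X.index).astype(int)
    return X
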