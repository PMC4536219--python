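import warnings

import numpy as np
import pandas as pd
import pytest

from riverems.boost import (
    BRTConfig,
    BoostedTreesRegressor,
    assemble_predictors,
    deviance,
    relative_influence,
    select_n_trees_cv,
)


@pytest.fixture
def linear_problem(rng):
    X = rng.normal(size=(150, 10))
    y = 2.0 * X[:, 0] + rng.normal(0, 0.5, 150)
    return X, y


class TestDeviance:
    def test_perfect_fit_zero(self):
        assert deviance([1, 2, 3], [1, 2, 3], "poisson") == pytest.approx(0.0)
        assert deviance([1.0, 2.0], [1.0, 2.0], "gaussian") == 0.0

    def test_gaussian_is_mse(self):
        assert deviance([0.0, 2.0], [1.0, 1.0], "gaussian") == pytest.approx(1.0)

    def test_poisson_formula_value(self):
        # 2*[0 + (2 log 2 - 1)]/2 with the y=0 log-term convention
        expected = 2 * (2 * np.log(2) - 1) / 2
        assert deviance([1, 2], [1, 1], "poisson") == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.386, abs=5e-4)

    def test_nonpositive_mu_rejected_for_poisson(self):
        with pytest.raises(ValueError):
            deviance([1], [0.0], "poisson")


class TestBoostedTreesRegressor:
    def test_constant_response_predicts_baseline(self):
        X = np.random.default_rng(0).normal(size=(40, 3))
        y = np.full(40, 7.0)
        m = BoostedTreesRegressor(n_trees=50, learning_rate=0.1, random_state=0).fit(X, y)
        assert np.allclose(m.predict(X), 7.0, atol=1e-6)

    def test_training_deviance_non_increasing(self, linear_problem):
        X, y = linear_problem
        m = BoostedTreesRegressor(n_trees=200, learning_rate=0.05, random_state=0).fit(X, y)
        path = np.array(m.train_deviance_path_)
        assert (np.diff(path) <= 1e-9).all()

    def test_signal_beats_variance_held_out(self, rng, linear_problem):
        X, y = linear_problem
        m = BoostedTreesRegressor(n_trees=400, learning_rate=0.05, random_state=1).fit(
            X[:100], y[:100]
        )
        mse = np.mean((m.predict(X[100:]) - y[100:]) ** 2)
        assert mse < np.var(y[100:])

    def test_seed_fixes_fit_exactly(self, linear_problem):
        X, y = linear_problem
        m1 = BoostedTreesRegressor(n_trees=60, learning_rate=0.05, random_state=9).fit(X, y)
        m2 = BoostedTreesRegressor(n_trees=60, learning_rate=0.05, random_state=9).fit(X, y)
        assert (m1.predict(X) == m2.predict(X)).all()

    def test_poisson_rejects_negative_response(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            BoostedTreesRegressor(loss="poisson").fit(X, np.array([-1] + [1] * 9))

    def test_poisson_predictions_positive(self, rng):
        X = rng.normal(size=(60, 4))
        y = rng.poisson(np.exp(0.5 * X[:, 0] + 1.0))
        m = BoostedTreesRegressor(
            loss="poisson", n_trees=150, learning_rate=0.05, random_state=0
        ).fit(X, y)
        assert (m.predict(X) > 0).all()


class TestRelativeInfluence:
    def test_sums_to_100_and_unused_variable_zero(self, rng):
        X = rng.normal(size=(120, 5))
        X[:, 4] = 0.0  # constant column can never be split on
        y = 3 * X[:, 1] + rng.normal(0, 0.3, 120)
        m = BoostedTreesRegressor(n_trees=150, learning_rate=0.05, random_state=0).fit(X, y)
        infl = relative_influence(m, feature_names=list("abcde"))
        assert infl["influence"].sum() == pytest.approx(100.0, abs=1e-6)
        assert infl.set_index("variable").loc["e", "influence"] == 0.0
        assert infl.iloc[0]["variable"] == "b"

    def test_category_column_attached(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["elevation", "chloride"])
        y = X["elevation"].to_numpy() + rng.normal(0, 0.1, 50)
        m = BoostedTreesRegressor(n_trees=50, learning_rate=0.1, random_state=0).fit(X, y)
        infl = relative_influence(
            m, categories={"elevation": "physical", "chloride": "chemical"}
        )
        assert set(infl["category"]) == {"physical", "chemical"}


class TestSelectNTreesCV:
    def test_training_identity_from_table_values(self):
        # percent deviance explained is 100*(null - residual)/null
        assert 100 * (3.976 - 1.578) / 3.976 == pytest.approx(60.3, abs=0.05)
        assert 100 * (3.976 - 2.871) / 3.976 == pytest.approx(27.8, abs=0.05)

    def test_perfect_predictor_near_full_cv_deviance(self, rng):
        X = rng.normal(size=(100, 3))
        y = X[:, 0].copy()
        cfg = BRTConfig(loss="gaussian", learning_rate=0.1, max_trees=2000,
                        step_size=100, min_trees=1, n_folds=5, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, ev, model = select_n_trees_cv(X, y, cfg)
        assert ev.cv_deviance_explained > 85.0
        assert ev.training_deviance_explained > 95.0
        assert model.n_trees == ev.n_trees

    def test_pure_noise_cv_deviance_not_positive(self, rng):
        X = rng.normal(size=(90, 8))
        y = rng.normal(size=90)
        cfg = BRTConfig(loss="gaussian", learning_rate=0.02, max_trees=600,
                        step_size=50, min_trees=1, n_folds=5, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, ev, _ = select_n_trees_cv(X, y, cfg)
        se_pct = 100 * ev.cv_residual_deviance_se / ev.mean_null_deviance
        assert ev.cv_deviance_explained <= 3 * se_pct

    def test_small_tree_count_warns_about_learning_rate(self, rng):
        X = rng.normal(size=(60, 3))
        y = X[:, 0] + rng.normal(0, 0.1, 60)
        cfg = BRTConfig(loss="gaussian", learning_rate=0.2, max_trees=300,
                        step_size=50, min_trees=1000, n_folds=5, seed=0)
        with pytest.warns(UserWarning, match="learning rate"):
            select_n_trees_cv(X, y, cfg)

    def test_fewer_rows_than_folds_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            select_n_trees_cv(X, np.zeros(5), BRTConfig(n_folds=10))


class TestAssemblePredictors:
    @pytest.fixture
    def site_table(self, rng):
        n = 12
        return pd.DataFrame(
            {
                "catch_size": rng.uniform(3, 900, n),
                "elevation": rng.uniform(100, 400, n),
                "agriculture": rng.uniform(0, 100, n),
                "chloride": rng.uniform(5, 200, n),
                "x": rng.uniform(0, 1e5, n),
                "y": rng.uniform(0, 1e5, n),
            },
            index=[f"s{i}" for i in range(n)],
        )

    def test_section_models_exclude_catchment_size(self, site_table):
        X = assemble_predictors(site_table, section="headwaters")
        assert "catch_size" not in X.columns
        assert "x" not in X.columns and "y" not in X.columns

    def test_all_sites_model_keeps_catchment_size(self, site_table):
        X = assemble_predictors(site_table, section="all")
        assert "catch_size" in X.columns

    def test_spatial_adds_exactly_two_columns(self, site_table):
        vec = pd.DataFrame(
            {"PCo1": np.zeros(12), "PCo2": np.ones(12)}, index=site_table.index
        )
        base = assemble_predictors(site_table, section="all")
        spat = assemble_predictors(site_table, pcoa_vectors=vec, section="all")
        assert spat.shape[1] == base.shape[1] + 2
        assert {"PCo1", "PCo2"} <= set(spat.columns)

    def test_drainage_factor_two_level(self, site_table):
        drainage = pd.Series(
            [0, 1] * 6, index=site_table.index, dtype=int
        )
        X = assemble_predictors(
            site_table, section="all", include_drainage=True, drainage=drainage
        )
        assert set(X["drainage"].unique()) == {0, 1}
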