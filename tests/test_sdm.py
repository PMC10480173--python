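"""Suitability models: fitting, prediction, ensembles, AUC."""

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from mhw_habitat.occurrence import DAY_OF_YEAR, rasterize_mask
from mhw_habitat.sdm import (
    ModelConfig,
    fit_ensemble,
    fit_model,
    kfold_auc,
    predict_daily,
    resolve_covariates,
    validate_auc,
)

FAST = ModelConfig(min_trees=100, learning_rates=(0.1, 0.01), seed=0)


def make_table(n=400, seed=0, informative=True, extra_noise_covs=2):
    """Presence/absence rows with label driven (or not) by covariate x."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    if informative:
        p = 1.0 / (1.0 + np.exp(-3.0 * x))
        label = (rng.random(n) < p).astype(int)
    else:
        label = rng.integers(0, 2, size=n)
    df = pd.DataFrame(
        {
            "species": "sp",
            "date": pd.Timestamp("2020-06-01") + pd.to_timedelta(rng.integers(0, 90, n), "D"),
            "lon": rng.uniform(-10, 0, n),
            "lat": rng.uniform(30, 40, n),
            "label": label,
            "x": x,
        }
    )
    for j in range(extra_noise_covs):
        df[f"noise{j}"] = rng.normal(size=n)
    return df


class TestFitModel:
    def test_separable_data_training_auc(self):
        df = make_table(300, seed=1)
        df["label"] = (df["x"] > 0).astype(int)
        model = fit_model(df, FAST)
        scores = model.predict(df[list(model.covariate_names)].to_numpy(float))
        assert validate_auc(scores, df["label"]) >= 0.99

    def test_uninformative_labels_cv_auc_near_half(self):
        df = make_table(500, seed=2, informative=False)
        aucs = kfold_auc(df, FAST, n_folds=5, seed=3)
        assert 0.4 <= aucs.mean() <= 0.6

    def test_informative_covariate_dominates_importance(self):
        df = make_table(600, seed=3)
        model = fit_model(df, FAST)
        assert model.importance.idxmax() == "x"
        assert model.importance.sum() == pytest.approx(100.0)

    def test_single_class_rejected(self):
        df = make_table(50, seed=4)
        df["label"] = 1
        with pytest.raises(ValueError, match="single class"):
            fit_model(df, FAST)

    def test_too_few_rows_rejected(self):
        df = make_table(200, seed=5)
        with pytest.raises(ValueError, match="at least"):
            fit_model(df.head(4), replace(FAST, bag_fraction=0.5))

    def test_learning_rate_fallback_warns(self):
        # a rate so large the holdout deteriorates long before min_trees
        df = make_table(300, seed=6)
        cfg = ModelConfig(min_trees=400, learning_rates=(0.9,), seed=0)
        with pytest.warns(UserWarning, match="sustained"):
            model = fit_model(df, cfg)
        assert model.n_trees == 400

    def test_temperature_only_selection(self):
        names = ["sst", "sst_sd", "chl", DAY_OF_YEAR]
        assert resolve_covariates("temperature-only", names) == ("sst", "sst_sd", DAY_OF_YEAR)
        assert resolve_covariates("full", names) == tuple(names)
        with pytest.raises(ValueError):
            resolve_covariates(("missing",), names)


class TestPredictDaily:
    def test_constant_environment_identical_days_without_doy(
        self, small_model, small_env, small_occurrences
    ):
        env2 = small_env.isel(time=slice(0, 2)).copy(deep=True)
        for v in env2.data_vars:
            env2[v].values[1] = env2[v].values[0]
        no_doy = tuple(c for c in small_model.covariate_names if c != DAY_OF_YEAR)
        model = fit_model(small_occurrences, replace(FAST, covariates=no_doy))
        cube = predict_daily(model, env2)
        np.testing.assert_array_equal(cube.values[0], cube.values[1])

    def test_hull_masking_everywhere(self, small_model, small_cube, small_scenario):
        hull_mask = rasterize_mask(small_scenario.grid, small_model.hull)
        outside = ~hull_mask
        assert np.all(np.isnan(small_cube.values[:, outside]))
        assert np.isfinite(small_cube.values[:, hull_mask]).any()

    def test_missing_covariate_named_in_error(self, small_model, small_env):
        env = small_env.drop_vars("chl")
        with pytest.raises(ValueError, match="chl"):
            predict_daily(small_model, env)

    def test_monotone_response_preserves_ranking(self):
        df = make_table(3000, seed=7, extra_noise_covs=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = fit_model(df, ModelConfig(min_trees=600, learning_rates=(0.02,), seed=0))
        x_grid = np.linspace(-2.5, 2.5, 200)
        scores = model.predict(x_grid[:, None])
        rho, _ = spearmanr(scores, x_grid)
        assert rho > 0.95


class TestEnsemble:
    def test_degenerate_ensemble_equals_single_fit(self, rng):
        df = make_table(250, seed=8)
        ens = fit_ensemble(df, FAST, n_replicates=1, fraction=1.0, seed=4)
        assert len(ens.models) == 1
        np.testing.assert_array_equal(ens.subsample_indices[0], np.arange(len(df)))
        single = fit_model(df, replace(FAST, seed=ens.seeds[0]))
        X = df[list(single.covariate_names)].to_numpy(float)
        np.testing.assert_allclose(ens.models[0].predict(X), single.predict(X))

    def test_replicate_subsamples_distinct_and_stratified(self):
        df = make_table(400, seed=9)
        ens = fit_ensemble(df, FAST, n_replicates=8, fraction=0.75, seed=5)
        keys = {tuple(idx) for idx in ens.subsample_indices}
        assert len(keys) == 8
        label = df["label"].to_numpy()
        for idx in ens.subsample_indices:
            for c in (0, 1):
                expected = round(0.75 * (label == c).sum())
                assert (label[idx] == c).sum() == expected

    def test_auc_spread_shrinks_with_sample_size(self):
        fast = ModelConfig(min_trees=60, learning_rates=(0.1,), seed=0)

        def replicate_aucs(n, seed):
            df = make_table(n, seed=seed, extra_noise_covs=1)
            holdout = make_table(800, seed=seed + 100, extra_noise_covs=1)
            ens = fit_ensemble(df, fast, n_replicates=6, fraction=0.75, seed=seed)
            Xh = holdout[list(ens.models[0].covariate_names)].to_numpy(float)
            return [validate_auc(m.predict(Xh), holdout["label"]) for m in ens.models]

        sd_small = np.std(replicate_aucs(400, seed=11), ddof=1)
        sd_large = np.std(replicate_aucs(4000, seed=12), ddof=1)
        assert sd_large < sd_small


class TestValidateAuc:
    def test_perfect_and_constant_scores(self):
        assert validate_auc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
        assert validate_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_known_pairwise_value(self):
        # all-pairs count: 3 of 4 presence/absence pairs correctly ordered
        assert validate_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            validate_auc([0.1, 0.2], [1, 1])


def test_multivariate_beats_temperature_only(small_occurrences):
    """With suitability driven by chlorophyll, the temperature covariates
    alone should rank holdout points worse than the full covariate set."""
    rng = np.random.default_rng(0)
    mask = rng.random(len(small_occurrences)) < 0.75
    train = small_occurrences[mask].reset_index(drop=True)
    test = small_occurrences[~mask]
    full = fit_model(train, FAST)
    temp = fit_model(train, replace(FAST, covariates="temperature-only"))
    auc_full = validate_auc(
        full.predict(test[list(full.covariate_names)].to_numpy(float)), test["label"]
    )
    auc_temp = validate_auc(
        temp.predict(test[list(temp.covariate_names)].to_numpy(float)), test["label"]
    )
    assert auc_full > auc_temp
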