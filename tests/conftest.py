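"""Shared fixtures: one small synthetic world fitted once per session.

The miniature world (8 x 8 degrees at 0.5 degrees, three seasons, one
event) keeps model fits to a couple of seconds; model-quality assertions
that need statistical power build their own larger worlds.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import mhw_habitat as mh

#: Fast boosted-tree settings for unit tests (the production default of
#: 2000 heavily-shrunk trees is exercised by the end-to-end recovery tests).
FAST_MODEL = mh.ModelConfig(min_trees=150, learning_rates=(0.05, 0.005), seed=42)


@pytest.fixture(scope="session")
def small_scenario():
    return mh.small_scenario(seed=7)


@pytest.fixture(scope="session")
def small_env(small_scenario):
    return mh.generate_environment(small_scenario)


@pytest.fixture(scope="session")
def small_telemetry(small_scenario, small_env):
    return mh.generate_telemetry(small_scenario, small_env)


@pytest.fixture(scope="session")
def small_zones(small_scenario):
    return mh.generate_jurisdictions(small_scenario)


@pytest.fixture(scope="session")
def small_occurrences(small_scenario, small_telemetry, small_env):
    labelled = mh.sample_pseudo_absences(small_telemetry, small_scenario.grid, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mh.match_covariates(labelled, small_env)


@pytest.fixture(scope="session")
def small_model(small_occurrences):
    return mh.fit_model(small_occurrences, FAST_MODEL)


@pytest.fixture(scope="session")
def small_cube(small_model, small_env):
    return mh.predict_daily(small_model, small_env)


@pytest.fixture(scope="session")
def small_core(small_model, small_occurrences, small_cube):
    pres = small_occurrences[small_occurrences["label"] == 1]
    scores = small_model.predict(
        pres[list(small_model.covariate_names)].to_numpy(dtype=float)
    )
    thr = mh.compute_threshold(scores, 0.5)
    return mh.binarize(small_cube, thr, species="species_a")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260917)
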