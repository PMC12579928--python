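"""Shared fixtures: a small synthetic world for unit tests and one
acceptance-scale world (20,000 plots, 200 trees) shared by the expensive
recovery tests."""

from __future__ import annotations

import pytest
from hypothesis import settings

import divtrend as dt
from divtrend import plot_data, richness_model as rm
from divtrend.synthetic_world import generate_series, generate_static

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg() -> dt.WorldConfig:
    # the bundled default world
    return dt.synthetic_world.default_config()


@pytest.fixture(scope="session")
def small_static(small_cfg):
    return generate_static(small_cfg)


@pytest.fixture(scope="session")
def small_series(small_cfg):
    return generate_series(small_cfg)


@pytest.fixture(scope="session")
def small_split(small_static):
    retained, _ = plot_data.apply_filters(small_static)
    train, test = plot_data.stratified_split(retained, seed=7)
    return retained, train, test


@pytest.fixture(scope="session")
def small_model(small_split):
    _, train, _ = small_split
    return rm.fit(train, rm.Hyperparams(n_trees=60, min_node_size=5, mtry=3, seed=3))


# -- acceptance-scale world --------------------------------------------------


@pytest.fixture(scope="session")
def recovery_cfg() -> dt.WorldConfig:
    # default world size: 20,000 static plots, 1,000 series
    return dt.WorldConfig(seed=101)


@pytest.fixture(scope="session")
def recovery_world(recovery_cfg):
    static = generate_static(recovery_cfg)
    series = generate_series(recovery_cfg)
    retained, _ = plot_data.apply_filters(static)
    return static, series, retained


@pytest.fixture(scope="session")
def recovery_model(recovery_world):
    _, _, retained = recovery_world
    train, test = plot_data.stratified_split(retained, seed=13)
    model = rm.fit(train, rm.Hyperparams(n_trees=200, min_node_size=5, mtry=3, seed=13))
    return model, train, test
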