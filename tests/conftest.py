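"""Shared fixtures: a small synthetic study region and the full-size one.

The expensive full-size run (landscape, sampling, aggregation, forest fit)
is session-scoped and computed once; tests only read from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from ashazard.forest import FittedForest, ForestSpec, fit_forest, stratified_split
from ashazard.prep import ModelingTable, build_modeling_table
from ashazard.synthetic import (
    ExceedanceModelSpec,
    Landscape,
    LandscapeConfig,
    SamplingConfig,
    generate_landscape,
    paper_like_scenario,
    sample_arsenic_points,
)


@pytest.fixture(scope="session")
def small_landscape() -> Landscape:
    cfg = LandscapeConfig(
        grid_shape=(60, 60),
        n_continuous=4,
        categorical_levels=(3,),
        correlation_length=4.0,
        seed=123,
    )
    return generate_landscape(cfg)


@pytest.fixture(scope="session")
def small_mechanism() -> ExceedanceModelSpec:
    return ExceedanceModelSpec(
        intercept=-0.3,
        linear_coefficients={"field_00": 1.8, "field_01": -1.2},
        peaked_terms={"field_02": (0.3, 0.5, 1.0)},
    )


@pytest.fixture(scope="session")
def small_points(small_landscape, small_mechanism) -> pd.DataFrame:
    sampling = SamplingConfig(
        n_points=4000, clustering_factor=1.0, hotspot_fraction=0.2, seed=11
    )
    return sample_arsenic_points(small_landscape, small_mechanism, sampling)


@pytest.fixture(scope="session")
def small_table(small_landscape, small_points) -> ModelingTable:
    return build_modeling_table(
        small_points,
        small_landscape.grid,
        small_landscape.predictors,
        small_landscape.categorical,
    )


@pytest.fixture(scope="session")
def small_forest(small_table) -> FittedForest:
    split = stratified_split(small_table, seed=5)
    return fit_forest(split.train, ForestSpec(n_trees=201, mtry=4, seed=5))


@dataclass
class StudyRun:
    """One full-size synthetic study: data, split, fitted forest, predictions."""

    landscape: Landscape
    table: ModelingTable
    split: object
    model: FittedForest
    test_prob: np.ndarray
    full_prob: np.ndarray
    mechanism: ExceedanceModelSpec


@pytest.fixture(scope="session")
def study_run() -> StudyRun:
    """The frozen full-size scenario, fit once with a reduced tree count."""
    from ashazard.forest import predict_prob_table

    landscape_cfg, mechanism, sampling = paper_like_scenario(seed=0)
    landscape = generate_landscape(landscape_cfg)
    points = sample_arsenic_points(landscape, mechanism, sampling)
    table = build_modeling_table(
        points, landscape.grid, landscape.predictors, landscape.categorical
    )
    split = stratified_split(table, seed=7)
    model = fit_forest(split.train, ForestSpec(n_trees=201, mtry=6, seed=7))
    return StudyRun(
        landscape=landscape,
        table=table,
        split=split,
        model=model,
        test_prob=predict_prob_table(model, split.test),
        full_prob=predict_prob_table(model, table),
        mechanism=mechanism,
    )
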