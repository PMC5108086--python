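"""Shared fixtures: tiny hand-built studies and small synthetic scenarios."""

from dataclasses import replace

import numpy as np
import pytest

from tiermeta.io import ExpressionStudy
from tiermeta.simulate import (
    PlantedPathway,
    SimulationConfig,
    generate_collection,
    generate_disease_studies,
)


@pytest.fixture
def tiny_study() -> ExpressionStudy:
    """3 genes x 6 samples, first gene with a clean case/control difference."""
    rng = np.random.default_rng(42)
    values = rng.normal(5.0, 1.0, size=(3, 6))
    values[0, :3] += 3.0
    return ExpressionStudy(
        study_id="S1",
        disease_id="D1",
        genes=["g1", "g2", "g3"],
        samples=[f"smp{i}" for i in range(6)],
        values=values,
        labels=["case"] * 3 + ["control"] * 3,
    )


@pytest.fixture
def small_config() -> SimulationConfig:
    """Fast scenario: 3 diseases x 3 studies x 5/group, 300 genes, 10 pathways."""
    return SimulationConfig(
        n_diseases=3,
        studies_per_disease=3,
        samples_per_group=5,
        n_genes=300,
        n_pathways=10,
        pathway_size_range=(10, 20),
        background_de_fraction=0.0,
        gene_dropout_fraction=0.1,
        seed=7,
    )


@pytest.fixture
def planted_small_config(small_config) -> SimulationConfig:
    planted = PlantedPathway(
        pathway="PW01", diseases=("D1", "D2"), effect=2.0
    )
    return replace(small_config, planted_pathways=(planted,))


@pytest.fixture
def small_collection(small_config):
    return generate_collection(small_config)


@pytest.fixture
def small_studies(small_config, small_collection):
    return generate_disease_studies(small_config, small_collection)
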