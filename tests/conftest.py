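"""Shared fixtures: the default synthetic benchmark and a hand-built toy."""

from __future__ import annotations

import numpy as np
import pytest

import repomine as rm
from repomine.data import SimilarityMatrix
from repomine.similarity import FeatureSimilarities


@pytest.fixture(scope="session")
def default_dataset() -> rm.SyntheticDataset:
    """The default planted-signal benchmark: 60x40, signal 0.9, seed 7."""
    return rm.generate(rm.GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def default_sims(default_dataset) -> FeatureSimilarities:
    return rm.build_all_similarities(default_dataset.drug_table, default_dataset.disease_table)


@pytest.fixture(scope="session")
def pipeline_result(default_dataset, default_sims) -> rm.PipelineResult:
    """One full pipeline run (mining + CV + final model) at seed 7."""
    return rm.run_pipeline(
        default_dataset.drug_table,
        default_dataset.disease_table,
        default_dataset.index,
        rm.PipelineConfig(seed=7),
        sims=default_sims,
    )


@pytest.fixture()
def toy_catalog() -> rm.FeatureCatalog:
    """Minimal one-drug-feature, one-disease-feature catalog."""
    return rm.FeatureCatalog(
        drug_features=(rm.FeatureSpec("target", "drug", "set_valued"),),
        disease_features=(rm.FeatureSpec("pathway", "disease", "set_valued"),),
    )


@pytest.fixture()
def toy_sims(toy_catalog) -> FeatureSimilarities:
    """Hand-built symmetric 3x3 similarity matrices over d1-d3 / s1-s3."""
    drug_vals = np.array(
        [
            [1.0, 0.6, 0.2],
            [0.6, 1.0, 0.3],
            [0.2, 0.3, 1.0],
        ]
    )
    disease_vals = np.array(
        [
            [1.0, 0.4, 0.8],
            [0.4, 1.0, 0.5],
            [0.8, 0.5, 1.0],
        ]
    )
    drug = {"target": SimilarityMatrix("target", ["d1", "d2", "d3"], drug_vals).validate()}
    disease = {"pathway": SimilarityMatrix("pathway", ["s1", "s2", "s3"], disease_vals).validate()}
    return FeatureSimilarities(toy_catalog, drug, disease)


@pytest.fixture()
def toy_index() -> rm.AssociationIndex:
    return rm.AssociationIndex.from_pairs([("d1", "s1"), ("d2", "s2"), ("d2", "s3")])
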