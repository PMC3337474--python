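"""Shared fixtures: a small simulated dataset and models trained on it.

Everything is generated at test time from fixed seeds; the heavier
artifacts are session-scoped so the training cost is paid once.
"""

from __future__ import annotations

import pytest

from ppipred import classify, negative_sampling, pipeline
from ppipred.synthetic_data import SimulationConfig, SyntheticDataset, simulate


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(
        n_proteins=150, n_edges=300, seed=7, n_complexes=2, complex_size=8
    )


@pytest.fixture(scope="session")
def sim_dataset(sim_config) -> SyntheticDataset:
    return simulate(sim_config)


@pytest.fixture(scope="session")
def gold_sets(sim_dataset):
    """Evidence-derived positives and degree-balanced negatives."""
    positives = pipeline.build_positive_set(
        sim_dataset.evidence.acceptor_records,
        sim_dataset.evidence.donor_records,
        sim_dataset.evidence.ortholog_map,
    )
    known = pipeline.known_pairs(sim_dataset.evidence.acceptor_records)
    known |= sim_dataset.true_edges
    negatives = negative_sampling.degree_preserving_shuffle(
        positives, known | positives, negative_sampling.ShuffleConfig(seed=11)
    )
    return positives, negatives


@pytest.fixture(scope="session")
def featurizer(sim_dataset):
    return pipeline.make_featurizer(sim_dataset)


@pytest.fixture(scope="session")
def training_data(featurizer, gold_sets):
    positives, negatives = gold_sets
    vectors, labels = pipeline.labelled_vectors(featurizer, positives, negatives)
    return vectors, labels


@pytest.fixture(scope="session")
def trained_models(training_data):
    vectors, labels = training_data
    return pipeline.train_both(vectors, labels, classify.TrainingConfig(seed=13))
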