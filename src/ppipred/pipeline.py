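"""High-level orchestration shared by the CLI, tests and analysis scripts.

These helpers wire the stage modules together for the common case of a
:class:`~ppipred.synthetic_data.SyntheticDataset` (or any object with
the same attributes): gold-standard construction from evidence,
degree-preserving negative sampling, featurization with the strict
completeness filter, and training/scoring of both learners.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from . import classify, gold_standard
from .classify import PredictionRecord, TrainedModel, TrainingConfig
from .io_formats import InteractionRecord, OrthologMap
from .pair_features import PairFeaturizer, PairFeatureVector, filter_complete
from .pairs import PairKey

__all__ = [
    "build_positive_set",
    "known_pairs",
    "make_featurizer",
    "labelled_vectors",
    "train_both",
    "score_pairs",
]


def build_positive_set(
    acceptor_records: Iterable[InteractionRecord],
    donor_records: Iterable[InteractionRecord] = (),
    ortholog_map: OrthologMap | None = None,
) -> set[PairKey]:
    """Two-evidence filtering plus interolog transfer from the donor species."""
    positives = gold_standard.filter_two_evidence(list(acceptor_records))
    donor_records = list(donor_records)
    if donor_records and ortholog_map is not None:
        donor_pairs = gold_standard.filter_two_evidence(donor_records)
        positives |= gold_standard.map_orthologs(donor_pairs, ortholog_map)
    return positives


def known_pairs(*record_lists: Iterable[InteractionRecord]) -> set[PairKey]:
    """Every pair observed at least once, by any method (exclusion pool)."""
    out: set[PairKey] = set()
    for records in record_lists:
        out.update(r.pair for r in records)
    return out


def make_featurizer(dataset, symmetric_mode: str = "per_feature") -> PairFeaturizer:
    return PairFeaturizer(
        features=dataset.features,
        expression=dataset.expression,
        localization=dataset.localization,
        positions=dataset.positions,
        genetic_edges=frozenset(dataset.genetic_edges),
        symmetric_mode=symmetric_mode,
    )


def labelled_vectors(
    featurizer: PairFeaturizer,
    positives: Iterable[PairKey],
    negatives: Iterable[PairKey],
) -> tuple[list[PairFeatureVector], np.ndarray]:
    """Complete pair vectors and aligned 0/1 labels for training."""
    pos = filter_complete(featurizer.vectors(sorted(positives)))
    neg = filter_complete(featurizer.vectors(sorted(negatives)))
    vectors = pos + neg
    labels = np.array([1] * len(pos) + [0] * len(neg))
    return vectors, labels


def train_both(
    vectors: Sequence[PairFeatureVector],
    labels,
    config: TrainingConfig,
) -> dict[str, TrainedModel]:
    """Fit the SVM and the random forest on the same training data."""
    return {
        "svm_rbf": classify.train(vectors, labels, replace(config, learner="svm_rbf")),
        "random_forest": classify.train(vectors, labels, replace(config, learner="random_forest")),
    }


def score_pairs(
    models: dict[str, TrainedModel],
    featurizer: PairFeaturizer,
    pairs: Iterable[PairKey],
    threshold: float,
) -> list[PredictionRecord]:
    """Score pairs with both learners and annotate consensus calls."""
    vectors = featurizer.vectors(sorted({PairKey.of(a, b) for a, b in pairs}))
    svm = classify.predict_scores(models["svm_rbf"], vectors)
    rf = classify.predict_scores(models["random_forest"], vectors)
    return classify.make_prediction_records(svm, rf, threshold)
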