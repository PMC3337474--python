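"""Analysis of predicted interaction networks.

Covers degree statistics and degree-vs-feature association tests,
neighborhood extraction around seed proteins, interaction-profile
similarity between complex subunits, and the held-out-complex
evaluation protocol: train on a gold standard purged of all test
proteins, then try to reconstruct a known complex against random
control proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import evaluate, gold_standard, negative_sampling, pipeline
from .classify import PredictionRecord, TrainingConfig
from .io_formats import FeatureTable
from .negative_sampling import ShuffleConfig
from .pairs import MISSING, PairKey, is_missing

logger = logging.getLogger(__name__)

__all__ = [
    "PredictedNetwork",
    "DegreeFeatureResult",
    "ComplexEvalConfig",
    "HeldOutComplexResult",
    "degree_feature_tests",
    "neighborhood",
    "held_out_complex_eval",
    "profile_similarity",
]


@dataclass
class PredictedNetwork:
    """A scored, undirected prediction network."""

    graph: nx.Graph

    @classmethod
    def from_predictions(
        cls,
        records: Iterable[PredictionRecord],
        consensus_only: bool = True,
        superslim: Mapping[str, str] | None = None,
    ) -> "PredictedNetwork":
        g = nx.Graph()
        for r in records:
            if consensus_only and not r.consensus:
                continue
            g.add_edge(r.pair.first, r.pair.second,
                       svm_score=r.svm_score, rf_score=r.rf_score)
        for node in g.nodes:
            g.nodes[node]["superslim"] = (superslim or {}).get(node)
        cls._set_degrees(g)
        return cls(graph=g)

    @classmethod
    def from_edges(cls, edges: Iterable[PairKey]) -> "PredictedNetwork":
        g = nx.Graph()
        for e in edges:
            g.add_edge(e.first, e.second)
        cls._set_degrees(g)
        return cls(graph=g)

    @staticmethod
    def _set_degrees(g: nx.Graph) -> None:
        for node, deg in g.degree():
            g.nodes[node]["degree"] = deg

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[PairKey]:
        return {PairKey.of(a, b) for a, b in self.graph.edges}

    def degrees(self) -> dict[str, int]:
        return {n: d for n, d in self.graph.degree()}


@dataclass
class DegreeFeatureResult:
    feature: str
    spearman_rho: float
    spearman_p: float
    wilcoxon_stat: float = MISSING
    wilcoxon_p: float = MISSING
    n: int = 0


def degree_feature_tests(
    network: PredictedNetwork,
    feature_table: FeatureTable,
    feature: str,
    groups: Mapping[str, int] | None = None,
) -> DegreeFeatureResult:
    """Association between node degree and a numeric feature.

    Spearman correlation over the nodes with observed feature values;
    when the feature is binary (or an explicit two-group labelling is
    supplied) a Wilcoxon rank-sum test between the two groups' degrees
    is reported as well.  Constant degree across nodes is an error.
    """
    if feature not in feature_table.kinds:
        raise KeyError(f"unknown feature {feature!r}")
    degs = network.degrees()
    pids = [
        p for p in sorted(degs)
        if p in feature_table.data.index
        and not is_missing(feature_table.data.at[p, feature])
    ]
    if len(pids) < 3:
        raise ValueError("need at least 3 nodes with feature values")
    d = np.array([degs[p] for p in pids], dtype=float)
    v = np.array([float(feature_table.data.at[p, feature]) for p in pids], dtype=float)
    if np.ptp(d) == 0:
        raise ValueError("constant node degree: correlation undefined")
    rho, p = evaluate.rank_correlation(d, v)

    result = DegreeFeatureResult(feature=feature, spearman_rho=rho,
                                 spearman_p=p, n=len(pids))
    group_vals = None
    if groups is not None:
        group_vals = np.array([groups.get(pid, 0) for pid in pids])
    elif feature_table.kinds[feature] == "binary":
        group_vals = (v > 0).astype(int)
    if group_vals is not None and len(set(group_vals)) == 2:
        g0 = d[group_vals == 0]
        g1 = d[group_vals == 1]
        method = "exact" if max(len(g0), len(g1)) <= 20 else "asymptotic"
        stat, wp = stats.mannwhitneyu(g1, g0, alternative="two-sided", method=method)
        result.wilcoxon_stat = float(stat)
        result.wilcoxon_p = float(wp)
    return result


def neighborhood(network: PredictedNetwork, seeds: Iterable[str],
                 depth: int) -> PredictedNetwork:
    """Induced subgraph on all nodes within ``depth`` hops of any seed.

    Unknown seeds are skipped with a warning; depth 0 induces on the
    seeds themselves.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    g = network.graph
    keep: set[str] = set()
    for s in seeds:
        if s not in g:
            logger.warning("seed protein %s not in network; skipped", s)
            continue
        keep.update(nx.single_source_shortest_path_length(g, s, cutoff=depth))
    sub = g.subgraph(keep).copy()
    PredictedNetwork._set_degrees(sub)
    return PredictedNetwork(graph=sub)


def profile_similarity(network: PredictedNetwork,
                       members: Sequence[str]) -> pd.DataFrame:
    """Pearson similarity of the members' interaction-score profiles.

    Each member's profile is its score against every other node of the
    network (absent edges score 0); for each member pair the columns of
    the two members themselves are removed before correlating.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("need at least 2 members")
    g = network.graph
    universe = sorted(g.nodes)
    col = {n: i for i, n in enumerate(universe)}
    profiles = np.zeros((len(members), len(universe)))
    for i, mbr in enumerate(members):
        if mbr not in g:
            continue
        for nb, attrs in g[mbr].items():
            score = attrs.get("svm_score")
            if score is None or is_missing(score):
                score = 1.0  # unscored edge: presence itself is the profile
            profiles[i, col[nb]] = score
    sim = pd.DataFrame(np.eye(len(members)), index=members, columns=members)
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            mask = np.ones(len(universe), dtype=bool)
            for mbr in (members[i], members[j]):
                if mbr in col:
                    mask[col[mbr]] = False
            a, b = profiles[i, mask], profiles[j, mask]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                r = MISSING
            else:
                r = float(np.corrcoef(a, b)[0, 1])
            sim.iat[i, j] = sim.iat[j, i] = r
    return sim


# ---------------------------------------------------------------------------
# Held-out-complex evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplexEvalConfig:
    """Protocol knobs for held-out-complex reconstruction."""

    n_controls: int | None = None  # default: as many controls as members
    threshold: float = 0.5
    seed: int = 0
    training: TrainingConfig = field(default_factory=TrainingConfig)
    shuffle: ShuffleConfig | None = None


@dataclass
class HeldOutComplexResult:
    members: tuple[str, ...]
    controls: tuple[str, ...]
    report_svm: evaluate.MetricsReport
    report_rf: evaluate.MetricsReport
    predictions: list[PredictionRecord]
    member_control_pairs: list[PairKey]
    trained_on_positives: int = 0
    trained_on_negatives: int = 0


def held_out_complex_eval(
    complex_members: Iterable[str],
    universe: Iterable[str],
    dataset,
    training_positives: Iterable[PairKey],
    known: Iterable[PairKey],
    config: ComplexEvalConfig | None = None,
) -> HeldOutComplexResult:
    """Reconstruct a known complex from a model that never saw its proteins.

    Controls are sampled uniformly (seeded) from the universe minus the
    members.  Every pair touching a member or a control is purged from
    the training positives before negatives are drawn and both learners
    are trained; all pairs among members + controls are then scored.
    Precision-recall (and the rest of the battery) is reported against
    the all-within-complex truth, and predicted member-control pairs are
    listed separately.
    """
    config = config or ComplexEvalConfig()
    members = sorted(set(complex_members))
    if len(members) < 2:
        raise ValueError("complex must have at least 2 members")
    pool = sorted(set(universe) - set(members))
    n_controls = config.n_controls if config.n_controls is not None else len(members)
    if len(pool) < n_controls:
        raise ValueError(f"control pool too small: {len(pool)} < {n_controls}")
    rng = np.random.default_rng(config.seed % (2**31))
    controls = sorted(rng.choice(pool, size=n_controls, replace=False).tolist())
    test_proteins = set(members) | set(controls)

    gold = gold_standard.GoldStandard(positives=set(training_positives))
    gold = gold_standard.exclude_proteins(gold, test_proteins)
    leak = {p for pair in gold.positives for p in pair} & test_proteins
    assert not leak, "training pairs leak test proteins"
    if not gold.positives:
        raise ValueError("no training positives left after excluding test proteins")

    shuffle_cfg = config.shuffle or ShuffleConfig(seed=config.seed)
    known = set(known) | set(training_positives)
    negatives = negative_sampling.degree_preserving_shuffle(
        gold.positives, known, shuffle_cfg
    )
    negatives = {p for p in negatives
                 if p.first not in test_proteins and p.second not in test_proteins}

    featurizer = pipeline.make_featurizer(dataset)
    vectors, labels = pipeline.labelled_vectors(featurizer, gold.positives, negatives)
    models = pipeline.train_both(vectors, labels, config.training)

    import itertools as _it

    all_pairs = [PairKey.of(a, b)
                 for a, b in _it.combinations(sorted(test_proteins), 2)]
    predictions = pipeline.score_pairs(models, featurizer, all_pairs, config.threshold)

    member_set = set(members)
    truth, svm_scores, rf_scores = [], [], []
    for rec in predictions:
        if is_missing(rec.svm_score) or is_missing(rec.rf_score):
            continue
        truth.append(int(rec.pair.first in member_set and rec.pair.second in member_set))
        svm_scores.append(rec.svm_score)
        rf_scores.append(rec.rf_score)
    report_svm = evaluate.report(svm_scores, truth, threshold=config.threshold)
    report_rf = evaluate.report(rf_scores, truth, threshold=config.threshold)

    member_control = [
        rec.pair for rec in predictions
        if rec.consensus
        and ((rec.pair.first in member_set) != (rec.pair.second in member_set))
    ]
    return HeldOutComplexResult(
        members=tuple(members),
        controls=tuple(controls),
        report_svm=report_svm,
        report_rf=report_rf,
        predictions=predictions,
        member_control_pairs=member_control,
        trained_on_positives=len(gold.positives),
        trained_on_negatives=len(negatives),
    )
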