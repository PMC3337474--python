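"""Fully synthetic proteomes, interaction networks, features and evidence.

The generator plants the statistical structure the classifier is meant
to exploit, without imitating any particular organism's marginals:

* a true interaction network (preferential attachment, configuration
  model, or Erdős–Rényi) over ``n_proteins`` with exactly ``n_edges``;
* an expression matrix built from latent condition programs — each
  interacting pair shares a program with loading ``coexpr_effect``, so
  co-expressed partners show elevated Pearson correlation;
* localization and coarse GO process annotations that agree between
  interacting pairs with configured probabilities;
* nuisance per-protein features (length, mass, isoelectric point, codon
  adaptation, mRNA metrics, ...) drawn from log-normal/normal baselines
  that carry no pair signal;
* noisy interaction evidence: each true edge is seen by Y2H and by a
  capture assay with configured sensitivities, false records are drawn
  from non-edges, and a donor species with partial one-to-one ortholog
  coverage re-reports covered edges for interolog transfer.

All generators are deterministic given ``seed``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import (
    FeatureTable,
    InteractionRecord,
    OrthologMap,
    System,
)
from .pair_features import SUPERSLIM_PRIORITY
from .pairs import PairKey

__all__ = [
    "SimulationConfig",
    "SyntheticFeatures",
    "EvidenceBundle",
    "SyntheticDataset",
    "generate_true_network",
    "generate_features",
    "generate_evidence",
    "simulate",
]

NETWORK_MODELS = ("pa", "er", "configuration")

LOCALIZATION_TERMS = (
    "nucleus", "cytoplasm", "mitochondrion", "ER",
    "golgi", "plasma_membrane", "nucleolus", "vacuole",
)

CHROMOSOMES = ("I", "II", "III")
CHROM_WEIGHTS = (0.45, 0.35, 0.20)
CHROM_LENGTHS = {"I": 5_600_000, "II": 4_500_000, "III": 2_500_000}

#: Maximum proteins per functional module (see generate_features).
_MODULE_CAP = 15

_CAPTURE_CHOICES = (
    System.AFFINITY_CAPTURE_MS,
    System.AFFINITY_CAPTURE,
    System.COIP,
    System.RECONSTITUTED_COMPLEX,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    The default scale (300 proteins, 600 true edges, 60 conditions) is
    large enough for stable AUC estimates yet keeps a full pipeline run
    in the minutes range.  ``coexpr_effect`` is the loading of the
    latent program shared by interacting pairs; 2.0 lifts the mean
    edge-vs-non-edge Pearson correlation difference well above 0.3.
    """

    n_proteins: int = 300
    n_edges: int = 600
    n_conditions: int = 60
    network_model: str = "pa"
    intra_module_edge_fraction: float = 0.7
    n_latent_programs: int = 150
    coexpr_effect: float = 2.0
    base_loading: float = 0.7
    expression_noise: float = 1.0
    coloc_agreement: float = 0.7
    shared_go_prob: float = 0.6
    y2h_sensitivity: float = 0.8
    capture_sensitivity: float = 0.8
    evidence_fpr: float = 0.05
    colocalization_rate: float = 0.05
    ortholog_coverage: float = 0.7
    one_to_many_fraction: float = 0.1
    missingness: float = 0.01
    n_complexes: int = 0
    complex_size: int = 8
    seed: int = 0
    acceptor_species: str = "fission_yeast"
    donor_species: str = "budding_yeast"

    def __post_init__(self):
        for name in ("coloc_agreement", "shared_go_prob", "y2h_sensitivity",
                     "capture_sensitivity", "ortholog_coverage",
                     "one_to_many_fraction", "missingness", "colocalization_rate",
                     "intra_module_edge_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.network_model not in NETWORK_MODELS:
            raise ValueError(f"unknown network model {self.network_model!r}")
        if self.n_edges > self.n_proteins * (self.n_proteins - 1) // 2:
            raise ValueError("edge count infeasible for n_proteins")

    @property
    def protein_ids(self) -> list[str]:
        width = len(str(self.n_proteins))
        return [f"SPP{i:0{width}d}" for i in range(1, self.n_proteins + 1)]


@dataclass
class SyntheticFeatures:
    features: FeatureTable
    expression: pd.DataFrame
    localization: dict[str, frozenset[str]]
    positions: pd.DataFrame
    go_annotations: dict[str, frozenset[str]]


@dataclass
class EvidenceBundle:
    acceptor_records: list[InteractionRecord]
    donor_records: list[InteractionRecord]
    ortholog_map: OrthologMap
    donor_of: dict[str, str]  # acceptor id -> donor id actually used


@dataclass
class SyntheticDataset:
    """Everything one pipeline run needs, generated from one config."""

    config: SimulationConfig
    true_edges: frozenset[PairKey]
    features: FeatureTable
    expression: pd.DataFrame
    localization: dict[str, frozenset[str]]
    positions: pd.DataFrame
    go_annotations: dict[str, frozenset[str]]
    evidence: EvidenceBundle
    complexes: dict[str, frozenset[str]] = field(default_factory=dict)
    genetic_edges: frozenset[PairKey] = frozenset()


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng((config.seed * 97 + stream) % (2**31))


# ---------------------------------------------------------------------------
# Module partition and true network
# ---------------------------------------------------------------------------

def _module_partition(config: SimulationConfig) -> list[list[int]]:
    """Partition protein indices into functional modules.

    Modules model co-complex membership: members share an expression
    program, a home compartment and a home functional category.  The
    first ``n_complexes`` modules have exactly ``complex_size`` members
    and double as the planted complex annotations.  Deterministic given
    the config seed (own stream, so the other generators can share it).
    """
    rng = _rng(config, 0)
    order = rng.permutation(config.n_proteins).tolist()
    modules: list[list[int]] = []
    pos = 0
    for _ in range(config.n_complexes):
        if pos + config.complex_size > config.n_proteins:
            raise ValueError("not enough proteins for the requested complexes")
        modules.append(sorted(order[pos:pos + config.complex_size]))
        pos += config.complex_size
    while pos < config.n_proteins:
        s = int(rng.integers(4, _MODULE_CAP + 1))
        modules.append(sorted(order[pos:pos + s]))
        pos += s
    return modules


def generate_true_network(config: SimulationConfig) -> frozenset[PairKey]:
    """Simple undirected graph with exactly ``config.n_edges`` edges.

    A fraction ``intra_module_edge_fraction`` of the edges falls within
    the planted modules (all within-complex pairs are forced); the rest
    follows the configured degree model: ``pa`` (preferential
    attachment), ``er`` (uniform pairs) or ``configuration`` (stubs of a
    heavy-tailed degree sequence, topped up to the exact edge count).
    """
    rng = _rng(config, 1)
    ids = config.protein_ids
    n, m = config.n_proteins, config.n_edges
    modules = _module_partition(config)
    edges: set[tuple[int, int]] = set()

    def add(i: int, j: int) -> bool:
        if i == j:
            return False
        e = (i, j) if i < j else (j, i)
        if e in edges:
            return False
        edges.add(e)
        return True

    # forced clique edges of the planted complexes
    for module in modules[: config.n_complexes]:
        for i, j in itertools.combinations(module, 2):
            add(i, j)
    if len(edges) > m:
        raise ValueError("edge budget smaller than the planted complex cliques")

    # intra-module edges up to the configured fraction
    intra_target = min(int(round(config.intra_module_edge_fraction * m)), m)
    pool = [
        (i, j)
        for module in modules
        for i, j in itertools.combinations(module, 2)
        if (i, j) not in edges
    ]
    k = min(max(intra_target - len(edges), 0), len(pool))
    if k > 0:
        for t in rng.choice(len(pool), size=k, replace=False):
            add(*pool[int(t)])

    # cross-module remainder by the configured degree model
    if config.network_model == "er":
        while len(edges) < m:
            i, j = rng.integers(0, n, size=2)
            add(int(i), int(j))
    elif config.network_model == "pa":
        deg = np.ones(n)
        for i, j in edges:
            deg[i] += 1
            deg[j] += 1
        while len(edges) < m:
            i = int(rng.integers(0, n))
            j = int(rng.choice(n, p=deg / deg.sum()))
            if add(i, j):
                deg[i] += 1
                deg[j] += 1
    else:  # configuration model stubs, topped up with random pairs
        raw = np.minimum(rng.zipf(2.5, size=n).astype(float), n - 1)
        target = raw * (2 * max(m - len(edges), 0) / raw.sum())
        stubs: list[int] = []
        for i, t in enumerate(target):
            stubs.extend([i] * int(round(t)))
        rng.shuffle(stubs)
        for k2 in range(0, len(stubs) - 1, 2):
            if len(edges) >= m:
                break
            add(stubs[k2], stubs[k2 + 1])
        while len(edges) < m:
            i, j = rng.integers(0, n, size=2)
            add(int(i), int(j))

    return frozenset(PairKey.of(ids[i], ids[j]) for i, j in edges)


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def _sorted_edges(edges: Iterable[PairKey]) -> list[PairKey]:
    return sorted(edges)


def generate_features(config: SimulationConfig,
                      true_edges: Iterable[PairKey]) -> SyntheticFeatures:
    """Feature tables with planted pair signal for the true edges."""
    rng = _rng(config, 2)
    ids = config.protein_ids
    idx = {p: i for i, p in enumerate(ids)}
    n = config.n_proteins

    # --- functional modules --------------------------------------------------
    # The planted module partition models co-complex membership: members
    # share a latent expression program, a home localization compartment and
    # a home functional category.  Edges crossing two modules carry no
    # planted signal, like any cross-complex contact.
    modules = _module_partition(config)
    module_of = np.empty(n, dtype=int)
    for mid, module in enumerate(modules):
        for i in module:
            module_of[i] = mid
    module_ids = list(range(len(modules)))

    # --- expression: latent condition programs ------------------------------
    K, C = config.n_latent_programs, config.n_conditions
    programs = rng.standard_normal((K, C))
    program_of_module = {mid: int(rng.integers(0, K)) for mid in module_ids}
    loadings = np.zeros((n, K))
    base_prog = rng.integers(0, K, size=n)
    loadings[np.arange(n), base_prog] += config.base_loading
    module_prog = np.array([program_of_module[m] for m in module_of])
    loadings[np.arange(n), module_prog] += config.coexpr_effect
    expr = loadings @ programs + config.expression_noise * rng.standard_normal((n, C))
    expression = pd.DataFrame(
        expr, index=pd.Index(ids, name="protein_id"),
        columns=[f"cond{j + 1:03d}" for j in range(C)],
    )

    # --- localization: module home compartment + random extras ---------------
    home_loc = {
        mid: LOCALIZATION_TERMS[int(rng.integers(0, len(LOCALIZATION_TERMS)))]
        for mid in module_ids
    }
    loc: dict[str, set[str]] = {}
    for i, p in enumerate(ids):
        terms = {LOCALIZATION_TERMS[int(rng.integers(0, len(LOCALIZATION_TERMS)))]}
        if rng.random() < config.coloc_agreement:
            terms.add(home_loc[module_of[i]])
        if rng.random() < 0.3:
            terms.add(LOCALIZATION_TERMS[int(rng.integers(0, len(LOCALIZATION_TERMS)))])
        loc[p] = terms

    # --- GO superslim binary memberships: base rates + module home term ------
    base_probs = {t: p for t, p in zip(SUPERSLIM_PRIORITY,
                                       (0.08, 0.10, 0.15, 0.15, 0.18,
                                        0.12, 0.12, 0.18, 0.25, 1.0))}
    go_member = {t: (rng.random(n) < base_probs[t]) for t in SUPERSLIM_PRIORITY}
    specific_terms = [t for t in SUPERSLIM_PRIORITY if base_probs[t] < 1.0]
    home_go = {
        mid: specific_terms[int(rng.integers(0, len(specific_terms)))]
        for mid in module_ids
    }
    for i in range(n):
        if rng.random() < config.shared_go_prob:
            go_member[home_go[module_of[i]]][i] = True

    # --- chromosomal positions ----------------------------------------------
    chrom = rng.choice(CHROMOSOMES, size=n, p=CHROM_WEIGHTS)
    strand = rng.choice(["+", "-"], size=n)
    gene_len = np.exp(rng.normal(7.3, 0.5, size=n)).astype(int) + 200
    start = np.array([
        int(rng.integers(1, CHROM_LENGTHS[c] - L)) for c, L in zip(chrom, gene_len)
    ])
    positions = pd.DataFrame(
        {"chromosome": chrom, "strand": strand, "start": start, "end": start + gene_len},
        index=pd.Index(ids, name="protein_id"),
    )

    # --- nuisance per-protein features --------------------------------------
    length_aa = np.maximum(gene_len // 3 + rng.integers(-20, 20, size=n), 50)
    mrna_level = np.exp(rng.normal(2.0, 1.0, size=n))
    table = {
        "length": length_aa.astype(float),
        "mass_kda": length_aa * 0.110 + rng.normal(0, 1.0, size=n),
        "isoelectric_point": np.clip(rng.normal(7.0, 1.8, size=n), 3.0, 12.5),
        "gc_content": np.clip(rng.normal(0.36, 0.02, size=n), 0.25, 0.55),
        "cai": rng.beta(5, 15, size=n),
        "intron_count": rng.poisson(1.0, size=n).astype(float),
        "mrna_halflife": np.exp(rng.normal(3.5, 0.6, size=n)),
        "mrna_level": mrna_level,
        "polII_occupancy": 0.6 * np.log(mrna_level) + rng.normal(0, 0.8, size=n),
        "ribosome_density": rng.normal(1.0, 0.3, size=n),
        "hydropathy": rng.normal(-0.3, 0.4, size=n),
        "aromaticity": rng.beta(2, 20, size=n),
    }
    kinds = {f: "numeric" for f in table}
    for t in SUPERSLIM_PRIORITY:
        col = t.replace(":", "_")
        table[col] = go_member[t].astype(float)
        kinds[col] = "binary"

    data = pd.DataFrame(table, index=pd.Index(ids, name="protein_id"))
    if config.missingness > 0:
        numeric = [f for f, k in kinds.items() if k == "numeric"]
        mask = rng.random((n, len(numeric))) < config.missingness
        block = data[numeric].to_numpy()
        block[mask] = np.nan
        data[numeric] = block
        expr_mask = rng.random(expression.shape) < config.missingness
        expression = expression.mask(expr_mask)

    go_annotations = {
        p: frozenset(t for t in SUPERSLIM_PRIORITY if go_member[t][idx[p]])
        for p in ids
    }
    return SyntheticFeatures(
        features=FeatureTable(data=data, kinds=kinds),
        expression=expression,
        localization={p: frozenset(s) for p, s in loc.items()},
        positions=positions,
        go_annotations=go_annotations,
    )


# ---------------------------------------------------------------------------
# Evidence
# ---------------------------------------------------------------------------

def generate_evidence(config: SimulationConfig,
                      true_edges: Iterable[PairKey]) -> EvidenceBundle:
    """Noisy Y2H / capture records in acceptor and donor species."""
    rng = _rng(config, 3)
    ids = config.protein_ids
    edges = _sorted_edges(true_edges)
    edge_set = set(edges)
    m = len(edges)

    def sample_nonedges(k: int) -> list[PairKey]:
        out: list[PairKey] = []
        guard = 0
        while len(out) < k and guard < 50 * (k + 1):
            guard += 1
            i, j = rng.integers(0, len(ids), size=2)
            if i == j:
                continue
            p = PairKey.of(ids[int(i)], ids[int(j)])
            if p not in edge_set:
                out.append(p)
        return out

    def capture_record(pair: PairKey, species: str) -> InteractionRecord:
        system = _CAPTURE_CHOICES[int(rng.integers(0, len(_CAPTURE_CHOICES)))]
        throughput = "high" if system is System.AFFINITY_CAPTURE_MS else "low"
        return InteractionRecord.create(
            pair.first, pair.second, system, "physical", throughput, species
        )

    acceptor: list[InteractionRecord] = []
    sp = config.acceptor_species
    for e in edges:
        if rng.random() < config.y2h_sensitivity:
            acceptor.append(
                InteractionRecord.create(e.first, e.second, System.Y2H,
                                         "physical", "high", sp)
            )
        if rng.random() < config.capture_sensitivity:
            acceptor.append(capture_record(e, sp))
    # false records: single-assay observations of non-edges
    for pair in sample_nonedges(int(rng.poisson(config.evidence_fpr * m))):
        acceptor.append(
            InteractionRecord.create(pair.first, pair.second, System.Y2H,
                                     "physical", "high", sp)
        )
    for pair in sample_nonedges(int(rng.poisson(config.evidence_fpr * m))):
        acceptor.append(capture_record(pair, sp))
    # colocalization records are noise the evidence filter must ignore
    for pair in sample_nonedges(int(rng.poisson(config.colocalization_rate * m))):
        acceptor.append(
            InteractionRecord.create(pair.first, pair.second, System.COLOCALIZATION,
                                     "physical", "low", sp)
        )

    # --- ortholog map and donor-species records ----------------------------
    covered = [p for p in ids if rng.random() < config.ortholog_coverage]
    donor_of = {p: f"Y{p[3:]}" for p in covered}
    pairs = [(donor_of[p], p) for p in covered]
    for p in covered:
        r = rng.random()
        if r < config.one_to_many_fraction / 2 and len(ids) > 1:
            # donor gene with a second acceptor counterpart (non-unique donor)
            other = ids[int(rng.integers(0, len(ids)))]
            if other != p:
                pairs.append((donor_of[p], other))
        elif r < config.one_to_many_fraction:
            # second donor gene hitting the same acceptor (non-unique acceptor)
            pairs.append((f"Ydup{p[3:]}", p))
    omap = OrthologMap(pairs=pairs)

    donor: list[InteractionRecord] = []
    dsp = config.donor_species
    for e in edges:
        da, db = donor_of.get(e.first), donor_of.get(e.second)
        if da is None or db is None:
            continue
        if rng.random() < config.y2h_sensitivity:
            donor.append(InteractionRecord.create(da, db, System.Y2H,
                                                  "physical", "high", dsp))
        if rng.random() < config.capture_sensitivity:
            donor.append(capture_record(PairKey.of(da, db), dsp))

    return EvidenceBundle(
        acceptor_records=acceptor,
        donor_records=donor,
        ortholog_map=omap,
        donor_of=donor_of,
    )


# ---------------------------------------------------------------------------
# Complete dataset
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Run all generators and bundle the results.

    With ``n_complexes > 0`` the first modules of the planted partition
    are disjoint cliques in the true network and are reported as complex
    annotations, so complex members carry the full planted signal.
    """
    edges = generate_true_network(config)
    ids = config.protein_ids
    complexes = {
        f"CPX{c + 1:03d}": frozenset(ids[i] for i in module)
        for c, module in enumerate(_module_partition(config)[: config.n_complexes])
    }
    feats = generate_features(config, edges)
    evidence = generate_evidence(config, edges)

    # a sprinkle of genetic interactions: some true edges plus random pairs
    grng = _rng(config, 5)
    ids = config.protein_ids
    genetic: set[PairKey] = {e for e in sorted(edges) if grng.random() < 0.2}
    for _ in range(len(edges) // 4):
        i, j = grng.integers(0, len(ids), size=2)
        if i != j:
            genetic.add(PairKey.of(ids[int(i)], ids[int(j)]))

    return SyntheticDataset(
        config=config,
        true_edges=edges,
        features=feats.features,
        expression=feats.expression,
        localization=feats.localization,
        positions=feats.positions,
        go_annotations=feats.go_annotations,
        evidence=evidence,
        complexes=complexes,
        genetic_edges=frozenset(genetic),
    )
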