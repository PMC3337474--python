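"""Order-invariant feature vectors for unordered protein pairs.

Each pair vector concatenates the two proteins' per-protein features
with the pair-level features (co-expression, co-localization,
chromosomal context, known genetic interaction).  To make the encoding
symmetric — if A interacts with B then B interacts with A — each
per-protein numeric feature is emitted as its (min, max) over the two
proteins, so the vector is bit-identical regardless of input order.  A
per-protein lexicographic ordering variant is available through
``symmetric_mode="per_protein"`` for comparison.

Missing values propagate into the vector and mark it incomplete; only
complete vectors are used for training and scoring.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import FeatureTable
from .pairs import MISSING, PairKey, is_missing

logger = logging.getLogger(__name__)

__all__ = [
    "SUPERSLIM_PRIORITY",
    "SUPERSLIM_NAMES",
    "PairFeatureVector",
    "PairFeaturizer",
    "expression_correlation",
    "colocalization_index",
    "chromosomal_pair_features",
    "assign_superslim",
    "assemble_pair_vector",
    "filter_complete",
]

# GO superslim process terms, from most specific to most generic.  A protein
# is labelled with the first term of this list it is annotated with;
# unannotated proteins fall back to the root biological_process term.
SUPERSLIM_PRIORITY: tuple[str, ...] = (
    "GO:0007005",  # mitochondrion organization
    "GO:0007165",  # signal transduction
    "GO:0006350",  # transcription
    "GO:0016070",  # RNA metabolism
    "GO:0006412",  # protein biosynthesis
    "GO:0006259",  # DNA metabolism
    "GO:0007049",  # cell cycle
    "GO:0006810",  # transport
    "GO:0044238",  # primary metabolism
    "GO:0008150",  # biological process (root / fallback)
)

SUPERSLIM_NAMES: dict[str, str] = {
    "GO:0007005": "mitochondrion organization",
    "GO:0007165": "signal transduction",
    "GO:0006350": "transcription",
    "GO:0016070": "RNA metabolism",
    "GO:0006412": "protein biosynthesis",
    "GO:0006259": "DNA metabolism",
    "GO:0007049": "cell cycle",
    "GO:0006810": "transport",
    "GO:0044238": "primary metabolism",
    "GO:0008150": "biological process",
}

SUPERSLIM_FALLBACK = "GO:0008150"


@dataclass
class PairFeatureVector:
    """Numeric feature vector for one unordered pair."""

    pair: PairKey
    values: np.ndarray
    layout: tuple[str, ...]
    complete: bool

    def __post_init__(self):
        if len(self.values) != len(self.layout):
            raise ValueError("vector length does not match layout length")


# ---------------------------------------------------------------------------
# Pair-level primitives
# ---------------------------------------------------------------------------

def expression_correlation(expr: pd.DataFrame, pair: PairKey) -> float:
    """Pearson correlation of the two expression profiles.

    Computed over the conditions where both profiles are observed; needs
    at least 3 shared conditions and non-zero variance in both profiles,
    otherwise MISSING.
    """
    if pair.first not in expr.index or pair.second not in expr.index:
        return MISSING
    x = expr.loc[pair.first].to_numpy(dtype=float)
    y = expr.loc[pair.second].to_numpy(dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 3:
        return MISSING
    x, y = x[mask], y[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero-variance expression profile in pair %s", pair)
        return MISSING
    return float(np.corrcoef(x, y)[0, 1])


def colocalization_index(localization: Mapping[str, frozenset], pair: PairKey) -> float:
    """Jaccard index of the two proteins' localization term sets."""
    a = localization.get(pair.first)
    b = localization.get(pair.second)
    if not a or not b:
        return MISSING
    return len(a & b) / len(a | b)


def chromosomal_pair_features(
    positions: pd.DataFrame, pair: PairKey
) -> tuple[float, float, float]:
    """(same_strand, same_chromosome, midpoint distance in bp).

    Distance is MISSING for cross-chromosome pairs; all three are
    MISSING when either gene lacks coordinates.
    """
    if pair.first not in positions.index or pair.second not in positions.index:
        return (MISSING, MISSING, MISSING)
    ra = positions.loc[pair.first]
    rb = positions.loc[pair.second]
    same_strand = float(ra["strand"] == rb["strand"])
    same_chrom = float(ra["chromosome"] == rb["chromosome"])
    if same_chrom:
        mid_a = (float(ra["start"]) + float(ra["end"])) / 2.0
        mid_b = (float(rb["start"]) + float(rb["end"])) / 2.0
        distance = abs(mid_a - mid_b)
    else:
        distance = MISSING
    return (same_strand, same_chrom, distance)


def assign_superslim(
    protein_terms: Iterable[str],
    priority_list: Sequence[str] = SUPERSLIM_PRIORITY,
) -> str:
    """Single coarse functional label: first annotated term in priority order."""
    terms = set(protein_terms)
    for term in priority_list:
        if term in terms:
            return term
    return SUPERSLIM_FALLBACK


# ---------------------------------------------------------------------------
# Vector assembly
# ---------------------------------------------------------------------------

PAIR_FEATURE_BLOCK = (
    "expression_correlation",
    "colocalization",
    "same_strand",
    "same_chromosome",
    "chromosome_distance",
    "genetic_interaction",
)


@dataclass
class PairFeaturizer:
    """Turns unordered pairs into numeric vectors with a fixed layout.

    The layout is a pure function of the feature schema and of which
    pair-level sources are supplied, so vectors from different runs over
    the same schema are directly comparable (and models reusable).
    """

    features: FeatureTable
    expression: pd.DataFrame | None = None
    localization: Mapping[str, frozenset] | None = None
    positions: pd.DataFrame | None = None
    genetic_edges: frozenset[PairKey] = frozenset()
    symmetric_mode: str = "per_feature"
    #: Encoding of the distance component for cross-chromosome pairs:
    #: "max" substitutes the total genome span (different chromosome is a
    #: known topology, not an unknown measurement, so the pair stays
    #: complete); "missing" propagates MISSING and the completeness filter
    #: will drop the pair.
    cross_chromosome_distance: str = "max"

    _layout: tuple[str, ...] = field(init=False, repr=False)
    _row: dict[str, int] = field(init=False, repr=False)
    _num_cols: list[str] = field(init=False, repr=False)
    _cat_cols: list[str] = field(init=False, repr=False)
    _num_matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.symmetric_mode not in ("per_feature", "per_protein"):
            raise ValueError(f"unknown symmetric_mode: {self.symmetric_mode!r}")
        if self.cross_chromosome_distance not in ("max", "missing"):
            raise ValueError(
                f"unknown cross_chromosome_distance mode: {self.cross_chromosome_distance!r}"
            )
        self.genetic_edges = frozenset(self.genetic_edges)
        self._genome_span = (
            float(self.positions.groupby("chromosome")["end"].max().sum())
            if self.positions is not None
            else MISSING
        )
        cols = self.features.feature_names
        kinds = self.features.kinds
        self._num_cols = [c for c in cols if kinds[c] in ("numeric", "binary")]
        self._cat_cols = [c for c in cols if kinds[c] == "categorical"]
        self._row = {pid: i for i, pid in enumerate(self.features.protein_ids)}
        self._num_matrix = self.features.data[self._num_cols].to_numpy(dtype=float)

        layout: list[str] = []
        suffixes = ("min", "max") if self.symmetric_mode == "per_feature" else ("p1", "p2")
        for c in self._num_cols:
            layout += [f"{c}__{suffixes[0]}", f"{c}__{suffixes[1]}"]
        for c in self._cat_cols:
            layout.append(f"{c}__same")
            layout += [f"{c}__n_{lvl}" for lvl in self.features.levels[c]]
        if self.expression is not None:
            layout.append("expression_correlation")
        if self.localization is not None:
            layout.append("colocalization")
        if self.positions is not None:
            layout += ["same_strand", "same_chromosome", "chromosome_distance"]
        layout.append("genetic_interaction")
        self._layout = tuple(layout)

    @property
    def layout(self) -> tuple[str, ...]:
        return self._layout

    def vector(self, pair: PairKey) -> PairFeatureVector:
        pair = PairKey.of(pair[0], pair[1])
        for p in pair:
            if p not in self._row:
                raise KeyError(f"protein {p!r} not in feature table")
        va = self._num_matrix[self._row[pair.first]]
        vb = self._num_matrix[self._row[pair.second]]

        parts: list[float] = []
        if self.symmetric_mode == "per_feature":
            lo = np.minimum(va, vb)  # NaN propagates: missing either side -> both MISSING
            hi = np.maximum(va, vb)
            parts.extend(float(x) for loihi in zip(lo, hi) for x in loihi)
        else:
            # Order the two proteins once, by lexicographic comparison of
            # their numeric profiles (NaN sorts last), then concatenate.
            ka = tuple(math.inf if is_missing(x) else x for x in va)
            kb = tuple(math.inf if is_missing(x) else x for x in vb)
            first, second = (va, vb) if ka <= kb else (vb, va)
            parts.extend(float(x) for ab in zip(first, second) for x in ab)

        for c in self._cat_cols:
            ca = self.features.data.at[pair.first, c]
            cb = self.features.data.at[pair.second, c]
            if ca is None or cb is None:
                parts.append(MISSING)
                parts.extend(MISSING for _ in self.features.levels[c])
            else:
                parts.append(float(ca == cb))
                counts = {lvl: 0.0 for lvl in self.features.levels[c]}
                for v in (ca, cb):
                    if v in counts:
                        counts[v] += 1.0
                parts.extend(counts[lvl] for lvl in self.features.levels[c])

        if self.expression is not None:
            parts.append(expression_correlation(self.expression, pair))
        if self.localization is not None:
            parts.append(colocalization_index(self.localization, pair))
        if self.positions is not None:
            same_strand, same_chrom, distance = chromosomal_pair_features(self.positions, pair)
            if (
                self.cross_chromosome_distance == "max"
                and same_chrom == 0.0
                and is_missing(distance)
            ):
                distance = self._genome_span
            parts.extend((same_strand, same_chrom, distance))
        parts.append(float(pair in self.genetic_edges))

        values = np.asarray(parts, dtype=float)
        return PairFeatureVector(
            pair=pair,
            values=values,
            layout=self._layout,
            complete=bool(not np.isnan(values).any()),
        )

    def vectors(self, pairs: Iterable) -> list[PairFeatureVector]:
        return [self.vector(PairKey.of(a, b)) for a, b in pairs]


def assemble_pair_vector(
    features: FeatureTable,
    expr: pd.DataFrame | None,
    localization: Mapping[str, frozenset] | None,
    positions: pd.DataFrame | None,
    genetic_edges: Iterable[PairKey],
    pair: PairKey,
    symmetric_mode: str = "per_feature",
) -> PairFeatureVector:
    """One-shot pair vector assembly (see :class:`PairFeaturizer`)."""
    fz = PairFeaturizer(
        features=features,
        expression=expr,
        localization=localization,
        positions=positions,
        genetic_edges=frozenset(genetic_edges),
        symmetric_mode=symmetric_mode,
    )
    return fz.vector(pair)


def filter_complete(vectors: Iterable[PairFeatureVector]) -> list[PairFeatureVector]:
    """Keep exactly the vectors with no missing component."""
    return [v for v in vectors if v.complete]
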