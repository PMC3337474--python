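"""Gold-standard construction: evidence filtering and ortholog transfer.

A protein pair enters the positive set only when its physical
interaction has been observed by two independent lines of evidence: at
least one yeast two-hybrid (Y2H) record and at least one capture-type
record (co-immunoprecipitation, affinity capture with or without mass
spectrometry, or complex reconstitution).  Colocalization records are
never counted.  Evidence is pooled within each species; interactions
supported in a donor species are transferred to the acceptor species
through one-to-one orthologs only.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io_formats import CAPTURE_SYSTEMS, InteractionRecord, OrthologMap, System, SystemClass
from .pairs import PairKey

logger = logging.getLogger(__name__)

__all__ = [
    "PairKey",
    "GoldStandard",
    "filter_two_evidence",
    "map_orthologs",
    "exclude_proteins",
    "build_complex_pairs",
]


@dataclass
class GoldStandard:
    """Positive and negative pair sets with per-pair provenance."""

    positives: set[PairKey] = field(default_factory=set)
    negatives: set[PairKey] = field(default_factory=set)
    provenance: dict[PairKey, str] = field(default_factory=dict)
    protein_universe: set[str] = field(default_factory=set)

    def __post_init__(self):
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"pairs labelled both positive and negative: {sorted(overlap)[:5]}")
        for p in itertools.chain(self.positives, self.negatives):
            self.protein_universe.update(p)

    @property
    def proteins_in_pairs(self) -> set[str]:
        out: set[str] = set()
        for p in itertools.chain(self.positives, self.negatives):
            out.update(p)
        return out


def filter_two_evidence(records: Iterable[InteractionRecord]) -> set[PairKey]:
    """Pairs supported by both Y2H and a capture technique.

    Only physical-class records count; colocalization is ignored
    entirely.  Evidence is tallied per (species, pair), so the two lines
    of evidence must come from the same species; the result is invariant
    to record order and duplication.
    """
    y2h: set[tuple[str, PairKey]] = set()
    capture: set[tuple[str, PairKey]] = set()
    for rec in records:
        if rec.system_class is not SystemClass.PHYSICAL:
            continue
        if rec.system is System.COLOCALIZATION:
            continue
        key = (rec.species, rec.pair)
        if rec.system is System.Y2H:
            y2h.add(key)
        elif rec.system in CAPTURE_SYSTEMS:
            capture.add(key)
    return {pair for (_, pair) in y2h & capture}


def map_orthologs(pairs: Iterable[PairKey], ortholog_map: OrthologMap) -> set[PairKey]:
    """Transfer donor-species pairs through one-to-one orthologs.

    A pair is transferred only when *both* proteins map uniquely;
    transferred pairs are re-canonicalized in acceptor ids and
    duplicates merged.  Pairs whose two proteins collapse onto the same
    acceptor gene are dropped.
    """
    one2one = ortholog_map.one_to_one()
    out: set[PairKey] = set()
    for pair in pairs:
        a = one2one.get(pair.first)
        b = one2one.get(pair.second)
        if a is None or b is None or a == b:
            continue
        out.add(PairKey.of(a, b))
    return out


def exclude_proteins(gold: GoldStandard, protein_set: Iterable[str]) -> GoldStandard:
    """Remove every pair touching any protein in ``protein_set``.

    Used to keep training sets disjoint from held-out test proteins.
    """
    excluded = set(protein_set)

    def keep(p: PairKey) -> bool:
        return p.first not in excluded and p.second not in excluded

    positives = {p for p in gold.positives if keep(p)}
    negatives = {p for p in gold.negatives if keep(p)}
    provenance = {p: v for p, v in gold.provenance.items() if keep(p)}
    return GoldStandard(
        positives=positives,
        negatives=negatives,
        provenance=provenance,
        protein_universe=set(gold.protein_universe),
    )


def build_complex_pairs(
    complexes: Mapping[str, frozenset[str]],
    universe: Iterable[str] | None = None,
) -> tuple[set[PairKey], set[PairKey]]:
    """Derive pair labels from complex membership.

    Positives are all within-complex pairs; negatives are pairs between
    members of *different* complexes, under the working assumption that
    complex members all interact with each other and not with members of
    other complexes.  A protein belonging to several complexes
    contributes positives for each membership and is never paired as a
    negative with any of its co-members.  Complexes with fewer than two
    members contribute no positives (warning).
    """
    if universe is not None:
        universe = set(universe)
        stray = {p for members in complexes.values() for p in members} - universe
        if stray:
            raise ValueError(f"complex members outside the universe: {sorted(stray)[:5]}")

    membership: dict[str, set[str]] = {}
    positives: set[PairKey] = set()
    for cid, members in complexes.items():
        if len(members) < 2:
            logger.warning("complex %s has <2 members; contributes no positives", cid)
        for p in members:
            membership.setdefault(p, set()).add(cid)
        for a, b in itertools.combinations(sorted(members), 2):
            positives.add(PairKey.of(a, b))

    annotated = sorted(membership)
    negatives: set[PairKey] = set()
    for a, b in itertools.combinations(annotated, 2):
        if membership[a] & membership[b]:
            continue  # co-members (possibly via a shared complex) are never negatives
        negatives.add(PairKey.of(a, b))
    return positives, negatives
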