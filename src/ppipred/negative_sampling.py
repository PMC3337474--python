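"""Degree-preserving negative sampling by randomized double-edge swaps.

Negative (presumed non-interacting) pair sets are built by shuffling the
links of the positive network while keeping every protein's degree
fixed, and excluding every pair that has been observed to interact at
least once.  This avoids the degree bias that plagues uniformly random
negative pairs: the negative set touches exactly the same proteins,
each with the same number of partners, as the positive set.

The sampler runs a double-edge-swap Markov chain: after a mixing phase
of random swaps, an exclusion-repair phase swaps away any remaining
excluded edges (never allowing the overlap with the exclusion set to
grow), followed by a second mixing phase restricted to valid states.
Stagnation triggers a seeded restart; exhausting all restarts raises an
explicit infeasibility error.  Uniformity over the feasible graphs is
approximate (it is a finite Markov chain, not an exact-uniform
sampler), but degrees are preserved exactly.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from .pairs import PairKey

__all__ = [
    "ShuffleConfig",
    "InfeasibleShuffleError",
    "degree_preserving_shuffle",
    "build_degree_balanced_testset",
    "build_imbalanced_negatives",
    "degree_sequence",
]


@dataclass(frozen=True)
class ShuffleConfig:
    """Knobs of the edge-swap chain.

    ``swaps_per_edge`` attempted swaps per edge are spent in each mixing
    phase; ``100 * n_edges`` consecutive rejections during repair
    trigger a restart with a fresh stream derived from ``seed``.
    """

    seed: int = 0
    max_restarts: int = 50
    swaps_per_edge: int = 10

    def __post_init__(self):
        if self.max_restarts < 1:
            raise ValueError("max_restarts must be >= 1")
        if self.swaps_per_edge < 1:
            raise ValueError("swaps_per_edge must be >= 1")


class InfeasibleShuffleError(RuntimeError):
    """No degree-preserving edge set avoiding the exclusions was found."""

    def __init__(self, message: str, rigid_nodes: tuple[str, ...] = ()):
        if rigid_nodes:
            message += f" (rigid nodes: {', '.join(rigid_nodes)})"
        super().__init__(message)
        self.rigid_nodes = rigid_nodes


def degree_sequence(edges: Iterable[PairKey]) -> dict[str, int]:
    """Node -> degree map of a simple undirected edge set."""
    deg: Counter[str] = Counter()
    for e in edges:
        deg[e.first] += 1
        deg[e.second] += 1
    return dict(deg)


def _restart_seed(seed: int, attempt: int) -> int:
    return (seed * 1_000_003 + attempt) % (2**31)


def _try_chain(
    edges: list[PairKey],
    excluded: frozenset[PairKey],
    rng: random.Random,
    swaps_per_edge: int,
) -> frozenset[PairKey] | None:
    m = len(edges)
    cur = list(edges)
    cur_set = set(cur)
    overlap = {e for e in cur_set if e in excluded}

    def attempt_swap(max_overlap_delta: int | None, force_overlap_edge: bool) -> bool:
        if force_overlap_edge:
            ei = rng.choice(sorted(overlap))
            i = cur.index(ei)  # m is small relative to chain length; fine
            j = rng.randrange(m)
            if i == j:
                return False
        else:
            i = rng.randrange(m)
            j = rng.randrange(m)
            if i == j:
                return False
        (a, b), (c, d) = cur[i], cur[j]
        if rng.random() < 0.5:
            c, d = d, c
        if a == c or b == d:
            return False
        e1, e2 = PairKey.of(a, c), PairKey.of(b, d)
        if e1 == e2 or e1 in cur_set or e2 in cur_set:
            return False
        if max_overlap_delta is not None:
            delta = (e1 in excluded) + (e2 in excluded)
            delta -= (cur[i] in excluded) + (cur[j] in excluded)
            if delta > max_overlap_delta:
                return False
        for old in (cur[i], cur[j]):
            cur_set.discard(old)
            overlap.discard(old)
        for new in (e1, e2):
            cur_set.add(new)
            if new in excluded:
                overlap.add(new)
        cur[i], cur[j] = e1, e2
        return True

    # Phase 1: free mixing (excluded edges may come and go).
    for _ in range(swaps_per_edge * m):
        attempt_swap(None, False)

    # Phase 2: repair — drive the overlap with the exclusion set to zero,
    # never letting it grow; stagnation aborts this restart.
    rejections = 0
    limit = 100 * max(m, 1)
    total_budget = 2000 * max(m, 1)  # hard cap: sideways moves must not loop forever
    while overlap:
        total_budget -= 1
        if total_budget <= 0:
            return None
        if attempt_swap(0, True):
            rejections = 0
        else:
            rejections += 1
            if rejections >= limit:
                return None

    # Phase 3: mixing restricted to valid (exclusion-free) states.
    for _ in range(swaps_per_edge * m):
        attempt_swap(0, False)

    return frozenset(cur_set)


def degree_preserving_shuffle(
    edges: Iterable[tuple],
    excluded: Iterable[tuple],
    config: ShuffleConfig | None = None,
) -> frozenset[PairKey]:
    """Sample an edge set with the input's exact degree sequence.

    The result is a simple graph (no self-loops, no multi-edges) with
    empty intersection with ``excluded``.  Raises
    :class:`InfeasibleShuffleError` when no such graph exists or none
    was found within ``config.max_restarts``; nodes whose exclusions
    alone make the problem impossible are named when detectable.
    """
    config = config or ShuffleConfig()
    edge_list = sorted({PairKey.of(a, b) for a, b in edges})
    excluded_set = frozenset(PairKey.of(a, b) for a, b in excluded)
    if not edge_list:
        return frozenset()

    deg = degree_sequence(edge_list)
    nodes = sorted(deg)
    # Rigidity pre-check: a node needs at least `degree` allowed partners.
    rigid = []
    for u in nodes:
        allowed = sum(
            1 for v in nodes if v != u and PairKey.of(u, v) not in excluded_set
        )
        if allowed < deg[u]:
            rigid.append(u)
    if rigid:
        raise InfeasibleShuffleError(
            "no degree-preserving edge set can avoid the exclusions",
            rigid_nodes=tuple(rigid),
        )

    if len(edge_list) == 1:
        only = edge_list[0]
        if only in excluded_set:
            raise InfeasibleShuffleError(
                "a single-edge graph admits no alternative realization"
            )
        return frozenset(edge_list)

    for attempt in range(config.max_restarts):
        rng = random.Random(_restart_seed(config.seed, attempt))
        result = _try_chain(edge_list, excluded_set, rng, config.swaps_per_edge)
        if result is not None:
            return result
    raise InfeasibleShuffleError(
        f"no valid shuffle found within {config.max_restarts} restarts"
    )


def build_degree_balanced_testset(
    positive_pairs: Iterable[tuple],
    known_any_species: Iterable[tuple],
    universe: Iterable[str],
    config: ShuffleConfig | None = None,
) -> frozenset[PairKey]:
    """Degree-balanced negatives over exactly the positive-set proteins.

    Every pair documented at least once in any species is excluded, as
    are the positives themselves; the output preserves each protein's
    degree in the positive set.
    """
    positives = {PairKey.of(a, b) for a, b in positive_pairs}
    if not positives:
        return frozenset()
    universe = set(universe)
    stray = {p for e in positives for p in e} - universe
    if stray:
        raise ValueError(f"positive pairs touch proteins outside the universe: {sorted(stray)[:5]}")
    excluded = {PairKey.of(a, b) for a, b in known_any_species} | positives
    return degree_preserving_shuffle(positives, excluded, config)


def build_imbalanced_negatives(
    known_interacting_proteins_edges: Iterable[tuple],
    config: ShuffleConfig | None = None,
) -> frozenset[PairKey]:
    """Shuffle the full known-interaction network into a large negative set.

    Intended for imbalanced testing: applied to the union network of all
    known interactions it yields one negative per known edge, with every
    protein keeping its observed number of partners.
    """
    known = {PairKey.of(a, b) for a, b in known_interacting_proteins_edges}
    return degree_preserving_shuffle(known, known, config)
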