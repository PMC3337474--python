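"""Canonical unordered protein-pair keys and the missing-value sentinel.

An interaction between proteins A and B is symmetric, so every pair is
stored under a single canonical key with the lexicographically smaller
identifier first.  Identifiers are compared case-sensitively because
systematic gene names (e.g. SPAC23C4.09c) are case-significant.

Missing feature values are represented by IEEE NaN, which is distinct
from every valid numeric value and propagates through arithmetic.
"""

from __future__ import annotations

import math
from typing import Iterable, NamedTuple

#: Sentinel for an absent / unparseable value.
MISSING: float = math.nan


def is_missing(x) -> bool:
    """True if ``x`` is the missing-value sentinel (NaN or None)."""
    if x is None:
        return True
    try:
        return math.isnan(float(x))
    except (TypeError, ValueError):
        return False


class PairKey(NamedTuple):
    """Canonical key for an unordered protein pair (``first < second``)."""

    first: str
    second: str

    @classmethod
    def of(cls, a: str, b: str) -> "PairKey":
        """Build the canonical key for proteins ``a`` and ``b``.

        Raises ``ValueError`` for self-pairs: a protein is never scored
        against itself.
        """
        if a == b:
            raise ValueError(f"self-pair is not a valid protein pair: {a!r}")
        return cls(a, b) if a < b else cls(b, a)

    def __contains__(self, protein) -> bool:  # type: ignore[override]
        return protein == self.first or protein == self.second


def pair_set(pairs: Iterable[tuple]) -> set[PairKey]:
    """Canonicalize an iterable of 2-tuples into a set of ``PairKey``."""
    return {PairKey.of(a, b) for a, b in pairs}
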