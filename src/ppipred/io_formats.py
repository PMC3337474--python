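"""Readers and writers for the tabular formats used throughout the pipeline.

All inputs are UTF-8, tab-separated files with a header row.  Missing
values are spelled either as an empty cell or as ``NA`` on disk; in
memory they become the :data:`~ppipred.pairs.MISSING` sentinel (NaN) for
numeric data and ``None`` for categorical data.

Interaction evidence uses a simplified dialect with one record per line:
``idA  idB  system  system_class  throughput  species``.  Pairs are
canonicalized at read time, so swapping the idA/idB columns of an input
file yields an identical record set.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pairs import MISSING, PairKey, is_missing

logger = logging.getLogger(__name__)

_NA_SPELLINGS = {"", "NA"}

#: Significant digits used when serializing scores (round-trip safe).
_SCORE_FMT = "%.10g"


# ---------------------------------------------------------------------------
# Interaction evidence
# ---------------------------------------------------------------------------

class System(str, enum.Enum):
    """Experimental system that produced an interaction record."""

    Y2H = "Y2H"
    AFFINITY_CAPTURE_MS = "affinity_capture_MS"
    AFFINITY_CAPTURE = "affinity_capture"
    COIP = "coIP"
    RECONSTITUTED_COMPLEX = "reconstituted_complex"
    COLOCALIZATION = "colocalization"
    OTHER = "other"


class SystemClass(str, enum.Enum):
    PHYSICAL = "physical"
    GENETIC = "genetic"


class Throughput(str, enum.Enum):
    HIGH = "high"
    LOW = "low"


#: Capture-type systems: pull-down style evidence of co-complex membership.
#: Y2H never counts toward this class, and colocalization is excluded from
#: evidence filtering entirely.
CAPTURE_SYSTEMS = frozenset(
    {
        System.AFFINITY_CAPTURE_MS,
        System.AFFINITY_CAPTURE,
        System.COIP,
        System.RECONSTITUTED_COMPLEX,
    }
)


@dataclass(frozen=True)
class InteractionRecord:
    """One evidence line for an unordered protein pair."""

    protein_a: str
    protein_b: str
    system: System
    system_class: SystemClass
    throughput: Throughput
    species: str

    @classmethod
    def create(cls, a, b, system, system_class, throughput, species):
        """Canonicalize the pair order and coerce enum fields."""
        key = PairKey.of(a, b)
        return cls(
            key.first,
            key.second,
            System(system),
            SystemClass(system_class),
            Throughput(throughput),
            str(species),
        )

    @property
    def pair(self) -> PairKey:
        return PairKey(self.protein_a, self.protein_b)


def read_interactions(path) -> list[InteractionRecord]:
    """Read evidence records; drops self-interactions with a warning.

    Raises ``ValueError`` naming the offending line for an unknown
    system / class / throughput token.
    """
    records: list[InteractionRecord] = []
    n_self = 0
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            return records
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            a, b, system, sclass, thr, species = fields[:6]
            if a == b:
                n_self += 1
                continue
            try:
                rec = InteractionRecord.create(a, b, system, sclass, thr, species)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    if n_self:
        logger.warning("dropped %d self-interaction record(s) from %s", n_self, path)
    return records


def write_interactions(records: Iterable[InteractionRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\tsystem\tsystem_class\tthroughput\tspecies\n")
        for r in records:
            fh.write(
                f"{r.protein_a}\t{r.protein_b}\t{r.system.value}\t"
                f"{r.system_class.value}\t{r.throughput.value}\t{r.species}\n"
            )


# ---------------------------------------------------------------------------
# Per-protein feature table
# ---------------------------------------------------------------------------

VALID_KINDS = ("numeric", "binary", "categorical")


@dataclass
class FeatureTable:
    """Per-protein named feature values with explicit missingness.

    ``data`` is indexed by protein id; numeric/binary columns are floats
    (NaN = missing), categorical columns hold strings (None = missing).
    """

    data: pd.DataFrame
    kinds: dict[str, str]
    levels: dict[str, list[str]] = field(default_factory=dict)
    n_parse_warnings: int = 0

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate protein id(s): {dups}")
        unknown = set(self.kinds.values()) - set(VALID_KINDS)
        if unknown:
            raise ValueError(f"unknown feature kind(s): {sorted(unknown)}")
        if set(self.kinds) != set(self.data.columns):
            raise ValueError("schema feature names do not match table columns")
        for f, kind in self.kinds.items():
            if kind == "categorical" and f not in self.levels:
                observed = sorted({v for v in self.data[f] if v is not None})
                self.levels[f] = observed

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def n_missing(self) -> int:
        total = 0
        for f, kind in self.kinds.items():
            col = self.data[f]
            if kind == "categorical":
                total += int(sum(v is None for v in col))
            else:
                total += int(col.isna().sum())
        return total


def read_feature_table(path, schema: Mapping[str, str],
                       levels: Mapping[str, Sequence[str]] | None = None) -> FeatureTable:
    """Read a header-bearing TSV of per-protein features.

    ``schema`` maps feature name -> kind in {numeric, binary, categorical}.
    Unparseable numeric cells become MISSING; the warning count is logged
    and stored on the returned table.  Duplicate protein ids are a hard
    error, as is an unknown kind in the schema.
    """
    for f, kind in schema.items():
        if kind not in VALID_KINDS:
            raise ValueError(f"unknown feature kind {kind!r} for feature {f!r}")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    id_col = raw.columns[0]
    ids = raw[id_col].tolist()
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValueError(f"duplicate protein id(s) in {path}: {dups}")
    missing_cols = [f for f in schema if f not in raw.columns]
    if missing_cols:
        raise ValueError(f"features declared in schema but absent from {path}: {missing_cols}")

    n_warn = 0
    out = {}
    for f, kind in schema.items():
        col = raw[f]
        if kind == "categorical":
            out[f] = [None if v in _NA_SPELLINGS else v for v in col]
        else:
            parsed = pd.to_numeric(col.replace(list(_NA_SPELLINGS), np.nan), errors="coerce")
            bad = parsed.isna() & ~col.isin(_NA_SPELLINGS)
            n_warn += int(bad.sum())
            out[f] = parsed.astype(float).values
    if n_warn:
        logger.warning("%d unparseable cell(s) in %s set to MISSING", n_warn, path)
    data = pd.DataFrame(out, index=pd.Index(ids, name="protein_id"))
    lv = {k: list(v) for k, v in (levels or {}).items()}
    return FeatureTable(data=data, kinds=dict(schema), levels=lv, n_parse_warnings=n_warn)


def write_feature_table(table: FeatureTable, path) -> None:
    df = table.data.copy()
    for f, kind in table.kinds.items():
        if kind == "categorical":
            df[f] = [("NA" if v is None else v) for v in df[f]]
        else:
            df[f] = [("NA" if is_missing(v) else _SCORE_FMT % v) for v in df[f]]
    df.to_csv(path, sep="\t", index=True, index_label="protein_id")


# ---------------------------------------------------------------------------
# Expression matrix, localization, positions, complexes, orthologs, pairs
# ---------------------------------------------------------------------------

def read_expression_matrix(path) -> pd.DataFrame:
    """Protein x condition matrix of log-expression values (NaN allowed)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=list(_NA_SPELLINGS),
                     keep_default_na=False)
    return df.astype(float)


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g",
                  index_label="protein_id")


def read_localization(path) -> dict[str, frozenset[str]]:
    """TSV ``protein_id<TAB>terms`` with comma-separated localization terms."""
    loc: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            pid, _, terms = line.rstrip("\n").partition("\t")
            terms = terms.strip()
            if terms and terms not in _NA_SPELLINGS:
                loc[pid] = frozenset(t.strip() for t in terms.split(",") if t.strip())
    return loc


def write_localization(loc: Mapping[str, frozenset], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\tterms\n")
        for pid in sorted(loc):
            fh.write(f"{pid}\t{','.join(sorted(loc[pid]))}\n")


def read_positions(path) -> pd.DataFrame:
    """Gene coordinates: columns chromosome, strand, start, end."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"chromosome": str, "strand": str})
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_positions(positions: pd.DataFrame, path) -> None:
    positions.to_csv(path, sep="\t", index_label="protein_id")


def read_complexes(path) -> dict[str, frozenset[str]]:
    """Long-format TSV ``complex_id<TAB>protein_id``, one member per row."""
    members: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            cid, _, pid = line.rstrip("\n").partition("\t")
            members.setdefault(cid, set()).add(pid)
    return {cid: frozenset(m) for cid, m in members.items()}


def write_complexes(complexes: Mapping[str, frozenset], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("complex_id\tprotein_id\n")
        for cid in sorted(complexes):
            for pid in sorted(complexes[cid]):
                fh.write(f"{cid}\t{pid}\n")


@dataclass
class OrthologMap:
    """Donor -> acceptor ortholog pairs with multiplicity bookkeeping."""

    pairs: list[tuple[str, str]]

    def donor_multiplicity(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for d, _ in self.pairs:
            counts[d] = counts.get(d, 0) + 1
        return counts

    def acceptor_multiplicity(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, a in self.pairs:
            counts[a] = counts.get(a, 0) + 1
        return counts

    def one_to_one(self) -> dict[str, str]:
        """Bijective donor -> acceptor mapping (unique orthologs only)."""
        dm = self.donor_multiplicity()
        am = self.acceptor_multiplicity()
        return {d: a for d, a in self.pairs if dm[d] == 1 and am[a] == 1}


def read_ortholog_map(path) -> OrthologMap:
    pairs = []
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            donor, _, acceptor = line.rstrip("\n").partition("\t")
            pairs.append((donor, acceptor.split("\t")[0]))
    return OrthologMap(pairs=pairs)


def write_ortholog_map(omap: OrthologMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("donor_id\tacceptor_id\n")
        for d, a in omap.pairs:
            fh.write(f"{d}\t{a}\n")


def read_pairs(path) -> set[PairKey]:
    """Read a two-column pair list into a canonical PairKey set."""
    out = set()
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            out.add(PairKey.of(fields[0], fields[1]))
    return out


def write_pairs(pairs: Iterable[PairKey], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\n")
        for p in sorted(pairs):
            fh.write(f"{p.first}\t{p.second}\n")


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------

def _fmt_score(x) -> str:
    return "NA" if is_missing(x) else _SCORE_FMT % x


def write_predictions(records, path, format: str = "tsv") -> None:
    """Write prediction records as TSV, or SIF (consensus pairs only).

    TSV columns: protein_a, protein_b, svm_score, rf_score, consensus.
    SIF lines ``a pp b`` are emitted only for consensus pairs.
    """
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown prediction format: {format!r}")
    with open(path, "w", encoding="utf-8") as fh:
        if format == "tsv":
            fh.write("protein_a\tprotein_b\tsvm_score\trf_score\tconsensus\n")
            for r in records:
                fh.write(
                    f"{r.pair.first}\t{r.pair.second}\t{_fmt_score(r.svm_score)}\t"
                    f"{_fmt_score(r.rf_score)}\t{int(bool(r.consensus))}\n"
                )
        else:
            for r in records:
                if r.consensus:
                    fh.write(f"{r.pair.first} pp {r.pair.second}\n")


def read_predictions(path):
    """Read a prediction TSV back into PredictionRecord objects."""
    from .classify import PredictionRecord  # local import avoids a cycle

    records = []
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            a, b, svm, rf, cons = line.rstrip("\n").split("\t")
            records.append(
                PredictionRecord(
                    pair=PairKey.of(a, b),
                    svm_score=MISSING if svm == "NA" else float(svm),
                    rf_score=MISSING if rf == "NA" else float(rf),
                    consensus=bool(int(cons)),
                )
            )
    return records
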