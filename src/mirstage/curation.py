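"""Curated miRNA dysregulation evidence: parsing, normalization, and queries.

The evidence database holds one record per (miRNA, direction, source,
reference) report of significant up- or downregulation in disease-derived
biospecimens. Records from tissue and saliva drive the direction filter;
blood and cell-line reports are retained but excluded from filtering by
default.
"""

from __future__ import annotations

import collections
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .enums import DEFAULT_ALLOWED_SOURCES, Direction, Qualifier, Source
from .errors import ParseError, ValidationError

__all__ = [
    "EvidenceRecord",
    "DysregulationDB",
    "DirectionVerdict",
    "normalize_mirna_id",
    "load_dysregulation",
    "write_dysregulation",
    "query_direction",
]

# Accepts the spellings seen in the wild: optional "hsa" prefix, mixed case,
# a missing hyphen between the family token and the number ("miR124-3p"),
# stray internal whitespace. The numeric tail (arm suffixes included) is
# preserved verbatim apart from lowercasing.
_MIRNA_RE = re.compile(r"^(?:hsa-?)?(mir|let)-?(\d[0-9a-z.-]*)$", re.IGNORECASE)


def normalize_mirna_id(raw: str) -> str:
    """Normalize a miRNA name to canonical ``hsa-miR-…`` / ``hsa-let-…`` form.

    The transform is idempotent: normalizing an already-canonical name
    returns it unchanged.

    Parameters
    ----------
    raw:
        A miRNA name such as ``"miR124-3p"``, ``"hsa-miR-34a-5p"`` or
        ``"let-7g-5p"``.

    Raises
    ------
    ValidationError
        If ``raw`` is empty or is not recognizable as a miRNA name.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise ValidationError(f"empty or non-string miRNA name: {raw!r}")
    token = "".join(raw.split())  # drop internal whitespace
    match = _MIRNA_RE.match(token)
    if match is None:
        raise ValidationError(f"not a recognizable miRNA name: {raw!r}")
    family = "miR" if match.group(1).lower() == "mir" else "let"
    return f"hsa-{family}-{match.group(2).lower()}"


@dataclass(frozen=True, order=True)
class EvidenceRecord:
    """One literature report of dysregulation for one miRNA.

    ``exosome`` marks saliva records derived from salivary exosomes; such
    records carry ``source == Source.SALIVA`` and count as saliva evidence.
    """

    mirna_id: str
    direction: Direction
    source: Source
    reference: str = ""
    exosome: bool = False

    def __post_init__(self) -> None:
        normalized = normalize_mirna_id(self.mirna_id)
        if normalized != self.mirna_id:
            raise ValidationError(
                f"mirna_id must be normalized: got {self.mirna_id!r}, "
                f"expected {normalized!r}"
            )
        if not isinstance(self.direction, Direction):
            raise ValidationError(f"direction must be a Direction, got {self.direction!r}")
        if not isinstance(self.source, Source):
            raise ValidationError(f"source must be a Source, got {self.source!r}")


class DysregulationDB:
    """Deduplicated collection of :class:`EvidenceRecord` with a per-miRNA index."""

    def __init__(self, records: Iterable[EvidenceRecord]):
        self.records: tuple[EvidenceRecord, ...] = tuple(sorted(set(records)))
        index: dict[str, dict[Direction, list[EvidenceRecord]]] = collections.defaultdict(
            lambda: {Direction.UP: [], Direction.DOWN: []}
        )
        for rec in self.records:
            index[rec.mirna_id][rec.direction].append(rec)
        self.index: Mapping[str, dict[Direction, list[EvidenceRecord]]] = dict(index)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DysregulationDB):
            return NotImplemented
        return self.records == other.records

    def mirnas(self) -> set[str]:
        return set(self.index)

    def evidence(self, mirna_id: str, direction: Direction) -> list[EvidenceRecord]:
        """All records for ``mirna_id`` in ``direction`` (empty if absent)."""
        return list(self.index.get(mirna_id, {}).get(direction, []))

    def directions_for(self, mirna_id: str) -> set[Direction]:
        entry = self.index.get(mirna_id)
        if entry is None:
            return set()
        return {d for d, recs in entry.items() if recs}


def _source_token(rec: EvidenceRecord) -> str:
    if rec.source is Source.SALIVA and rec.exosome:
        return "saliva_exosome"
    return rec.source.value


_REQUIRED_COLUMNS = ("mirna_id", "direction", "source", "reference")


def load_dysregulation(path: str | Path) -> DysregulationDB:
    """Load a dysregulation TSV into a :class:`DysregulationDB`.

    The file must be UTF-8 with a header row naming the columns
    ``mirna_id``, ``direction``, ``source``, ``reference``. Identifiers are
    normalized and exact duplicate records are collapsed.

    Raises
    ------
    ParseError
        On a missing header, an empty file, or an unknown direction or
        source token (reported with its line number).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError("empty dysregulation file", path=str(path)) from None
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"missing required columns {missing}", path=str(path))
    if frame.empty:
        raise ParseError("dysregulation file has a header but no records", path=str(path))

    records: list[EvidenceRecord] = []
    for idx, row in frame.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            source, exosome = Source.parse(row["source"])
            records.append(
                EvidenceRecord(
                    mirna_id=normalize_mirna_id(row["mirna_id"]),
                    direction=Direction.parse(row["direction"]),
                    source=source,
                    reference=row["reference"],
                    exosome=exosome,
                )
            )
        except ValidationError as exc:
            raise ParseError(str(exc), path=str(path), line=line) from None
    return DysregulationDB(records)


def write_dysregulation(db: DysregulationDB, path: str | Path) -> None:
    """Write a database back to the TSV format read by :func:`load_dysregulation`."""
    frame = pd.DataFrame(
        {
            "mirna_id": [r.mirna_id for r in db.records],
            "direction": [r.direction.value for r in db.records],
            "source": [_source_token(r) for r in db.records],
            "reference": [r.reference for r in db.records],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class DirectionVerdict:
    """Outcome of querying the database for a required dysregulation direction.

    ``passes`` is true iff at least one record in the allowed source set
    matches the required direction. The qualifier compares supporting vs
    opposing record counts within the allowed sources: CONSISTENT when no
    opposing record exists, MOSTLY when supporting records are at least as
    numerous, RARELY when opposing records outnumber supporting ones, and
    NONE when there is no supporting record at all.
    """

    direction_required: Direction
    passes: bool
    qualifier: Qualifier
    supporting_sources: frozenset[Source] = frozenset()
    n_supporting: int = 0
    n_opposing: int = 0
    #: Records matching the required direction but outside the allowed
    #: sources; reported for audit, never counted toward ``passes``.
    excluded_support: tuple[EvidenceRecord, ...] = field(default=(), compare=False)


def query_direction(
    db: DysregulationDB,
    mirna: str,
    required: Direction,
    allowed_sources: frozenset[Source] | set[Source] = DEFAULT_ALLOWED_SOURCES,
) -> DirectionVerdict:
    """Ask whether ``mirna`` has evidence of ``required`` dysregulation.

    Absent miRNAs yield ``passes=False`` with qualifier NONE rather than an
    error. Enlarging ``allowed_sources`` can only add supporting evidence,
    so it never flips ``passes`` from true to false.
    """
    if not allowed_sources:
        raise ValidationError("allowed_sources must be non-empty")
    allowed = frozenset(allowed_sources)
    supporting = [r for r in db.evidence(mirna, required) if r.source in allowed]
    opposing = [r for r in db.evidence(mirna, required.opposite) if r.source in allowed]
    excluded = tuple(r for r in db.evidence(mirna, required) if r.source not in allowed)

    if not supporting:
        qualifier = Qualifier.NONE
    elif not opposing:
        qualifier = Qualifier.CONSISTENT
    elif len(opposing) > len(supporting):
        qualifier = Qualifier.RARELY
    else:
        qualifier = Qualifier.MOSTLY

    return DirectionVerdict(
        direction_required=required,
        passes=bool(supporting),
        qualifier=qualifier,
        supporting_sources=frozenset(r.source for r in supporting),
        n_supporting=len(supporting),
        n_opposing=len(opposing),
        excluded_support=excluded,
    )
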