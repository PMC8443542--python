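"""Unified sequence-record model and the flagging rules that gate FASTA assembly.

Records arriving from BOLD-style and GenBank-style sources differ in field
names and taxonomy conventions.  This module harmonizes them into a single row
type (:class:`UnifiedRecord`), computes per-record quality flags, and reads and
writes the tab-separated "total table" that every downstream stage consumes.

Flags mark *why* a record is suspect (missing marker name, missing taxonomy,
missing sequence, trinomial/annotated names, digits or punctuation in taxon
names); they never delete data.  Inclusion is decided later, per flag, by
:func:`filter_records`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Source",
    "RecordFlag",
    "UnifiedRecord",
    "TotalTable",
    "MalformedRecordError",
    "TotalTableParseError",
    "flag_record",
    "harmonize_record",
    "dereplicate",
    "filter_records",
    "write_total_table",
    "read_total_table",
]


class Source(str, Enum):
    """Origin database of a record."""

    BOLD = "BOLD"
    NCBI = "NCBI"


class RecordFlag(str, Enum):
    """Per-record quality flags; one enum value per inclusion toggle."""

    NO_MARKER = "no_marker"
    NO_TAXA = "no_taxa"
    NO_SEQ = "no_seq"
    NAME_ISSUE = "name_issue"
    TAXA_DIGITS = "taxa_digits"
    TAXA_PUNCT = "taxa_punct"


#: Canonical flag order used for serialization.
FLAG_ORDER: tuple[RecordFlag, ...] = tuple(RecordFlag)

#: Placeholder written when a record carries no flags.
NO_FLAG = "-"


class MalformedRecordError(ValueError):
    """A source record is missing a structurally required field."""


class TotalTableParseError(ValueError):
    """The on-disk total table is malformed; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def flag_record(
    genus: str, species: str, marker_raw: str, sequence: str
) -> frozenset[RecordFlag]:
    """Compute the full flag set for one record's fields.

    Total function: any combination of (possibly empty) strings is accepted.

    - ``no_marker``: marker name empty after stripping whitespace.
    - ``no_taxa``: genus or species empty.
    - ``no_seq``: sequence empty.
    - ``name_issue``: the combined name ``"genus species"`` has more than two
      whitespace-separated terms (e.g. "Neotamias sp. 3").
    - ``taxa_digits``: genus or species contains a decimal digit.
    - ``taxa_punct``: genus or species contains punctuation, defined as any
      character that is not a letter, digit, or whitespace (hyphens count).
    """
    flags: set[RecordFlag] = set()
    name = f"{genus} {species}"
    if not marker_raw.strip():
        flags.add(RecordFlag.NO_MARKER)
    if not genus.strip() or not species.strip():
        flags.add(RecordFlag.NO_TAXA)
    if not sequence.strip():
        flags.add(RecordFlag.NO_SEQ)
    if len(name.split()) > 2:
        flags.add(RecordFlag.NAME_ISSUE)
    if any(c.isdigit() for c in name):
        flags.add(RecordFlag.TAXA_DIGITS)
    if any(not (c.isalnum() or c.isspace()) for c in name):
        flags.add(RecordFlag.TAXA_PUNCT)
    return frozenset(flags)


@dataclass(frozen=True)
class UnifiedRecord:
    """One harmonized sequence record: the row type of the total table."""

    uid: str
    accession: str
    source_db: Source
    genus: str
    species: str
    marker_raw: str
    marker_norm: str
    sequence: str
    flags: frozenset[RecordFlag]

    def flags_str(self) -> str:
        if not self.flags:
            return NO_FLAG
        return ";".join(f.value for f in FLAG_ORDER if f in self.flags)


@dataclass
class TotalTable:
    """Ordered accumulation of harmonized records plus fetch provenance."""

    records: list[UnifiedRecord] = field(default_factory=list)
    provenance: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        uids = [r.uid for r in self.records]
        if len(set(uids)) != len(uids):
            dup = next(u for u in uids if uids.count(u) > 1)
            raise ValueError(f"duplicate uid in total table: {dup!r}")

    def __len__(self) -> int:
        return len(self.records)


# Field names a source map may use for each harmonized slot.  BOLD exports
# name the organism column 'species_name' and the sequence 'nucleotides';
# the GenBank marker name may live in the gene, product, or definition field
# (preference order configurable via ``marker_fields``).
_ORGANISM_KEYS = ("organism", "species_name", "taxon")
_SEQ_KEYS = ("seq", "sequence", "nucleotides")
_BOLD_MARKER_KEYS = ("marker", "markercode")
_NCBI_MARKER_KEYS = ("gene", "product", "definition")


def _first_present(raw: Mapping[str, str], keys: Sequence[str]) -> str:
    for k in keys:
        v = raw.get(k)
        if v:
            return str(v)
    return ""


def harmonize_record(
    raw: Mapping[str, str],
    source: Source,
    marker_fields: Sequence[str] | None = None,
) -> UnifiedRecord:
    """Convert one source-specific record map into a :class:`UnifiedRecord`.

    The organism string is split on whitespace: first term becomes the genus,
    the remainder (verbatim, re-joined) the species.  A one-term organism
    yields ``species == ""`` and hence the ``no_taxa`` flag.

    Raises
    ------
    MalformedRecordError
        If the source's identifier field (``processid`` for BOLD,
        ``accession`` for NCBI) is absent or empty.
    """
    source = Source(source)
    id_field = "processid" if source is Source.BOLD else "accession"
    accession = str(raw.get(id_field) or "").strip()
    if not accession:
        raise MalformedRecordError(
            f"{source.value} record is missing identifier field {id_field!r}"
        )

    organism = _first_present(raw, _ORGANISM_KEYS).strip()
    parts = organism.split()
    genus = parts[0] if parts else ""
    species = " ".join(parts[1:])

    if marker_fields is None:
        marker_fields = _BOLD_MARKER_KEYS if source is Source.BOLD else _NCBI_MARKER_KEYS
    marker_raw = _first_present(raw, marker_fields).strip()

    sequence = "".join(_first_present(raw, _SEQ_KEYS).split())

    from .marker_grouping import normalize_marker_name  # deferred: avoids cycle

    marker_norm = normalize_marker_name(marker_raw) if marker_raw.strip() else ""
    return UnifiedRecord(
        uid=f"{source.value}:{accession}",
        accession=accession,
        source_db=source,
        genus=genus,
        species=species,
        marker_raw=marker_raw,
        marker_norm=marker_norm,
        sequence=sequence,
        flags=flag_record(genus, species, marker_raw, sequence),
    )


def dereplicate(records: Iterable[UnifiedRecord]) -> list[UnifiedRecord]:
    """Collapse records sharing an accession, keeping the first occurrence."""
    seen: set[str] = set()
    out: list[UnifiedRecord] = []
    for rec in records:
        if rec.accession in seen:
            continue
        seen.add(rec.accession)
        out.append(rec)
    return out


def _normalize_include(
    include: Mapping[RecordFlag, bool] | None,
) -> dict[RecordFlag, bool]:
    full = {f: False for f in RecordFlag}
    if include:
        for k, v in include.items():
            full[RecordFlag(k)] = bool(v)
    return full


def filter_records(
    table: TotalTable, include: Mapping[RecordFlag, bool] | None = None
) -> list[UnifiedRecord]:
    """Return records whose every carried flag is permitted by ``include``.

    Unflagged records always pass.  Flags absent from ``include`` default to
    False (excluded), matching the source tools' defaults.  The gate is
    conjunctive: a record carrying {no_seq, taxa_digits} is returned only if
    *both* flags are set to True.
    """
    inc = _normalize_include(include)
    return [r for r in table.records if all(inc[f] for f in r.flags)]


_HEADER = (
    "uid",
    "accession",
    "source_db",
    "genus",
    "species",
    "marker_raw",
    "marker_norm",
    "sequence",
    "flags",
)


def write_total_table(table: TotalTable, path) -> None:
    """Serialize the table as UTF-8 TSV with a fixed header row."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_HEADER)
        for r in table.records:
            w.writerow(
                (
                    r.uid,
                    r.accession,
                    r.source_db.value,
                    r.genus,
                    r.species,
                    r.marker_raw,
                    r.marker_norm,
                    r.sequence,
                    r.flags_str(),
                )
            )


def read_total_table(path) -> TotalTable:
    """Parse a total-table TSV; inverse of :func:`write_total_table`.

    Raises :class:`TotalTableParseError` (with the offending 1-based line
    number) on a bad header or a ragged row.
    """
    records: list[UnifiedRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TotalTableParseError("empty file, expected header row", 1) from None
        if tuple(header) != _HEADER:
            raise TotalTableParseError(
                f"bad header {header!r}, expected {list(_HEADER)}", 1
            )
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(_HEADER):
                raise TotalTableParseError(
                    f"expected {len(_HEADER)} columns, found {len(row)}", lineno
                )
            (uid, acc, src, genus, species, m_raw, m_norm, seq, flags_s) = row
            flags = (
                frozenset()
                if flags_s == NO_FLAG
                else frozenset(RecordFlag(v) for v in flags_s.split(";"))
            )
            records.append(
                UnifiedRecord(
                    uid=uid,
                    accession=acc,
                    source_db=Source(src),
                    genus=genus,
                    species=species,
                    marker_raw=m_raw,
                    marker_norm=m_norm,
                    sequence=seq,
                    flags=flags,
                )
            )
    return TotalTable(records=records)
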