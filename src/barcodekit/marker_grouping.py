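"""Marker-name normalization and genus×marker FASTA assembly.

Public databases are inconsistent about marker naming ("COI-5P",
"cytochrome c oxidase subunit I", "CYTOCHROMEOXIDASESUBUNIT1", typos, ...).
The user enumerates the synonyms they accept in a tab-separated parameter
file: one column per output FASTA, the genus in row one and marker-name
synonyms below it.  Matching is exact on normalized names — no fuzzy or
substring matching.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .records import RecordFlag, TotalTable, UnifiedRecord, filter_records

__all__ = [
    "MarkerGroupSpec",
    "ParameterFileError",
    "normalize_marker_name",
    "parse_parameter_file",
    "assemble_fasta_groups",
    "fasta_header",
]

log = logging.getLogger(__name__)

_KEEP = re.compile(r"[^A-Z0-9-]")


class ParameterFileError(ValueError):
    """The marker parameter file is structurally invalid."""


def normalize_marker_name(name: str) -> str:
    """Uppercase ``name`` and strip every character but letters, digits, '-'.

    Idempotent; e.g. "Cytochrome c oxidase subunit I" ->
    "CYTOCHROMECOXIDASESUBUNITI" while "COI-5P" is a fixed point.

    Raises ``ValueError`` if nothing survives normalization.
    """
    cleaned = _KEEP.sub("", name.upper())
    if not cleaned:
        raise ValueError(f"marker name {name!r} is empty after normalization")
    return cleaned


@dataclass(frozen=True)
class MarkerGroupSpec:
    """One genus plus its ordered marker-synonym set; defines one output FASTA."""

    genus: str
    synonyms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genus.strip():
            raise ValueError("MarkerGroupSpec requires a non-empty genus")
        if not self.synonyms:
            raise ValueError(f"genus {self.genus!r}: empty synonym list")
        if len(set(self.synonyms)) != len(self.synonyms):
            raise ValueError(f"genus {self.genus!r}: duplicate synonyms")

    @property
    def output_name(self) -> str:
        """Output file stem: genus + first synonym in the column."""
        return f"{self.genus}_{self.synonyms[0]}"


def parse_parameter_file(path) -> list[MarkerGroupSpec]:
    """Parse a Table-1-style parameter file into one spec per column.

    Layout: tab-separated; row 1 holds the target genus of each column,
    subsequent rows hold marker-name synonyms (cells may be empty; rows may
    be ragged).  Synonyms are normalized and deduplicated preserving order.

    Raises :class:`ParameterFileError` for an empty file or a column that
    names a genus but lists no synonyms.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines()]
    rows = [ln.split("\t") for ln in lines if ln.strip("\t ").strip()]
    if not rows:
        raise ParameterFileError(f"parameter file {path} is empty")
    ncols = max(len(r) for r in rows)
    specs: list[MarkerGroupSpec] = []
    for j in range(ncols):
        genus = rows[0][j].strip() if j < len(rows[0]) else ""
        cells = [r[j].strip() for r in rows[1:] if j < len(r)]
        synonyms: list[str] = []
        for cell in cells:
            if not cell:
                continue
            norm = normalize_marker_name(cell)
            if norm not in synonyms:
                synonyms.append(norm)
        if not genus:
            if synonyms:
                raise ParameterFileError(
                    f"column {j + 1}: marker synonyms present but no genus in row 1"
                )
            continue
        if not synonyms:
            raise ParameterFileError(
                f"column {j + 1} (genus {genus!r}): no marker synonyms listed"
            )
        specs.append(MarkerGroupSpec(genus=genus, synonyms=tuple(synonyms)))
    if not specs:
        raise ParameterFileError(f"parameter file {path} defines no columns")
    return specs


def fasta_header(rec: UnifiedRecord) -> str:
    """Pipe-delimited header so taxonomy survives into downstream stages."""
    return "|".join(
        (rec.uid, rec.accession, rec.genus, rec.species, rec.marker_norm)
    )


def assemble_fasta_groups(
    table: TotalTable,
    specs: list[MarkerGroupSpec],
    include: Mapping[RecordFlag, bool] | None = None,
    out_dir=".",
) -> list[Path]:
    """Write one multi-FASTA per spec from the flag-filtered total table.

    A record lands in a spec's file when its genus matches and its
    ``marker_norm`` is one of the spec's synonyms.  Specs with zero matching
    records produce no file (logged).  Sequences are written unwrapped, one
    record per entry, headers ``uid|accession|genus|species|marker_norm``.

    Returns the list of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    passing = filter_records(table, include)

    # Warn when two specs could claim the same record.
    seen_keys: dict[tuple[str, str], str] = {}
    for spec in specs:
        for syn in spec.synonyms:
            key = (spec.genus, syn)
            if key in seen_keys and seen_keys[key] != spec.output_name:
                log.warning(
                    "synonym %s of genus %s is shared by %s and %s; matching "
                    "records will appear in both files",
                    syn, spec.genus, seen_keys[key], spec.output_name,
                )
            seen_keys.setdefault(key, spec.output_name)

    written: list[Path] = []
    for spec in specs:
        members = [
            r
            for r in passing
            if r.genus == spec.genus and r.marker_norm in spec.synonyms
        ]
        if not members:
            log.info("group %s: no matching records, no file written",
                     spec.output_name)
            continue
        path = out_dir / f"{spec.output_name}.fas"
        with open(path, "w", encoding="utf-8") as fh:
            for rec in members:
                fh.write(f">{fasta_header(rec)}\n{rec.sequence}\n")
        log.info("group %s: wrote %d sequences", spec.output_name, len(members))
        written.append(path)
    return written
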