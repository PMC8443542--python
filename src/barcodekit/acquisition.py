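"""Record acquisition: query building, source fetching, download summaries.

All network access goes through an injectable :class:`Transport`, so the full
pipeline is testable offline by replaying fixture records
(:class:`FixtureTransport`).  :class:`LiveTransport` talks to the real NCBI
E-utilities and BOLD endpoints over plain ``urllib`` with bounded exponential
backoff and a polite inter-request delay.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import time
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Callable, Mapping, Protocol, Sequence

from .records import (
    Source,
    TotalTable,
    UnifiedRecord,
    dereplicate,
    harmonize_record,
    write_total_table,
)

__all__ = [
    "DEFAULT_QUERY_TEMPLATE",
    "DownloadConfig",
    "DownloadSummary",
    "FetchError",
    "BoldParseError",
    "Transport",
    "FixtureTransport",
    "LiveTransport",
    "build_genbank_query",
    "fetch_genbank",
    "fetch_bold",
    "summarize_download",
    "format_summary",
    "run_download",
    "read_genus_list",
]

log = logging.getLogger(__name__)

#: Default GenBank nucleotide query; excludes whole-genome/shotgun records.
DEFAULT_QUERY_TEMPLATE = (
    "({genus}[ORGN]) NOT (shotgun[ALL] OR genome[ALL] OR "
    "assembled[ALL] OR microsatellite[ALL])"
)

# Pagination and politeness defaults (documented, overridable per call).
DEFAULT_PAGE_SIZE = 200
DEFAULT_RETRIES = 3
DEFAULT_DELAY = 0.5  # seconds; base of the exponential backoff


class FetchError(RuntimeError):
    """A source fetch failed after the configured number of retries."""

    def __init__(self, genus: str, query: str, cause: BaseException | None = None):
        super().__init__(
            f"fetch failed for genus {genus!r} (query {query!r}): {cause}"
        )
        self.genus = genus
        self.query = query
        self.cause = cause


class BoldParseError(ValueError):
    """A BOLD-style TSV payload is malformed; carries the 1-based row number."""

    def __init__(self, message: str, row: int):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass
class DownloadConfig:
    genus_list: list[str]
    output_root: Path | str = "."
    use_bold: bool = True
    use_ncbi: bool = True
    search_str: str | None = None

    def __post_init__(self) -> None:
        if not (self.use_bold or self.use_ncbi):
            raise ValueError("at least one of use_bold/use_ncbi must be true")
        if self.search_str is not None and len(self.genus_list) > 1:
            raise ValueError(
                "custom search string: only a single genus at a time can be searched"
            )


def build_genbank_query(genus: str, custom: str | None = None) -> str:
    """Return the GenBank query for one genus.

    With ``custom=None`` the default template is filled with the genus;
    otherwise ``custom`` is returned verbatim.
    """
    if custom is not None:
        return custom
    if not genus.strip():
        raise ValueError("genus must be non-empty when no custom query is given")
    return DEFAULT_QUERY_TEMPLATE.format(genus=genus)


class Transport(Protocol):
    """Search/fetch primitives each source needs; live HTTP or fixture replay."""

    def genbank_search(
        self, genus: str, query: str, retstart: int, retmax: int
    ) -> tuple[list[str], int]:
        """Return (record ids in [retstart, retstart+retmax), total count)."""

    def genbank_fetch(self, ids: Sequence[str]) -> list[dict]:
        """Return source-specific record maps for the given ids."""

    def bold_tsv(self, genus: str) -> str:
        """Return the raw BOLD-style TSV payload for one genus."""


class FixtureTransport:
    """Replays stored records; the offline stand-in for live endpoints."""

    def __init__(
        self,
        genbank: Mapping[str, Sequence[dict]] | None = None,
        bold: Mapping[str, str] | None = None,
    ):
        self._genbank = {g: list(recs) for g, recs in (genbank or {}).items()}
        self._bold = dict(bold or {})
        self._by_id = {
            rec["accession"]: rec
            for recs in self._genbank.values()
            for rec in recs
        }

    def genbank_search(self, genus, query, retstart, retmax):
        ids = [r["accession"] for r in self._genbank.get(genus, [])]
        return ids[retstart : retstart + retmax], len(ids)

    def genbank_fetch(self, ids):
        return [dict(self._by_id[i]) for i in ids]

    def bold_tsv(self, genus):
        return self._bold.get(genus, "processid\torganism\tmarker\tseq\n")


class LiveTransport:
    """Plain-``urllib`` client for NCBI E-utilities and the BOLD public API.

    Exercised only in live runs; every test replays fixtures instead.
    """

    EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"
    BOLD = "https://www.boldsystems.org/index.php/API_Public/combined"

    def __init__(self, email: str | None = None, timeout: float = 60.0):
        self.email = email
        self.timeout = timeout

    def _get(self, url: str) -> bytes:
        import urllib.request

        with urllib.request.urlopen(url, timeout=self.timeout) as resp:
            return resp.read()

    def genbank_search(self, genus, query, retstart, retmax):
        import urllib.parse

        params = urllib.parse.urlencode(
            {
                "db": "nucleotide",
                "term": query,
                "retstart": retstart,
                "retmax": retmax,
                "retmode": "json",
            }
        )
        payload = json.loads(self._get(f"{self.EUTILS}/esearch.fcgi?{params}"))
        res = payload["esearchresult"]
        return list(res.get("idlist", [])), int(res.get("count", 0))

    def genbank_fetch(self, ids):
        import urllib.parse

        from Bio import SeqIO

        params = urllib.parse.urlencode(
            {
                "db": "nucleotide",
                "id": ",".join(ids),
                "rettype": "gb",
                "retmode": "text",
            }
        )
        text = self._get(f"{self.EUTILS}/efetch.fcgi?{params}").decode()
        out = []
        for gb in SeqIO.parse(io.StringIO(text), "genbank"):
            gene = product = ""
            for feat in gb.features:
                gene = gene or "".join(feat.qualifiers.get("gene", [""])[:1])
                product = product or "".join(feat.qualifiers.get("product", [""])[:1])
            out.append(
                {
                    "accession": gb.id,
                    "organism": gb.annotations.get("organism", ""),
                    "gene": gene,
                    "product": product,
                    "definition": gb.description,
                    "sequence": str(gb.seq),
                }
            )
        return out

    def bold_tsv(self, genus):
        import urllib.parse

        params = urllib.parse.urlencode({"taxon": genus, "format": "tsv"})
        return self._get(f"{self.BOLD}?{params}").decode(errors="replace")


def _with_retries(
    fn: Callable, genus: str, query: str, retries: int, delay: float
):
    last: BaseException | None = None
    for attempt in range(retries):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 — transports raise arbitrarily
            last = exc
            log.warning("fetch attempt %d/%d failed: %s", attempt + 1, retries, exc)
            if attempt + 1 < retries and delay > 0:
                time.sleep(delay * 2**attempt)
    raise FetchError(genus, query, last)


def fetch_genbank(
    genus: str,
    query: str,
    transport: Transport,
    page_size: int = DEFAULT_PAGE_SIZE,
    retries: int = DEFAULT_RETRIES,
    delay: float = DEFAULT_DELAY,
) -> list[dict]:
    """Fetch all GenBank-style records matching ``query``, paginating until
    exhaustion.  An empty result is an empty list, not an error."""
    records: list[dict] = []
    retstart = 0
    while True:
        ids, total = _with_retries(
            lambda: transport.genbank_search(genus, query, retstart, page_size),
            genus, query, retries, delay,
        )
        if not ids:
            break
        records.extend(
            _with_retries(
                lambda: transport.genbank_fetch(ids), genus, query, retries, delay
            )
        )
        retstart += len(ids)
        if retstart >= total:
            break
    return records


def parse_bold_tsv(text: str) -> list[dict]:
    """Parse a BOLD-style TSV payload into record maps.

    Raises :class:`BoldParseError` naming the first ragged data row.
    """
    reader = csv.reader(io.StringIO(text), delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        return []
    out: list[dict] = []
    for rowno, row in enumerate(reader, start=2):
        if not any(cell.strip() for cell in row):
            continue  # tolerate trailing blank line(s)
        if len(row) != len(header):
            raise BoldParseError(
                f"expected {len(header)} fields, found {len(row)}", rowno
            )
        out.append(dict(zip(header, row)))
    return out


def fetch_bold(
    genus: str,
    transport: Transport,
    retries: int = DEFAULT_RETRIES,
    delay: float = DEFAULT_DELAY,
    raw_path: Path | str | None = None,
) -> list[dict]:
    """Fetch and parse BOLD-style records for one genus.

    When ``raw_path`` is given the raw TSV payload is persisted verbatim
    before parsing.
    """
    text = _with_retries(
        lambda: transport.bold_tsv(genus), genus, "<bold>", retries, delay
    )
    if raw_path is not None:
        Path(raw_path).write_text(text, encoding="utf-8")
    return parse_bold_tsv(text)


@dataclass
class GenusSummary:
    species: list[str] = field(default_factory=list)
    marker_counts: dict[str, int] = field(default_factory=dict)
    source_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class DownloadSummary:
    per_genus: dict[str, GenusSummary] = field(default_factory=dict)

    @property
    def total_records(self) -> int:
        return sum(
            sum(g.source_counts.values()) for g in self.per_genus.values()
        )


def summarize_download(table: TotalTable) -> DownloadSummary:
    """Tally the total table per genus: unique species, marker counts, and
    record counts per source.  Counts always sum to ``len(table.records)``."""
    summary = DownloadSummary()
    for rec in table.records:
        g = summary.per_genus.setdefault(rec.genus, GenusSummary())
        if rec.species and rec.species not in g.species:
            g.species.append(rec.species)
        if rec.marker_norm:
            g.marker_counts[rec.marker_norm] = g.marker_counts.get(rec.marker_norm, 0) + 1
        g.source_counts[rec.source_db.value] = (
            g.source_counts.get(rec.source_db.value, 0) + 1
        )
    for g in summary.per_genus.values():
        g.species.sort()
    return summary


def format_summary(summary: DownloadSummary) -> str:
    lines: list[str] = []
    for genus in sorted(summary.per_genus):
        g = summary.per_genus[genus]
        lines.append(f"Genus: {genus}")
        lines.append(
            "  Records: "
            + ", ".join(f"{src}={n}" for src, n in sorted(g.source_counts.items()))
        )
        lines.append("  Species: " + (", ".join(g.species) or "(none)"))
        lines.append(
            "  Markers: "
            + (
                ", ".join(
                    f"{m}={n}" for m, n in sorted(g.marker_counts.items())
                )
                or "(none)"
            )
        )
        lines.append("")
    return "\n".join(lines)


def read_genus_list(path) -> list[str]:
    """One genus per line; blank lines (incl. a trailing one) are tolerated."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


@dataclass
class DownloadResult:
    table: TotalTable
    summary: DownloadSummary
    run_dir: Path


def run_download(
    config: DownloadConfig,
    transport: Transport,
    run_name: str | None = None,
    retries: int = DEFAULT_RETRIES,
    delay: float = DEFAULT_DELAY,
) -> DownloadResult:
    """Fetch every configured source for every genus and write the run folder.

    Layout: ``<output_root>/<run_name>/{BOLD,NCBI,Total_tables}`` with
    ``Total_tables/A_Summary.txt`` and ``Total_tables/A_Total_Table.dat``.
    The default ``run_name`` is timestamped (``Seq_auto_dl_HHMMSS_Mon_DD``);
    pass an explicit name for reproducible layouts.
    """
    if run_name is None:
        run_name = datetime.now().strftime("Seq_auto_dl_%H%M%S_%b_%d")
    run_dir = Path(config.output_root) / run_name
    bold_dir = run_dir / "BOLD"
    ncbi_dir = run_dir / "NCBI"
    tables_dir = run_dir / "Total_tables"
    for d in (bold_dir, ncbi_dir, tables_dir):
        d.mkdir(parents=True, exist_ok=True)

    records: list[UnifiedRecord] = []
    provenance: dict[str, dict] = {}
    for genus in config.genus_list:
        if config.use_bold:
            raw = fetch_bold(
                genus, transport, retries=retries, delay=delay,
                raw_path=bold_dir / f"{genus}.tsv",
            )
            records.extend(harmonize_record(r, Source.BOLD) for r in raw)
            provenance.setdefault("BOLD", {"genera": []})["genera"].append(genus)
        if config.use_ncbi:
            query = build_genbank_query(genus, config.search_str)
            raw = fetch_genbank(
                genus, query, transport, retries=retries, delay=delay
            )
            (ncbi_dir / f"{genus}.json").write_text(
                json.dumps(raw, indent=1), encoding="utf-8"
            )
            records.extend(harmonize_record(r, Source.NCBI) for r in raw)
            provenance.setdefault("NCBI", {"queries": []})["queries"].append(query)

    table = TotalTable(records=dereplicate(records), provenance=provenance)
    summary = summarize_download(table)
    write_total_table(table, tables_dir / "A_Total_Table.dat")
    (tables_dir / "A_Summary.txt").write_text(
        format_summary(summary), encoding="utf-8"
    )
    return DownloadResult(table=table, summary=summary, run_dir=run_dir)
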