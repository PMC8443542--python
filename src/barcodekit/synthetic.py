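"""Deterministic synthetic datasets with known ground truth.

Every pipeline stage is testable offline against fixtures produced here: a
random ancestor barcode sequence is mutated per-site to create a cohort of
conspecific-like "clean" records, plus planted anomalies — a highly divergent
outlier, records carrying IUPAC ambiguity codes, records carrying stop codons
in all three reading frames, and records with internal insertions.  The
generator records the expected flag for every record, so truth recovery can
be asserted exactly.

Mutations are drawn uniformly over the three alternative bases (no
transition/transversion bias); fixtures do not emulate tree-structured
evolution, rate heterogeneity, or sequencing chemistry artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .align_trim import MSA
from .cleaning import FLAG_GENUS, FLAG_NON_AGCT, FLAG_NONE, FLAG_STOP

__all__ = ["FixtureSpec", "FixtureTruth", "Fixture", "SourceFixtures",
           "generate_fixture", "make_source_fixtures"]

_BASES = np.array(list("ACGT"))

# Stop motif: TAA at offsets 0, 4 and 8, so that when written at a position
# divisible by 3 every forward reading frame of the full sequence contains a
# complete TAA codon (a stop under the standard, vertebrate- and
# invertebrate-mitochondrial codes alike).
_STOP_MOTIF = "TAAGTAAGTAAG"

# Codons that are a stop under at least one of the three supported genetic
# codes.  Clean records are kept open-reading-frame in frame 1 by excluding
# these from the ancestor and reverting any mutation that creates one, the
# way a real protein-coding barcode stays translatable.
_FORBIDDEN_CODONS = frozenset({"TAA", "TAG", "TGA", "AGA", "AGG"})
_SAFE_CODONS = np.array(
    sorted(
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in _FORBIDDEN_CODONS
    )
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Defaults describe a small single-genus barcode cohort: ten clean records
    diverging ~1% per site from a common ancestor over 120 sites, one planted
    outlier at 30% divergence, one ambiguity-bearing and one stop-bearing
    record, split across two species.
    """

    seed: int = 0
    n_clean: int = 10
    seq_len: int = 120
    background_divergence: float = 0.01
    n_outliers: int = 1
    outlier_divergence: float = 0.30
    n_ambig: int = 1
    n_stop: int = 1
    n_insertion: int = 0
    insertion_len: int = 3
    species_partition: tuple[int, ...] | None = None
    species_divergence: float = 0.05
    genus: str = "Simulomys"
    marker: str = "COI-5P"
    pigl: float = 0.95
    flag_violations: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = (self.n_clean, self.n_outliers, self.n_ambig, self.n_stop,
                  self.n_insertion)
        if any(c < 0 for c in counts):
            raise ValueError("all record counts must be >= 0")
        if self.n_outliers and not (
            self.outlier_divergence > self.background_divergence
        ):
            raise ValueError(
                "outlier_divergence must exceed background_divergence"
            )
        if self.n_stop and self.seq_len < len(_STOP_MOTIF):
            raise ValueError(
                f"seq_len must be >= {len(_STOP_MOTIF)} to plant stop codons "
                "in all three frames"
            )
        if self.species_partition is not None and (
            sum(self.species_partition) != self.n_clean
        ):
            raise ValueError("species_partition must sum to n_clean")
        if self.n_insertion:
            if self.insertion_len % 3 != 0 or self.insertion_len < 3:
                raise ValueError(
                    "insertion_len must be a positive multiple of 3 so that "
                    "insertion carriers stay translatable"
                )
            if self.seq_len < 9:
                raise ValueError("seq_len too short to place internal insertions")

    def resolved_partition(self) -> tuple[int, ...]:
        if self.species_partition is not None:
            return tuple(self.species_partition)
        if self.n_clean == 0:
            return ()
        if self.n_clean < 4:
            return (self.n_clean,)
        half = self.n_clean // 2
        return (self.n_clean - half, half)


@dataclass
class FixtureTruth:
    """Ground truth bundled with a fixture."""

    expected_flags: dict[str, str]
    trimmed_length: int
    removed_by_trim: list[str]


@dataclass
class Fixture:
    records: list[tuple[str, str]]  # (header, unaligned sequence)
    reference: tuple[str, str]
    aligned: MSA  # pre-gapped alignment including the reference row
    truth: FixtureTruth

    def write(self, out_dir) -> dict[str, Path]:
        """Emit records FASTA, reference FASTA, aligned FASTA, truth JSON."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "records": out_dir / "records.fas",
            "reference": out_dir / "reference.fas",
            "aligned": out_dir / "aligned.fas",
            "truth": out_dir / "truth.json",
        }
        with open(paths["records"], "w", encoding="utf-8") as fh:
            for header, seq in self.records:
                fh.write(f">{header}\n{seq}\n")
        with open(paths["reference"], "w", encoding="utf-8") as fh:
            fh.write(f">{self.reference[0]}\n{self.reference[1]}\n")
        self.aligned.to_fasta(paths["aligned"])
        paths["truth"].write_text(
            json.dumps(
                {
                    "expected_flags": self.truth.expected_flags,
                    "trimmed_length": self.truth.trimmed_length,
                    "removed_by_trim": self.truth.removed_by_trim,
                },
                indent=1,
            ),
            encoding="utf-8",
        )
        return paths


def _random_orf(seq_len: int, rng: np.random.Generator) -> np.ndarray:
    """Random sequence with no frame-1 stop codon under any supported code."""
    n_codons, tail = divmod(seq_len, 3)
    codons = rng.choice(_SAFE_CODONS, size=n_codons)
    chars = list("".join(codons)) + list(rng.choice(_BASES, size=tail))
    return np.array(chars)


def _mutate(
    seq: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    parent: np.ndarray | None = None,
) -> np.ndarray:
    """Substitute exactly ``round(rate * len)`` sites, chosen uniformly.

    Fixing the substitution count (rather than thinning per site) makes each
    derived record's divergence exactly the nominal rate, so group-level
    distance summaries are homogeneous by construction.  Each hit site is
    replaced by one of the three alternative bases uniformly.  When
    ``parent`` is given, any frame-1 codon the substitutions turn into a
    stop (under any supported code) is reverted to the parental codon, so
    derived records remain translatable like a real protein-coding barcode.
    """
    out = seq.copy()
    n_sub = int(round(rate * seq.size))
    hits = rng.choice(seq.size, size=min(n_sub, seq.size), replace=False)
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    if parent is not None:
        for k in range(seq.size // 3):
            codon = "".join(out[3 * k : 3 * k + 3])
            if codon in _FORBIDDEN_CODONS:
                out[3 * k : 3 * k + 3] = parent[3 * k : 3 * k + 3]
    return out


def _header(spec: FixtureSpec, role: str, k: int, species: str) -> str:
    acc = f"SYN{role[0].upper()}{k:03d}"
    return f"fx:{acc}|{acc}|{spec.genus}|{species}|{spec.marker}"


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build one synthetic dataset; same spec and seed -> identical bytes.

    Each species descends from its own founder haplotype: the first species'
    founder is the ancestor itself, later founders diverge from it by
    ``species_divergence``, giving the cohort a genuine barcode gap.  Clean
    records substitute exactly ``background_divergence x seq_len`` sites of
    their founder; outliers diverge from the ancestor at
    ``outlier_divergence``; ambiguity records additionally carry one to three
    'N's; stop records carry an in-frame stop codon in all three forward
    frames; insertion records carry ``insertion_len`` extra bases at a random
    internal position.  The pre-gapped alignment places '-' in every
    non-carrier row (reference included) under each insertion.
    """
    rng = np.random.default_rng(spec.seed)
    ancestor = _random_orf(spec.seq_len, rng)

    partition = spec.resolved_partition()
    species_names = [f"species{chr(ord('a') + i)}" for i in range(len(partition))]
    founders = {}
    for i, name in enumerate(species_names):
        founders[name] = (
            ancestor
            if i == 0
            else _mutate(ancestor, spec.species_divergence, rng, ancestor)
        )
    clean_species: list[str] = []
    for name, size in zip(species_names, partition):
        clean_species.extend([name] * size)
    anomaly_species = species_names[0] if species_names else "speciesa"
    anomaly_founder = founders.get(anomaly_species, ancestor)

    headers: list[str] = []
    seqs: list[str] = []
    expected: dict[str, str] = {}
    insertions: list[tuple[str, int, str]] = []  # (header, position, bases)

    for k in range(spec.n_clean):
        h = _header(spec, "clean", k + 1, clean_species[k])
        founder = founders[clean_species[k]]
        seq = _mutate(founder, spec.background_divergence, rng, founder)
        headers.append(h)
        seqs.append("".join(seq))
        expected[h] = FLAG_NONE

    for k in range(spec.n_outliers):
        h = _header(spec, "outlier", k + 1, anomaly_species)
        seq = _mutate(ancestor, spec.outlier_divergence, rng, ancestor)
        headers.append(h)
        seqs.append("".join(seq))
        expected[h] = FLAG_GENUS

    for k in range(spec.n_ambig):
        h = _header(spec, "ambig", k + 1, anomaly_species)
        seq = _mutate(anomaly_founder, spec.background_divergence, rng,
                      anomaly_founder)
        n_amb = int(rng.integers(1, 4))
        pos = rng.choice(spec.seq_len, size=min(n_amb, spec.seq_len), replace=False)
        seq[pos] = "N"
        headers.append(h)
        seqs.append("".join(seq))
        expected[h] = FLAG_NON_AGCT

    for k in range(spec.n_stop):
        h = _header(spec, "stop", k + 1, anomaly_species)
        seq = _mutate(anomaly_founder, spec.background_divergence, rng,
                      anomaly_founder)
        start_max = (spec.seq_len - len(_STOP_MOTIF)) // 3
        p = 3 * int(rng.integers(0, start_max + 1))
        seq[p : p + len(_STOP_MOTIF)] = list(_STOP_MOTIF)
        headers.append(h)
        seqs.append("".join(seq))
        expected[h] = FLAG_STOP

    for k in range(spec.n_insertion):
        h = _header(spec, "insert", k + 1, anomaly_species)
        seq = _mutate(anomaly_founder, spec.background_divergence, rng,
                      anomaly_founder)
        # Codon-aligned internal position + stop-free codons: the carrier's
        # full sequence stays translatable.
        pos = 3 * int(rng.integers(1, spec.seq_len // 3))
        bases = "".join(rng.choice(_SAFE_CODONS, size=spec.insertion_len // 3))
        headers.append(h)
        seqs.append("".join(seq[:pos]) + bases + "".join(seq[pos:]))
        insertions.append((h, pos, bases))
        expected[h] = FLAG_NONE

    ref_header = f"{spec.genus}_reference"
    ref_seq = "".join(ancestor)

    # Pre-gapped alignment: one extra column block per insertion event, gap
    # everywhere except in the carrier row.
    events = sorted(insertions, key=lambda e: e[1])
    n_records = len(headers)
    n_rows_no_ref = n_records

    def gapped(seq_str: str, carrier: str | None) -> str:
        out = []
        cursor = 0
        base_seq = seq_str
        for h, pos, bases in events:
            out.append(base_seq[cursor:pos])
            out.append(bases if h == carrier else "-" * len(bases))
            cursor = pos
        out.append(base_seq[cursor:])
        return "".join(out)

    aligned_ids = [ref_header]
    aligned_rows = [gapped(ref_seq, None)]
    for h, seq_str in zip(headers, seqs):
        base = seq_str
        if any(h == eh for eh, _, _ in events):
            # Carrier: strip its own insertion, then rebuild the gapped row
            # placing its bases into its own column block.
            _, pos, bases = next(e for e in events if e[0] == h)
            base = seq_str[:pos] + seq_str[pos + len(bases):]
            row_parts = []
            cursor = 0
            for e in events:
                row_parts.append(base[cursor:e[1]])
                row_parts.append(bases if e[0] == h else "-" * len(e[2]))
                cursor = e[1]
            row_parts.append(base[cursor:])
            row = "".join(row_parts)
        else:
            row = gapped(base, None)
        aligned_ids.append(h)
        aligned_rows.append(row)
    aligned = MSA(ids=aligned_ids, rows=aligned_rows, ref_id=ref_header)

    # Truth for the trimming stage.  Every record fully covers the reference
    # span; an insertion column is gap in (n-1)/n of the non-reference rows
    # and removes its carrier when that fraction strictly exceeds pigl.
    removed_by_trim: list[str] = []
    extra_cols = 0
    if events:
        frac = (n_rows_no_ref - 1) / n_rows_no_ref if n_rows_no_ref else 0.0
        if spec.pigl > 0 and frac > spec.pigl:
            removed_by_trim = [h for h, _, _ in events]
        else:
            extra_cols = sum(len(b) for _, _, b in events)
    truth = FixtureTruth(
        expected_flags=expected,
        trimmed_length=spec.seq_len + extra_cols,
        removed_by_trim=removed_by_trim,
    )
    return Fixture(
        records=list(zip(headers, seqs)),
        reference=(ref_header, ref_seq),
        aligned=aligned,
        truth=truth,
    )


@dataclass
class SourceFixtures:
    """The same records serialized in both source shapes."""

    bold_tsv: str
    genbank_records: list[dict]
    expected_flags: dict[str, set[str]]  # accession -> record-level flag names


_VIOLATIONS = {
    "no_marker": {"marker": ""},
    "no_seq": {"seq": ""},
    "no_taxa": {"organism": "{genus}"},
    "name_issue": {"organism": "{genus} cf species extra"},
    "taxa_digits": {"organism": "{genus} minimus2"},
    "taxa_punct": {"organism": "{genus} min-imus"},
}


def make_source_fixtures(spec: FixtureSpec) -> SourceFixtures:
    """Serialize a fixture's records as a BOLD-style TSV and GenBank-style
    record maps, optionally planting records that violate each flag rule.

    ``spec.flag_violations`` maps a flag name to the number of records that
    should trigger exactly that flag (mostly — ``name_issue`` examples use
    extra clean terms, ``taxa_digits``/``taxa_punct`` a single offending
    character).  Violations are applied to distinct records in order.
    """
    fixture = generate_fixture(spec)
    rows: list[dict] = []
    expected: dict[str, set[str]] = {}
    for header, seq in fixture.records:
        _, acc, genus, species, marker = header.split("|")
        rows.append(
            {
                "accession": acc,
                "organism": f"{genus} {species}",
                "marker": marker,
                "seq": seq,
            }
        )
        expected[acc] = set()

    idx = 0
    for flag_name, count in spec.flag_violations.items():
        if flag_name not in _VIOLATIONS:
            raise ValueError(f"unknown flag violation {flag_name!r}")
        for _ in range(count):
            if idx >= len(rows):
                raise ValueError("more violations requested than records exist")
            row = rows[idx]
            for key, template in _VIOLATIONS[flag_name].items():
                row[key] = template.format(genus=spec.genus)
            expected[row["accession"]].add(flag_name)
            idx += 1

    header_cols = ("processid", "organism", "marker", "seq")
    tsv_lines = ["\t".join(header_cols)]
    for row in rows:
        tsv_lines.append(
            "\t".join((row["accession"], row["organism"], row["marker"], row["seq"]))
        )
    bold_tsv = "\n".join(tsv_lines) + "\n"

    genbank_records = [
        {
            "accession": row["accession"],
            "organism": row["organism"],
            "gene": row["marker"],
            "sequence": row["seq"],
        }
        for row in rows
    ]
    return SourceFixtures(
        bold_tsv=bold_tsv,
        genbank_records=genbank_records,
        expected_flags=expected,
    )
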