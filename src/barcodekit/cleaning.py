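"""Alignment cleaning: p-distances, outlier flagging, translation screening,
AGCT filtering, and barcode-gap reporting.

The cleaning pipeline takes a trimmed multiple sequence alignment and assigns
each record exactly one flag:

``non_AGCT``
    the sequence contains residues outside {A, C, G, T} (IUPAC ambiguity
    codes); alignment gaps are ignored — they are artifacts, not residues.
``Stop_Codon``
    no forward reading frame of the degapped sequence is free of stop codons
    under the selected genetic code (standard, vertebrate-mitochondrial, or
    invertebrate-mitochondrial).
``Genus_Outlier`` / ``Species_Outlier``
    the record's mean pairwise p-distance to its genus (resp. species) group
    exceeds 1.5x the group's mean (the multiplier and the thresholding
    method are configurable).  Genus-level flagging runs first;
    species-level flagging is evaluated on the records that remain.
``-``
    retained.

p-distances use pairwise deletion: per pair, only positions where both rows
hold an unambiguous A/C/G/T are compared.  The barcode gap per species is the
separation between its largest intraspecific distance and its smallest
distance to any other species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

from .align_trim import MSA

__all__ = [
    "DistanceMatrix",
    "GeneticCode",
    "GENETIC_CODES",
    "CleanConfig",
    "CleanResult",
    "BarcodeGapRow",
    "p_distance_matrix",
    "flag_distance_outliers",
    "translation_check",
    "agct_check",
    "barcode_gap_report",
    "clean_dataset",
    "clean_file",
    "clean_folder",
    "parse_taxonomy_from_header",
]

log = logging.getLogger(__name__)

GAP = "-"
_ACGT = frozenset("ACGT")

FLAG_NON_AGCT = "non_AGCT"
FLAG_STOP = "Stop_Codon"
FLAG_GENUS = "Genus_Outlier"
FLAG_SPECIES = "Species_Outlier"
FLAG_NONE = "-"


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map (64 entries; stop codons map to '*')."""

    name: str
    table: Mapping[str, str]

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.table.items() if aa == "*")


def _code_from_ncbi(name: str, table_id: int) -> GeneticCode:
    t = CodonTable.unambiguous_dna_by_id[table_id]
    table = dict(t.forward_table)
    for stop in t.stop_codons:
        table[stop] = "*"
    assert len(table) == 64
    return GeneticCode(name=name, table=table)


#: std = NCBI table 1, vert = vertebrate mitochondrial (2),
#: invert = invertebrate mitochondrial (5).
GENETIC_CODES: dict[str, GeneticCode] = {
    "std": _code_from_ncbi("std", 1),
    "vert": _code_from_ncbi("vert", 2),
    "invert": _code_from_ncbi("invert", 5),
}


@dataclass(frozen=True)
class CleanConfig:
    """Cleaning parameters.

    ``aa_code``: genetic code for stop-codon screening ("off" disables);
    invertebrate mitochondrial by default, as appropriate for COI-5P barcodes
    of most animal datasets.  ``agct_only``: reject sequences containing
    IUPAC ambiguity codes.  ``outlier_multiplier``: the 1.5 in "greater than
    1.5x pairwise sequence distance".  ``outlier_method``: how the threshold
    is formed — "ratio" (default) flags a record whose summary distance
    exceeds multiplier x the group's mean summary distance, the literal
    multiplicative reading of the rule; "tukey" instead uses the fence
    Q3 + multiplier x IQR over the summaries.  ``min_group_size``: smallest
    group on which outlier detection runs (thresholds from 2-3 points are
    unstable).  ``outlier_statistic``: per-record summary of within-group
    distances, "mean" (default) or "median".
    """

    aa_code: str = "invert"
    agct_only: bool = True
    outlier_multiplier: float = 1.5
    min_group_size: int = 4
    outlier_method: str = "ratio"
    outlier_statistic: str = "mean"

    def __post_init__(self) -> None:
        if self.aa_code not in ("std", "vert", "invert", "off"):
            raise ValueError("aa_code must be std, vert, invert, or off")
        if self.outlier_multiplier <= 0:
            raise ValueError("outlier_multiplier must be positive")
        if self.min_group_size < 2:
            raise ValueError("min_group_size must be >= 2")
        if self.outlier_method not in ("ratio", "tukey"):
            raise ValueError("outlier_method must be 'ratio' or 'tukey'")
        if self.outlier_statistic not in ("mean", "median"):
            raise ValueError("outlier_statistic must be 'mean' or 'median'")


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with per-pair compared-site counts.

    ``d`` holds NaN where a pair shares zero comparable sites.
    """

    ids: list[str]
    d: np.ndarray
    n_sites: np.ndarray

    def submatrix(self, keep_ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in keep_ids]
        return DistanceMatrix(
            ids=list(keep_ids),
            d=self.d[np.ix_(idx, idx)].copy(),
            n_sites=self.n_sites[np.ix_(idx, idx)].copy(),
        )

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t" + "\t".join(self.ids) + "\n")
            for i, sid in enumerate(self.ids):
                cells = [
                    "NA" if np.isnan(v) else f"{v:.6f}" for v in self.d[i]
                ]
                fh.write(sid + "\t" + "\t".join(cells) + "\n")


def p_distance_matrix(msa: MSA) -> DistanceMatrix:
    """All-pairs p-distance under pairwise deletion.

    Compared sites for a pair are the positions where *both* rows hold an
    unambiguous A/C/G/T (case-insensitive); the distance is mismatches over
    compared sites, NaN when no site is comparable.
    """
    if len(msa) < 2:
        raise ValueError("p_distance_matrix requires at least 2 sequences")
    arr = np.array([list(r.upper()) for r in msa.rows])
    valid = np.isin(arr, list(_ACGT))
    n = len(msa)
    d = np.zeros((n, n), dtype=float)
    sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        sites[i, i] = int(valid[i].sum())
        for j in range(i + 1, n):
            comp = valid[i] & valid[j]
            m = int(comp.sum())
            sites[i, j] = sites[j, i] = m
            if m == 0:
                d[i, j] = d[j, i] = np.nan
            else:
                mism = int(((arr[i] != arr[j]) & comp).sum())
                d[i, j] = d[j, i] = mism / m
    return DistanceMatrix(ids=list(msa.ids), d=d, n_sites=sites)


def _group_means(
    dm: DistanceMatrix, members: Sequence[int], statistic: str
) -> dict[int, float]:
    """Per-member summary distance to the other group members (NaN-aware).

    Members with no defined distance to any other member get NaN.
    """
    out: dict[int, float] = {}
    for i in members:
        others = [j for j in members if j != i]
        vals = dm.d[i, others]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            out[i] = float("nan")
        elif statistic == "median":
            out[i] = float(np.median(vals))
        else:
            out[i] = float(np.mean(vals))
    return out


def flag_distance_outliers(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    multiplier: float = 1.5,
    min_group_size: int = 4,
    statistic: str = "mean",
    method: str = "ratio",
) -> set[str]:
    """Identify distance outliers within groups.

    Within each group of at least ``min_group_size`` members, each member's
    mean (or median, per ``statistic``) pairwise distance to the other group
    members is computed, missing pairs excluded.  The threshold is then:

    - ``method="ratio"`` (default): multiplier x the group's mean summary —
      a record more than 1.5x as distant as the group typically is from
      itself is an outlier;
    - ``method="tukey"``: the fence Q3 + multiplier x IQR of the summaries
      (quartiles by linear interpolation).

    Members strictly above the threshold are returned; groups smaller than
    ``min_group_size`` contribute no outliers.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    if method not in ("ratio", "tukey"):
        raise ValueError("method must be 'ratio' or 'tukey'")
    by_group: dict[str, list[int]] = {}
    for i, sid in enumerate(dm.ids):
        by_group.setdefault(groups[sid], []).append(i)

    outliers: set[str] = set()
    for members in by_group.values():
        if len(members) < min_group_size:
            continue
        means = _group_means(dm, members, statistic)
        defined = [i for i in members if not np.isnan(means[i])]
        if len(defined) < 2:
            continue
        vals = np.array([means[i] for i in defined])
        if method == "ratio":
            threshold = multiplier * float(np.mean(vals))
        else:
            q1, q3 = np.percentile(vals, [25, 75])
            threshold = q3 + multiplier * (q3 - q1)
        for i in defined:
            if means[i] > threshold:
                outliers.add(dm.ids[i])
    return outliers


def agct_check(sequence: str) -> bool:
    """True iff every non-gap character is an unambiguous A/C/G/T."""
    return all(c in _ACGT for c in sequence.upper() if c != GAP)


def translation_check(sequence: str, code: GeneticCode) -> bool:
    """True iff some forward frame of the degapped sequence is stop-free.

    All three forward frames are translated; codons containing a non-AGCT
    character are skipped.  A frame counts only if it holds at least one
    complete codon.  Sequences shorter than one codon after degapping fail.
    """
    seq = sequence.upper().replace(GAP, "")
    if len(seq) < 3:
        log.info("translation check: degapped length %d < 3, failing", len(seq))
        return False
    for frame in range(3):
        n_codons = (len(seq) - frame) // 3
        if n_codons < 1:
            continue
        has_stop = False
        for k in range(n_codons):
            codon = seq[frame + 3 * k : frame + 3 * k + 3]
            if set(codon) - _ACGT:
                continue
            if code.table[codon] == "*":
                has_stop = True
                break
        if not has_stop:
            return True
    return False


@dataclass
class BarcodeGapRow:
    species: str
    n: int
    max_intra: float | None
    min_inter: float | None
    gap_present: bool | None


def barcode_gap_report(
    dm: DistanceMatrix, species: Mapping[str, str]
) -> list[BarcodeGapRow]:
    """Per-species barcode-gap summary.

    ``max_intra`` is the largest conspecific distance (missing when the
    species has fewer than two members or no comparable conspecific pair);
    ``min_inter`` the smallest distance to any other species;
    ``gap_present`` = min_inter > max_intra when both are defined.
    """
    by_sp: dict[str, list[int]] = {}
    for i, sid in enumerate(dm.ids):
        by_sp.setdefault(species[sid], []).append(i)

    rows: list[BarcodeGapRow] = []
    for sp in sorted(by_sp):
        members = by_sp[sp]
        others = [i for i in range(len(dm.ids)) if i not in set(members)]
        intra = [
            dm.d[i, j]
            for a, i in enumerate(members)
            for j in members[a + 1 :]
            if not np.isnan(dm.d[i, j])
        ]
        inter = [
            dm.d[i, j]
            for i in members
            for j in others
            if not np.isnan(dm.d[i, j])
        ]
        max_intra = float(max(intra)) if intra else None
        min_inter = float(min(inter)) if inter else None
        gap = (
            bool(min_inter > max_intra)
            if (max_intra is not None and min_inter is not None)
            else None
        )
        rows.append(
            BarcodeGapRow(
                species=sp,
                n=len(members),
                max_intra=max_intra,
                min_inter=min_inter,
                gap_present=gap,
            )
        )
    return rows


@dataclass
class CleanResult:
    flags: dict[str, str]
    retained: MSA
    distance_matrix: DistanceMatrix | None
    gap_rows: list[BarcodeGapRow]
    log_lines: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.flags.values():
            out[f] = out.get(f, 0) + 1
        return out


def clean_dataset(
    msa: MSA,
    taxonomy: Mapping[str, tuple[str, str]],
    config: CleanConfig | None = None,
) -> CleanResult:
    """Run the full cleaning pipeline over one alignment.

    Stage order (first failure wins; each record gets exactly one flag):

    1. AGCT screen (when ``agct_only``) -> ``non_AGCT``;
    2. translation screen (when ``aa_code != "off"``) -> ``Stop_Codon``;
    3. p-distance matrix over the survivors;
    4. genus-level distance outliers -> ``Genus_Outlier`` (a survivor with
       no comparable site against any other survivor also cannot be placed
       and is flagged here, logged distinctly);
    5. species-level outliers among the remaining records ->
       ``Species_Outlier``;
    6. barcode-gap report over the records flagged ``-``.

    With fewer than two survivors after stages 1-2, stages 3-6 are skipped
    with a logged warning.
    """
    config = config or CleanConfig()
    missing = [sid for sid in msa.ids if sid not in taxonomy]
    if missing:
        raise ValueError(f"taxonomy missing for ids: {missing[:3]}...")

    flags: dict[str, str] = {sid: FLAG_NONE for sid in msa.ids}
    lines: list[str] = []

    if config.agct_only:
        for sid, row in zip(msa.ids, msa.rows):
            if not agct_check(row):
                flags[sid] = FLAG_NON_AGCT
        lines.append(
            f"AGCT screen: {sum(f == FLAG_NON_AGCT for f in flags.values())} flagged"
        )

    if config.aa_code != "off":
        code = GENETIC_CODES[config.aa_code]
        for sid, row in zip(msa.ids, msa.rows):
            if flags[sid] == FLAG_NONE and not translation_check(row, code):
                flags[sid] = FLAG_STOP
        lines.append(
            f"translation screen ({config.aa_code}): "
            f"{sum(f == FLAG_STOP for f in flags.values())} flagged"
        )

    survivors = [sid for sid in msa.ids if flags[sid] == FLAG_NONE]
    dm: DistanceMatrix | None = None
    gap_rows: list[BarcodeGapRow] = []
    if len(survivors) < 2:
        lines.append(
            f"only {len(survivors)} record(s) survive content screens; "
            "distance, outlier and barcode-gap stages skipped"
        )
        log.warning(lines[-1])
    else:
        sub = MSA(
            ids=survivors, rows=[msa.row(sid) for sid in survivors]
        )
        dm = p_distance_matrix(sub)

        # A record with no comparable site against any other survivor cannot
        # be placed in the genus and is flagged at the genus level.
        off = ~np.eye(len(survivors), dtype=bool)
        unplaceable = [
            survivors[i]
            for i in range(len(survivors))
            if np.isnan(dm.d[i][off[i]]).all()
        ]
        for sid in unplaceable:
            flags[sid] = FLAG_GENUS
            lines.append(f"{sid}: no comparable sites with any record; "
                         "flagged Genus_Outlier (unplaceable)")

        genus_of = {sid: taxonomy[sid][0] for sid in survivors}
        genus_out = flag_distance_outliers(
            dm,
            genus_of,
            multiplier=config.outlier_multiplier,
            min_group_size=config.min_group_size,
            statistic=config.outlier_statistic,
            method=config.outlier_method,
        )
        for sid in genus_out:
            if flags[sid] == FLAG_NONE:
                flags[sid] = FLAG_GENUS
        lines.append(f"genus-level outliers: {len(genus_out)}")

        remaining = [sid for sid in survivors if flags[sid] == FLAG_NONE]
        if len(remaining) >= 2:
            species_of = {
                sid: f"{taxonomy[sid][0]} {taxonomy[sid][1]}" for sid in remaining
            }
            sp_out = flag_distance_outliers(
                dm.submatrix(remaining),
                species_of,
                multiplier=config.outlier_multiplier,
                min_group_size=config.min_group_size,
                statistic=config.outlier_statistic,
                method=config.outlier_method,
            )
            for sid in sp_out:
                flags[sid] = FLAG_SPECIES
            lines.append(f"species-level outliers: {len(sp_out)}")

        clean_ids = [sid for sid in msa.ids if flags[sid] == FLAG_NONE]
        if len(clean_ids) >= 2:
            gap_rows = barcode_gap_report(
                dm.submatrix(clean_ids),
                {sid: f"{taxonomy[sid][0]} {taxonomy[sid][1]}" for sid in clean_ids},
            )

    retained_ids = [sid for sid in msa.ids if flags[sid] == FLAG_NONE]
    retained = MSA(
        ids=retained_ids, rows=[msa.row(sid) for sid in retained_ids]
    )
    return CleanResult(
        flags=flags,
        retained=retained,
        distance_matrix=dm,
        gap_rows=gap_rows,
        log_lines=lines,
    )


def parse_taxonomy_from_header(header: str) -> tuple[str, str]:
    """Recover (genus, species) from a FASTA header.

    Pipe-delimited headers written by the assembly stage
    (``uid|accession|genus|species|marker``) are preferred; otherwise the
    second and third whitespace tokens are taken as the binomial
    (``>id Genus species ...``).  Headers carrying neither yield empty
    strings.
    """
    if "|" in header:
        parts = [p.strip() for p in header.split("|")]
        if len(parts) >= 4:
            return parts[2], parts[3]
    toks = header.split()
    if len(toks) >= 3:
        return toks[1], toks[2]
    return "", ""


def _write_data_table(path, msa: MSA, taxonomy, flags) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tgenus\tspecies\tflag\n")
        for sid in msa.ids:
            genus, species = taxonomy[sid]
            fh.write(f"{sid}\t{genus}\t{species}\t{flags[sid]}\n")


def clean_file(
    fasta_path,
    config: CleanConfig | None = None,
    out_dir=None,
    taxonomy: Mapping[str, tuple[str, str]] | None = None,
) -> CleanResult:
    """Clean one aligned FASTA and write its three output files.

    Outputs, named after the input stem: ``<stem>_dist_table.dat`` (square
    distance matrix TSV), ``<stem>_data_table.dat`` (id, genus, species,
    flag), ``<stem>_no_outlier.fas`` (records flagged ``-``).  Taxonomy is
    parsed from headers unless supplied.
    """
    fasta_path = Path(fasta_path)
    out_dir = Path(out_dir) if out_dir is not None else fasta_path.parent
    out_dir.mkdir(parents=True, exist_ok=True)
    msa = MSA.from_fasta(fasta_path)
    if taxonomy is None:
        taxonomy = {sid: parse_taxonomy_from_header(sid) for sid in msa.ids}
    result = clean_dataset(msa, taxonomy, config)

    stem = fasta_path.stem
    if result.distance_matrix is not None:
        result.distance_matrix.to_tsv(out_dir / f"{stem}_dist_table.dat")
    else:
        (out_dir / f"{stem}_dist_table.dat").write_text("", encoding="utf-8")
    _write_data_table(out_dir / f"{stem}_data_table.dat", msa, taxonomy, result.flags)
    result.retained.to_fasta(out_dir / f"{stem}_no_outlier.fas")
    return result


def clean_folder(
    data_dir,
    config: CleanConfig | None = None,
    out_dir=None,
    log_name: str | None = None,
) -> dict[str, CleanResult]:
    """Clean every alignment FASTA in a folder; one run log per invocation."""
    data_dir = Path(data_dir)
    out_root = Path(out_dir) if out_dir is not None else data_dir
    out_root.mkdir(parents=True, exist_ok=True)
    inputs = sorted(
        p
        for pat in ("*.fas", "*.fasta", "*.fa")
        for p in data_dir.glob(pat)
        if not p.name.endswith("_no_outlier.fas")
    )
    if not inputs:
        raise FileNotFoundError(f"no FASTA files found in {data_dir}")
    if log_name is None:
        log_name = datetime.now().strftime("A_Clean_File_%Y-%m-%d_%H%M%S.txt")

    results: dict[str, CleanResult] = {}
    log_lines: list[str] = []
    for path in inputs:
        res = clean_file(path, config=config, out_dir=out_root)
        results[path.name] = res
        counts = res.counts()
        log_lines.append(f"{path.name}: " + ", ".join(
            f"{k}={v}" for k, v in sorted(counts.items())
        ))
        log_lines.extend(f"  {ln}" for ln in res.log_lines)
        for row in res.gap_rows:
            log_lines.append(
                f"  barcode gap {row.species}: n={row.n} "
                f"max_intra={row.max_intra} min_inter={row.min_inter} "
                f"gap={row.gap_present}"
            )
    (out_root / log_name).write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return results
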