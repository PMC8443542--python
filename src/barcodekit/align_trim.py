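"""Reference-guided alignment and trimming.

Each genus×marker FASTA is aligned (via an external MAFFT executable) against
a single reference sequence for the target region.  The alignment is then
cropped to the reference's column span, records that do not fully cover that
span are dropped, and rare insertions are resolved by the proportional
internal-gap rule: a column that is gap in more than ``pigl`` of the rows is
considered an artifact of the few records carrying an insertion there, and
those carrier records are removed.

Column bookkeeping is 0-based half-open internally and 1-based inclusive in
logs and reports.
"""

from __future__ import annotations

import io
import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "MSA",
    "TrimConfig",
    "TrimResult",
    "GapResolveResult",
    "AlignerNotFoundError",
    "AlignerError",
    "invoke_aligner",
    "trim_to_reference",
    "resolve_internal_gaps",
    "align_and_trim_folder",
]

log = logging.getLogger(__name__)

GAP = "-"


class AlignerNotFoundError(EnvironmentError):
    """The external aligner executable could not be located."""


class AlignerError(RuntimeError):
    """The external aligner exited non-zero; message carries its stderr."""


@dataclass
class MSA:
    """Equal-length gapped sequences with identifiers.

    ``ref_id``, when set, names the reference row used for trimming.
    """

    ids: list[str]
    rows: list[str]
    ref_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence identifiers in MSA")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"rows are not equal length: {sorted(widths)}")
        if self.ref_id is not None and self.ref_id not in self.ids:
            raise ValueError(f"ref_id {self.ref_id!r} is not a member of ids")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    @classmethod
    def from_fasta(cls, path, ref_id: str | None = None) -> "MSA":
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.description)
            rows.append(str(rec.seq).upper())
        return cls(ids=ids, rows=rows, ref_id=ref_id)

    def to_fasta(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")


@dataclass(frozen=True)
class TrimConfig:
    """Trimming parameters.

    ``pigl``: proportional internal-gap threshold in [0, 1]; 0 disables
    internal-gap resolution.  ``op``: gap-opening penalty handed to the
    aligner; high values suppress gaps, appropriate for conserved barcode
    regions such as COI-5P.
    """

    pigl: float = 0.95
    op: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pigl <= 1.0:
            raise ValueError("pigl must be within [0, 1]")
        if self.op <= 0:
            raise ValueError("gap-opening penalty must be positive")


@dataclass
class TrimResult:
    msa: MSA
    removed_ids: list[str]
    window: tuple[int, int]  # 1-based inclusive reference span


@dataclass
class GapResolveResult:
    msa: MSA
    removed_ids: list[str]
    trigger_columns: list[int]  # 1-based, relative to the input MSA


def _resolve_executable(aligner_location) -> str:
    loc = Path(aligner_location)
    if loc.is_dir():
        loc = loc / "mafft"
    if loc.exists():
        return str(loc)
    found = shutil.which(str(aligner_location))
    if found:
        return found
    raise AlignerNotFoundError(
        f"aligner executable not found at {aligner_location!r}; install MAFFT "
        "(https://mafft.cbrc.jp/alignment/software/) or pass its location"
    )


def invoke_aligner(
    target_fasta,
    ref_fasta,
    op: float = 10.0,
    aligner_location: str = "mafft",
    out_path=None,
) -> MSA:
    """Align reference + targets with MAFFT; returns the MSA with ``ref_id``
    set to the reference's identifier.

    ``ref_fasta`` must contain exactly one sequence.  When ``out_path`` is
    given the raw aligned FASTA is persisted there.
    """
    exe = _resolve_executable(aligner_location)
    refs = list(SeqIO.parse(str(ref_fasta), "fasta"))
    if len(refs) != 1:
        raise ValueError(
            f"reference FASTA must contain exactly one sequence, found {len(refs)}"
        )
    ref = refs[0]
    targets = list(SeqIO.parse(str(target_fasta), "fasta"))

    with tempfile.TemporaryDirectory() as tmp:
        combined = Path(tmp) / "combined.fas"
        with open(combined, "w", encoding="utf-8") as fh:
            fh.write(f">{ref.description}\n{ref.seq}\n")
            for rec in targets:
                fh.write(f">{rec.description}\n{rec.seq}\n")
        proc = subprocess.run(
            [exe, "--op", str(op), "--quiet", str(combined)],
            capture_output=True,
            text=True,
        )
    if proc.returncode != 0:
        raise AlignerError(
            f"aligner exited {proc.returncode}: {proc.stderr.strip()}"
        )
    ids, rows = [], []
    for rec in SeqIO.parse(io.StringIO(proc.stdout), "fasta"):
        ids.append(rec.description)
        rows.append(str(rec.seq).upper())
    msa = MSA(ids=ids, rows=rows, ref_id=ref.description)
    if out_path is not None:
        msa.to_fasta(out_path)
    return msa


def trim_to_reference(msa: MSA) -> TrimResult:
    """Crop to the reference span and drop records without full coverage.

    Columns outside the first/last non-gap column of the reference row are
    removed; the reference row itself is then dropped; any record whose
    cropped row starts or ends with a gap (a run of any length) lacked full
    coverage of the reference span and is removed and reported.
    """
    if msa.ref_id is None:
        raise ValueError("trim_to_reference requires msa.ref_id")
    ref_row = msa.row(msa.ref_id)
    non_gap = [i for i, c in enumerate(ref_row) if c != GAP]
    if not non_gap:
        raise ValueError("reference row consists entirely of gaps")
    first, last = non_gap[0], non_gap[-1]

    kept_ids: list[str] = []
    kept_rows: list[str] = []
    removed: list[str] = []
    for sid, row in zip(msa.ids, msa.rows):
        if sid == msa.ref_id:
            continue
        cropped = row[first : last + 1]
        if cropped.startswith(GAP) or cropped.endswith(GAP):
            removed.append(sid)
        else:
            kept_ids.append(sid)
            kept_rows.append(cropped)
    return TrimResult(
        msa=MSA(ids=kept_ids, rows=kept_rows),
        removed_ids=removed,
        window=(first + 1, last + 1),
    )


def _gap_columns(rows: list[str]):
    arr = np.array([list(r) for r in rows])
    return arr, arr == GAP


def resolve_internal_gaps(
    msa: MSA, pigl: float, comparison: str = "gt"
) -> GapResolveResult:
    """Remove records whose insertions open near-universal gap columns.

    For each column the gap fraction (# gap rows / # rows) is computed; a
    column exceeding ``pigl`` (strict ``>`` by default; ``comparison="ge"``
    switches to ``>=``) marks every record holding a non-gap character there
    as an insertion carrier.  Carriers are removed, all-gap columns deleted,
    and the evaluation repeats until no column exceeds the threshold, so the
    operation is idempotent.  ``pigl == 0`` disables the rule entirely.
    """
    if not 0.0 <= pigl <= 1.0:
        raise ValueError("pigl must be within [0, 1]")
    if comparison not in ("gt", "ge"):
        raise ValueError("comparison must be 'gt' or 'ge'")
    if pigl == 0 or not msa.rows:
        return GapResolveResult(msa=msa, removed_ids=[], trigger_columns=[])

    ids = list(msa.ids)
    rows = list(msa.rows)
    # Map current columns back to input coordinates for reporting.
    col_origin = list(range(msa.width))
    removed: list[str] = []
    triggers: list[int] = []

    while rows:
        arr, gaps = _gap_columns(rows)
        frac = gaps.mean(axis=0)
        over = frac > pigl if comparison == "gt" else frac >= pigl
        # All-gap columns cannot name a carrier; they are deleted below.
        over &= frac < 1.0
        if over.any():
            triggers.extend(col_origin[j] + 1 for j in np.flatnonzero(over))
            carriers = np.flatnonzero((~gaps[:, over]).any(axis=1))
            for i in carriers:
                removed.append(ids[i])
            keep = [i for i in range(len(ids)) if i not in set(carriers.tolist())]
            ids = [ids[i] for i in keep]
            rows = [rows[i] for i in keep]
            if not rows:
                break
            arr, gaps = _gap_columns(rows)
        # Delete columns that are now entirely gaps.
        full_gap = gaps.all(axis=0)
        if full_gap.any():
            keep_cols = np.flatnonzero(~full_gap)
            rows = ["".join(arr[i, keep_cols]) for i in range(len(rows))]
            col_origin = [col_origin[j] for j in keep_cols]
        if not over.any():
            break

    return GapResolveResult(
        msa=MSA(ids=ids, rows=rows),
        removed_ids=removed,
        trigger_columns=sorted(set(triggers)),
    )


def _fasta_files(folder: Path) -> list[Path]:
    out: list[Path] = []
    for pattern in ("*.fas", "*.fasta", "*.fa"):
        out.extend(folder.glob(pattern))
    return sorted(set(out))


@dataclass
class FileReport:
    source: Path
    n_input: int = 0
    n_trim_removed: int = 0
    n_gap_removed: int = 0
    n_kept: int = 0
    error: str | None = None


def align_and_trim_folder(
    folder,
    ref_fasta,
    config: TrimConfig | None = None,
    aligner_location: str = "mafft",
    output=None,
) -> list[FileReport]:
    """Align and trim every FASTA in ``folder`` against one reference.

    Writes ``MAFFT/<name>_MAFFT.fas`` (raw alignment) and
    ``MAFFT_trimmed/<name>_MAFFT_trimmed.fas`` (trimmed), and appends per-file
    removal counts to ``MAFFT_log.txt``.  A failure on one file is logged and
    does not abort the batch.
    """
    config = config or TrimConfig()
    folder = Path(folder)
    out_root = Path(output) if output is not None else folder
    files = _fasta_files(folder)
    if not files:
        raise FileNotFoundError(f"no FASTA files found in {folder}")
    mafft_dir = out_root / "MAFFT"
    trimmed_dir = out_root / "MAFFT_trimmed"
    mafft_dir.mkdir(parents=True, exist_ok=True)
    trimmed_dir.mkdir(parents=True, exist_ok=True)

    reports: list[FileReport] = []
    log_lines: list[str] = []
    for path in files:
        rep = FileReport(source=path)
        try:
            raw = invoke_aligner(
                path,
                ref_fasta,
                op=config.op,
                aligner_location=aligner_location,
                out_path=mafft_dir / f"{path.stem}_MAFFT.fas",
            )
            rep.n_input = len(raw) - 1  # reference excluded
            trimmed = trim_to_reference(raw)
            rep.n_trim_removed = len(trimmed.removed_ids)
            resolved = resolve_internal_gaps(trimmed.msa, config.pigl)
            rep.n_gap_removed = len(resolved.removed_ids)
            rep.n_kept = len(resolved.msa)
            resolved.msa.to_fasta(trimmed_dir / f"{path.stem}_MAFFT_trimmed.fas")
            log_lines.append(
                f"{path.name}: input={rep.n_input} "
                f"coverage_removed={rep.n_trim_removed} "
                f"(ids: {', '.join(trimmed.removed_ids) or '-'}) "
                f"window={trimmed.window[0]}..{trimmed.window[1]} "
                f"internal_gap_removed={rep.n_gap_removed} "
                f"(ids: {', '.join(resolved.removed_ids) or '-'}; "
                f"columns: {', '.join(map(str, resolved.trigger_columns)) or '-'}) "
                f"kept={rep.n_kept}"
            )
        except Exception as exc:  # noqa: BLE001 — per-file isolation
            rep.error = str(exc)
            log_lines.append(f"{path.name}: FAILED — {exc}")
            log.error("align/trim failed for %s: %s", path, exc)
        reports.append(rep)

    with open(out_root / "MAFFT_log.txt", "a", encoding="utf-8") as fh:
        for line in log_lines:
            fh.write(line + "\n")
    return reports
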