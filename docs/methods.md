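# Methods

This note records the models, rules and numerical choices behind
`barcodekit`, in the order the pipeline applies them, together with what the
synthetic test data do and do not establish.

## Record harmonization and flagging

Records from BOLD-style and GenBank-style sources are mapped onto one row
type keyed by an opaque `uid` (`<source>:<accession>`). The organism string
is split on whitespace: the first term is the genus, the remainder the
species epithet verbatim; a one-term organism yields an empty species and
the `no_taxa` flag, because a binomial is required downstream. Six flags are
computed per record and stored, never acted on at ingest:

| flag | rule |
|---|---|
| `no_marker` | marker name empty after trimming |
| `no_taxa` | genus or species empty |
| `no_seq` | sequence empty |
| `name_issue` | combined name has > 2 whitespace-separated terms |
| `taxa_digits` | any decimal digit in genus or species |
| `taxa_punct` | any character that is not a letter, digit or whitespace |

Punctuation deliberately includes the hyphen: hyphenated taxon names in
public records are overwhelmingly annotation artifacts. Inclusion at FASTA
assembly is conjunctive — a record is written only if *every* flag it
carries has been explicitly permitted. Dereplication across sources keeps
the first record per accession; no sequence-content comparison is attempted
at this stage.

The GenBank marker name is taken from the first non-empty of
`gene`, `product`, `definition` (configurable), since source records are
inconsistent about which field carries it.

## Marker grouping

Marker-name matching is exact on normalized names (uppercase; characters
outside `[A-Z0-9-]` removed). No fuzzy or substring matching: the parameter
file is the user's explicit statement of which naming variants belong to
which output file, and it is followed verbatim even where a listed synonym
looks like it belongs to a different marker.

## Alignment and trimming

Alignment is delegated to MAFFT, invoked per FASTA with the reference
sequence prepended and `--op` passed through (default 10 — far above
MAFFT's own 1.53 — because barcode regions are expected to align without
gaps, and a high opening penalty suppresses spurious ones).

Trimming is reference-guided: columns outside the reference row's first and
last non-gap columns are cropped, the reference row is dropped, and any
record whose cropped row begins or ends with a gap — a run of any length —
lacked full coverage of the reference span and is removed (reported with
the 1-based window). The reference is a guide only: it never appears in
outputs and never counts toward gap fractions.

Internal gaps are resolved by the proportional threshold `pigl`
(default 0.95; 0 disables the rule): for each column the gap fraction over
the remaining rows is computed, and every record holding a *non-gap*
character in a column whose fraction strictly exceeds `pigl` is removed —
those few records carry the insertion that opened the gap for everyone
else. Two numerical choices here:

- **Strict `>`.** "More than the proportional value" is read as a strict
  inequality; a column gapped in exactly 19/20 rows at `pigl = 0.95` does
  not trigger. A `comparison="ge"` switch is exposed.
- **Iteration to a fixpoint.** Removing carriers shrinks the denominator,
  which can push a previously sub-threshold column over the line, so the
  evaluation repeats until no column exceeds the threshold. A single pass
  would make the operation non-idempotent; the fixpoint is deterministic,
  idempotent, and in practice terminates in one or two rounds. All-gap
  columns are deleted afterwards. Columns are treated independently;
  adjacent gap columns are not merged into joint events.

Reverse-complement detection is out of scope; sequences are assumed
oriented (a mis-oriented record fails full-coverage trimming or distance
screening instead).

## Cleaning

Stages run in a fixed order and each record receives exactly one flag, the
first failure winning: `non_AGCT` → `Stop_Codon` → `Genus_Outlier` →
`Species_Outlier` → `-` (retained).

**AGCT screen.** A sequence passes iff every non-gap character is an
unambiguous A/C/G/T (case-insensitive). Alignment gaps are ignored: the
flag targets residue content, not alignment artifacts.

**Translation screen.** The degapped sequence is translated in all three
forward frames under the selected genetic code (standard, vertebrate
mitochondrial or invertebrate mitochondrial — NCBI tables 1, 2 and 5 via
Biopython; the invertebrate table is the default, matching COI-5P practice
for most animal datasets). Codons containing a non-AGCT character are
skipped. The record passes if *any* frame with at least one complete codon
is stop-free: after trimming, the reading frame is not guaranteed, so
demanding a specific frame would over-flag. Reverse frames are not scanned
(orientation is the alignment stage's concern). Sequences shorter than one
codon after degapping fail.

**Distance matrix.** p-distances under pairwise deletion: per pair, only
positions where both rows hold A/C/G/T are compared; the distance is
mismatches over compared sites, and a pair with zero comparable sites is
*missing* (excluded from all summaries). Compared-site counts are kept
alongside the distances. Only records surviving the two content screens
enter the matrix (they would otherwise distort distances with Ns and
frameshifts), and the written `_dist_table.dat` covers exactly those
records.

**Outlier flagging.** Within each group (genus first, then species among
the records the genus stage left), each member's mean pairwise distance to
the other members is computed (missing pairs excluded; a median alternative
is exposed). A record is an outlier when its summary exceeds
`multiplier × the group's mean summary` (strict `>`, multiplier 1.5 by
default) — the literal reading of "greater than 1.5× pairwise sequence
distance". A Tukey-fence alternative (`Q3 + multiplier × IQR`, quartiles by
linear interpolation) is available as `outlier_method="tukey"`; it is the
stricter convention for near-homogeneous groups, but on small groups its
false-flag probability per clean record is non-negligible (a few tenths of
a percent even for well-behaved data, far more for the discrete distance
spectra of short markers), which is why the multiplicative rule is the
default. Groups smaller than `min_group_size` (default 4) are skipped —
thresholds estimated from 2–3 points are noise. Genus-level flagging runs
before and feeds species-level flagging (sequential, not parallel); a
record with no comparable sites against any other record cannot be placed
and is flagged at the genus level, logged distinctly.

**Barcode gap.** Per species among retained records: `max_intra` is the
largest conspecific distance (missing if the species has fewer than two
members or no comparable conspecific pair), `min_inter` the smallest
distance to any other species, and `gap_present = min_inter > max_intra`
(strict: two identical species have no gap). Fewer than two survivors skip
the distance, outlier and gap stages with a logged warning; outputs are
still written.

## Synthetic data

The generator derives everything from one seed (NumPy `default_rng`): an
ancestor sequence built codon-wise from codons that are stop-free under all
three supported genetic codes; one founder haplotype per species (the first
founder is the ancestor, later founders diverge from it by
`species_divergence`, default 0.05 — a typical congeneric separation and
the source of a genuine barcode gap); and records that substitute exactly
`round(rate × length)` uniformly chosen sites of their parent, with any
substitution that would create a frame-1 stop codon reverted. Fixing the
substitution count rather than thinning per site makes every record's
divergence exactly the nominal rate, mimicking the tight conspecific
clusters of curated barcode data and giving the truth labels a sharp
meaning. Defaults describe a small single-genus cohort: ten clean records
at 1% background divergence over 120 sites in two species of five, one 30%
outlier, one ambiguity-bearing record (1–3 Ns), one record carrying a TAA
stop in all three reading frames (motif `TAAGTAAGTAAG` at a codon-aligned
position). Insertion records (off by default) add a codon-aligned,
stop-free insertion of `insertion_len` bases (a multiple of 3, so carriers
stay translatable); the pre-gapped alignment the generator also emits makes
the trimming stage testable without running MAFFT.

What the fixtures do **not** emulate: tree-structured evolution within
species, transition/transversion bias, rate heterogeneity, length
variation, chimeras, or sequencing-chemistry error profiles. Passing the
truth-recovery tests therefore demonstrates that the decision rules fire
exactly as specified under controlled divergence structure — not that the
1.5× rule has any particular sensitivity/specificity on real survey data,
where within-group spread is wider and flags on genuine records are
expected and intended behaviour.

The source-shape fixtures serialize the same cohort as a BOLD-style TSV and
GenBank-style record maps, optionally planting one violation per flagging
rule, so ingest and flagging are exercised end to end.

## Sizes and determinism

Test and acceptance workloads are deliberately small — cohorts of ~13–28
records of 120 bp, hundreds of randomized oracle instances, 20 seeded
truth-recovery cohorts — sizes at which every check runs in seconds while
still exercising each rule's boundary cases (e.g. gap fractions exactly at
vs. just above `pigl`). All randomness flows from explicit seeds;
timestamps are confined to logs and manifests, so two runs with identical
inputs and arguments produce byte-identical FASTA and table outputs, which
the acceptance script verifies across the full four-stage pipeline.

## Known limitations

- Distances are uncorrected p-distances only; no K2P or other model
  corrections, no haplotype collapsing, no OTU/BIN clustering.
- Taxonomy is taken at face value from source records; no name validation
  against external services.
- The live transports cover the fields the total table needs, not full
  GenBank flatfile or BOLD specimen metadata.
- The outlier rule's two conventions (ratio vs. Tukey fence) can disagree
  near the threshold; the choice and multiplier are recorded in the run
  manifest for exactly this reason.
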