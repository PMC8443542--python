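# barcodekit

Assemble, align, trim and clean DNA-barcode reference datasets.

Curated, static reference libraries of marker sequences (classically the
COI-5P mitochondrial barcode for animals) underpin species identification,
metabarcoding and regulatory work. Building them by hand — searching
GenBank and BOLD, reconciling inconsistent marker names, aligning, trimming
and weeding out suspect records — is slow and, worse, irreproducible.
`barcodekit` turns that workflow into four scripted, parameterized stages so
that a dataset can be rebuilt exactly from a genus list and a handful of
published arguments.

## The pipeline

1. **download** — fetch records per genus from BOLD-style and GenBank-style
   sources (default GenBank query:
   `(<genus>[ORGN]) NOT (shotgun[ALL] OR genome[ALL] OR assembled[ALL] OR
   microsatellite[ALL])`), harmonize them into one tab-separated *total
   table*, dereplicate shared accessions, and summarize per genus.
   Records are flagged — `no_marker`, `no_taxa`, `no_seq`, `name_issue`
   (more than two name terms), `taxa_digits`, `taxa_punct` — never deleted.
2. **make-fastas** — group records into genus×marker FASTA files driven by a
   marker-synonym parameter file (one column per output file: genus on top,
   the marker-name variants below). Names are normalized (uppercase;
   letters, digits and hyphen only), so `"Cytochrome c oxidase subunit I"`
   and `CYTOCHROMECOXIDASESUBUNITI` match.
3. **align-trim** — align each FASTA against a single reference sequence
   with MAFFT (gap-opening penalty `--op`, default 10), crop the alignment
   to the reference span, drop records without full coverage, and resolve
   rare insertions: any column that is gap in more than `pigl` (default
   0.95) of the rows marks its few non-gap "carrier" records for removal.
4. **clean** — compute the pairwise p-distance matrix (pairwise deletion:
   only positions where both sequences hold A/C/G/T are compared), flag
   records whose mean within-group distance exceeds 1.5× the group mean at
   the genus and then the species level (`Genus_Outlier`,
   `Species_Outlier`), screen translations for stop codons under the
   standard / vertebrate-mitochondrial / invertebrate-mitochondrial genetic
   codes (`Stop_Codon`), reject ambiguity codes (`non_AGCT`), and report
   the per-species **barcode gap**: is the smallest distance to another
   species larger than the largest intraspecific distance?

A deterministic synthetic-data generator (`barcodekit fixtures`, or
`barcodekit.synthetic` in the library) produces cohorts with known ground
truth — planted divergent outliers, ambiguity codes, stop codons in all
three reading frames, internal insertions — so every stage is testable
without network access.

## Worked example

Entirely offline, using the synthetic generator as the record source:

```sh
barcodekit fixtures --output fx --seed 7
printf 'Simulomys\n' > genera.txt
printf 'Simulomys\nCOI-5P\n' > params.tsv
barcodekit download  --input genera.txt --output dl --replay fx --run-name run
barcodekit make-fastas --data dl/run/Total_tables/A_Total_Table.dat \
                       --params params.tsv --output groups
barcodekit align-trim --data groups --ref fx/reference.fas --output at
barcodekit clean      --data at/MAFFT_trimmed --output cl
```

which prints:

```
downloaded 13 records across 1 genera -> dl/run
wrote 1 FASTA file(s) from 1 group(s)
Simulomys_COI-5P.fas: kept 13/13 (coverage -0, internal gaps -0)
Simulomys_COI-5P_MAFFT_trimmed.fas: -=10, Genus_Outlier=1, Stop_Codon=1, non_AGCT=1
```

The seed-7 fixture plants exactly one 30%-divergent record, one record with
an ambiguity code, and one with stop codons in every frame among ten clean
sequences; the clean stage flags precisely those three and retains the ten
(`-`). Its run log also reports the barcode gap per species:

```
barcode gap Simulomys speciesa: n=5 max_intra=0.0167 min_inter=0.0417 gap=True
barcode gap Simulomys speciesb: n=5 max_intra=0.0167 min_inter=0.0417 gap=True
```

i.e. both simulated species are diagnosable: their deepest intraspecific
divergence (1.7%) sits below their closest heterospecific distance (4.2%).
Each input FASTA yields `<name>_dist_table.dat` (the distance matrix),
`<name>_data_table.dat` (id, genus, species, flag) and
`<name>_no_outlier.fas` (the retained records); every run writes a
`run_manifest.json` with arguments, tool version and input digests.

Live downloads use the same commands without `--replay`; all HTTP goes
through an injectable transport with bounded retries, so the whole test
suite runs offline.

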