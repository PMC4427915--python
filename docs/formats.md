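# File formats

All coordinates in every phosmap format are **1-based and inclusive**. A
site written `S544` is the serine at sequence position 544; the feature
table deliberately diverges from 0-based half-open BED and says so in its
header comment.

## FASTA

Headers of the form `>accession|name|species` populate all identity
fields (`species` is normalized to `human` / `mouse` / `rat` / `other`).
Any other header is taken whole as the accession, with species `other`.
Sequences are uppercased on read; letters outside the 20 standard amino
acids plus `X` are an error naming the record and offset.

## Site tables (TSV)

### `unified` dialect (the package's native format)

| column     | content                                             |
|------------|-----------------------------------------------------|
| accession  | protein identifier                                  |
| position   | 1-based residue position                            |
| residue    | one of S, T, Y                                      |
| species    | human / mouse / rat / other (free text normalized)  |
| source     | comma-separated set of database names               |
| evidence   | `verified` or `predicted`                           |

`write_site_table` emits this dialect, rows ordered by
(accession, position); reading it back reproduces the table row for row.

### `phosphositeplus_like`

Columns `ACC_ID`, `ORGANISM`, `MOD_RSD`. The site string (`S544-p`)
carries residue, position and a modification suffix that is stripped.
Source defaults to `PhosphoSitePlus`, evidence to `verified`.

### `uniprot_like`

Columns `Accession`, `Species`, `Site` (combined strings like `T1148`),
optional `Source` (default `UniProt`) and `Evidence` (default
`verified`).

Malformed rows (unparsable position, non-STY residue) are skipped with a
logged diagnostic and collected on the returned list's `errors`
attribute; `--strict` upgrades them to errors. A missing mandatory column
always raises, naming the column.

## Feature tables (TSV)

Columns: `accession`, `kind`, `start`, `end`, `label`, optional `agent`
and `note`. Kinds: `cleavage_site`, `motif_interval`, `binding_region`,
`domain_segment`. A `cleavage_site` row denotes the **scissile bond**
between residues `start` (P1) and `end` (P1′), so `end = start + 1` is
enforced; all other kinds are inclusive intervals with
`1 ≤ start ≤ end`.

## Domain-architecture registry (TSV)

Columns: `accession`, `name`, `class`, `family`, `start`, `end`,
`label`, `note` — one row per domain segment. Segments of one accession
must tile `[1, length]` contiguously without overlap. `label` is drawn
from a fixed vocabulary (`signal_peptide`, `N_propeptide`,
`triple_helix`, `interruption`, `C_propeptide`, `NC_domain`,
`ectodomain`, `cytoplasmic`, `transmembrane`, `other`); finer names for
non-collagen records (propeptide, catalytic, hemopexin) live in `note`.
`class` is one of `fibrillar`, `FACIT`, `network`, `membrane`,
`multiplexin`, `short_chain`, `other`, `not_collagen`.

## Aligned FASTA and region sidecar

The conservation module consumes any aligned FASTA (gap characters `-`
or `.`); all rows must have equal length and each degapped row must
equal the corresponding input sequence when sequences are supplied.
Highlighted regions (e.g. the chain recognition sequence) are supplied
as a sidecar TSV with columns `label`, `start_column`, `end_column`
(1-based inclusive alignment columns).
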