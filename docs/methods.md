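# Methods

## Problem and scope

Large-scale mining of phosphoproteomics databases shows that most
extracellular matrix proteins — nearly the whole 28-type collagen
family, most MMPs and BMPs — can occur in phosphorylated states, with
secreted kinases such as FAM20C, and ecto-kinases such as PKA and CKII,
as candidate writers. phosmap re-implements the analysis layer of such a
database-mining study as a reusable pipeline: it does **not** query the
source databases (Phosida, PhosphoSitePlus, PhosphoNet, HPRD, dbPTM,
UniProt) or predict phosphosites; it ingests exported site tables,
keeps only experimentally verified sites, and computes the downstream
annotations — motif content, cleavage-site proximity, domain placement,
alignment conservation — that give those sites functional context.

## Harmonization model

A phosphosite's identity is the triple (accession, 1-based position,
residue letter). Everything else — which databases reported it, which
kinase is implicated — is provenance, not identity. Merging unions
provenance over sources; two claims at the same (accession, position)
with different residue letters cannot both be right, and since no
arbitration rule is defensible from export data alone, both are dropped
and the conflict reported. Orthologous sites are never pooled across
species (orthologs carry different accessions); species is retained
per row and rendered with the conventional colour code (red human, blue
mouse, black rat).

Validation partitions the input exactly: a site is retained iff its
evidence is `verified`, its accession resolves, its position is in
range, and the sequence letter at that position equals the claim. The
counting identity `n_input = n_retained + n_residue_mismatch +
n_out_of_range + n_predicted_dropped` is enforced on every run. Sites
reported on non-canonical isoforms fail residue validation and are
reported, not rescued; lifting isoform coordinates is out of scope.

## Offset convention

A cleavage site is stored as the scissile bond (P1, P1′), never as a
single residue. The k-th residue after the bond has offset +k
(`position − P1`), the k-th before it −k (`position − P1′`); offset 0
does not exist. This is the unique convention under which two enzymes
cutting the same region at bonds d residues apart give
`offset_A − offset_B = d` for every shared downstream site — exactly
the arithmetic reported for the procollagen α1(I) N-telopeptide sites
(10/11/15 residues downstream of the ADAMTS2 bond and 4/5/9 downstream
of the meprin bond six residues further along), and it is verified as a
property test. The default proximity window is 35 residues, the
reported extent of the PCPE-1 binding region downstream of the BMP1
cleavage site on fibrillar procollagens; it is always overridable.

## Motif scanning

Patterns are ordered residue sets: `S-x-E` is ({S}, any, {E}). Design
choices, each covered by a test:

* `x` means any single standard residue, including S and E (no source
  restricts it).
* `X` (unknown residue) matches nothing, not even `x`, so unknown
  residues can never create hits.
* All matching windows are reported, overlaps included — the maps mark
  motif locations, not a maximal non-overlapping set.
* The phospho-primed variant `S-x-Sp` requires the +2 residue to be a
  serine carrying a **verified** phosphosite at its absolute position; a
  threonine does not prime. Priming makes matching a function of the
  site table, so the primed-hit set is monotone in the table (tested).
* A hit is "starred" (motif known to be phosphorylated) iff a verified
  site sits at the hit's first S/T — the motif's phosphoacceptor. Which
  position should carry the star is genuinely underdetermined, so
  `star_anywhere=True` relaxes it to any S/T in the window.

The scanner is checked for exact equality against a brute-force
all-windows oracle on 1,000 random sequence/pattern/site-table
instances; the oracle is an independent re-implementation kept in the
test suite.

## Domain architectures

The packaged registry models the 28 collagen types as 45 α-chains in
seven structural classes, plus MMP2/MMP9/BMP1/BMP15 records. The
architectures are **simplified block models** at the level of schematic
domain diagrams — signal peptide, propeptides, triple helix with
interruptions for FACIT and multiplexin chains, cytoplasmic/
transmembrane/ectodomain for membrane collagens — not curation-grade
boundaries; every chain where a published residue coordinate matters
(COL1A1, COL1A2, COL3A1, COL17A1, BMP1, MMP2) has its segment
boundaries and cleavage bonds placed so the published offsets are
reproduced exactly. Segment provenance is carried per row so curated
coordinates can be substituted via `--registry`. Architectures must
tile [1, length] contiguously; `assign_domain` is therefore total, and
per-domain tallies sum to each chain's total site count (both tested).

## Conservation projection

The aligner is out of scope; the module consumes aligned FASTA and
builds mutually inverse position↔column maps per row (round-trip is a
property test, as is invariance of co-occurrence verdicts under gap
column insertion). "Highly conserved" has no canonical numeric
definition here, so the conserved-phospho threshold m (minimum number
of rows with a verified site in a column) is a parameter with default
2. Highlighted regions such as the chain recognition sequence are
supplied as column intervals in a sidecar TSV, since such regions are
published graphically, not numerically.

## Synthetic data generator

`generate_synthetic` emulates the statistical structure of multi-source
database exports, with a complete truth record. Defaults: 6 proteins of
150–250 residues, 8 planted S/T/Y sites per protein, two planted S-x-E
instances and one RGD per protein, 2 cleavage bonds per protein, 50%
source overlap (each protein's duplicate count is known exactly), 20%
of sites corrupted to a wrong residue letter (driving the validation
mismatch tally), window 35. Background residues are drawn uniformly
from the 20 letters; planted items keep a clearance of the longest
pattern, and a rewrite pass mutates any background window that
accidentally matches a planted pattern (mutations use letters that
appear in no pattern, so the pass only destroys matches and
terminates). Rejection-rewriting was chosen over probabilistic
tolerance so recovery tests are exact, not statistical: harmonize →
scan → proximity recovers 100% of planted sites, motifs and
cleavage-adjacency flags with zero extras over 50 seeds, at 3 proteins
× 6 sites per seed (the property holds at the defaults too; the
smaller size keeps the suite fast).

What the generator does **not** emulate: real accession formats,
inter-database accession conflicts (ingestion keys on accession; an
explicit alias map is the user's responsibility), isoform coordinate
shifts, non-uniform residue composition, and correlated errors between
databases. Passing recovery tests therefore demonstrates the pipeline's
bookkeeping is exact, not that real exports are this clean.

## Literature fixtures

`paper_fixture` packages the short sequences and residue coordinates
reported in the extracellular-phosphorylation literature: the six
RGD-context peptides, the PEDF-binding motif IKGHRGFSGL (containing the
heparin motif KGHRG(F/Y)), the furin recognition sequence of BMP1 with
its internal S-x-S motif, and coordinate stubs for vitronectin, PEDF,
MMP2, collagen XVII and procollagens α1(I)/α2(I)/α1(II)/α1(III). Stubs
are glycine-padded synthetic sequences that preserve the printed
residue numbering (no full database sequence is redistributed); each is
labelled a synthetic stub in its record name, and each feature carries
a note stating the reported relationship it encodes. The glycine
padding cannot create S-x-E, RGD or KGHRG(F/Y) matches, so motif counts
on the stubs are exactly the planted ones.

## Numerical and degenerate-input choices

* Coordinates 1-based inclusive everywhere; a sentinel test plants a
  phosphosite at residue 1 to catch 0-based drift.
* Malformed site-table rows are skipped and tallied (exports are
  dirty); `--strict` upgrades them to errors.
* Unknown species map to `other`, never dropped.
* A pattern longer than the sequence yields an empty hit list, not an
  error.
* Ties and orderings are fixed (sites by key, hits by start,
  annotations by accession/label/offset, JSON keys sorted) so re-running
  the pipeline on identical inputs is byte-identical.
* `merge_sources` resolves a species disagreement within one dedup key
  by the fixed order human < mouse < rat < other, keeping the merge
  order-insensitive.

## Known limitations

* Registry boundaries outside the hand-placed chains are schematic by
  construction.
* No isoform lifting, no cross-accession merging, no phosphosite
  prediction, no 3-D distance to cleavage sites — sequence-order
  offsets only.
* Conservation requires an externally computed alignment and treats
  columns independently; no substitution-model scoring.
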