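# phosmap

Harmonize, validate and map **experimentally verified extracellular
phosphosites** onto protein domain architectures.

Mass-spectrometry databases report thousands of phosphorylated serines,
threonines and tyrosines on extracellular matrix proteins — nearly the
whole 28-type collagen family, most MMPs and BMPs — with secreted
kinases (FAM20C, VLK) and surface-associated kinases (PKA, CKII) as
candidate writers. Making sense of these lists requires the same
bookkeeping every such study repeats by hand: merging inconsistent
per-database exports, checking each claimed site against the actual
sequence, asking whether a site sits in a kinase recognition motif,
how far it lies from a proteolytic cleavage bond or a binding motif,
which domain of the protein carries it, and whether orthologs share it.
phosmap packages that analysis layer as a tested library and CLI.

It does **not** query the source databases or predict phosphosites:
inputs are exported site tables (TSV), protein sequences (FASTA),
feature tables (cleavage bonds, binding intervals) and, optionally, an
aligned FASTA for conservation analysis.

## Core quantities

* **Harmonization.** Site identity is (accession, 1-based position,
  residue). Sources are unioned into per-site provenance; conflicting
  residue claims at one position drop both rows; validation retains a
  site iff the sequence letter at the claimed position matches the
  claim, and partitions the input exactly
  (`n_input = n_retained + n_residue_mismatch + n_out_of_range +
  n_predicted_dropped`).
* **Motif scanning.** The FAM20C motif S-x-E (any residue at x) and the
  phospho-primed S-x-pS variant, where the second serine must carry a
  verified phosphosite — plus literal motifs with alternatives such as
  RGD and KGHRG(F/Y). All overlapping windows are reported; `X` matches
  nothing.
* **Cleavage proximity.** A cleavage site is the scissile bond
  (P1, P1′); the k-th residue after the bond has offset +k
  (`position − P1`), the k-th before it −k (`position − P1′`), never 0.
  Two enzymes cutting bonds d residues apart therefore satisfy
  `offset_A − offset_B = d` for every shared downstream site. Default
  adjacency window: 35 residues (the PCPE-1 binding extent downstream
  of the BMP1 bond).
* **Architecture and conservation.** A packaged registry of block
  domain architectures for the 45 collagen α-chains (28 types) plus
  MMP/BMP records assigns each site to its domain; an alignment
  projection maps sites to columns and flags conserved-phospho columns
  (≥ m rows with a verified site, default m = 2).

## Worked example

Offsets of the three procollagen α1(I) N-telopeptide phosphosites from
the two N-propeptide proteinase bonds, using the packaged coordinate
fixtures:

```python
import phosmap as pm

b = pm.paper_fixture()
adamts2 = b.feature("COL1A1", "ADAMTS2")
meprin = b.feature("COL1A1", "meprin-N")
for p in (171, 172, 176):
    print(f"S{p}: ADAMTS2 {pm.signed_offset(p, adamts2):+d}, "
          f"meprin {pm.signed_offset(p, meprin):+d}")
telo = pm.SiteTable(s for s in b.sites.for_accession("COL1A1")
                    if s.position in (171, 172, 176))
print("bond separation:", pm.dual_enzyme_consistency(telo, adamts2, meprin))
print("S544 vs TACE:", pm.signed_offset(544, b.feature("COL17A1", "TACE")))
```

```
S171: ADAMTS2 +10, meprin +4
S172: ADAMTS2 +11, meprin +5
S176: ADAMTS2 +15, meprin +9
bond separation: 6
S544 vs TACE: 5
```

The same three sites are 10/11/15 residues downstream of the ADAMTS2
bond and 4/5/9 downstream of the meprin bond — consistent because the
bonds are 6 residues apart — and the collagen XVII ectodomain site S544
is 5 residues downstream of the TACE shedding bond, where its
phosphorylation inhibits shedding.

The CLI chains the same stages on any inputs; here on a synthetic
multi-source bundle with known ground truth:

```sh
phosmap makedata --seed 7 --out data
phosmap harmonize --sites data/sites_synthA.tsv --sites data/sites_synthB.tsv \
    --fasta data/proteins.fa --out merged.tsv --report report.json
# retained 38/48 sites (10 residue mismatches, 0 out of range, 0 predicted dropped)
phosmap scan --fasta data/proteins.fa --sites merged.tsv \
    --pattern "S-x-E" --literal RGD --out hits.tsv
# 18 hits
phosmap proximity --sites merged.tsv --features data/features.tsv --out prox.tsv
# 76 annotations, 32 within 35 residues
```

The 10 residue mismatches are exactly the sites the generator corrupted
(its truth record lists them), and the 18 hits are exactly the planted
motif instances. `phosmap summarize`, `phosmap conserve` and
`phosmap run <config.yaml>` cover the remaining stages; file formats are
documented in `docs/formats.md` and the model in `docs/methods.md`.

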