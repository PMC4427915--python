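"""Synthetic data generator and curated literature fixtures.

The public phosphosite databases behind extracellular-phosphorylation
maps cannot be redistributed, so every pipeline stage is exercised on two
kinds of inputs generated here:

* :func:`generate_synthetic` emulates multi-source database exports with
  a known ground truth: planted phosphosites split across two synthetic
  "source databases" with a controlled duplicate fraction, a controlled
  fraction of sites corrupted to wrong residue letters (exercising
  sequence validation), planted motif instances, and planted cleavage
  bonds.  Background sequence that would accidentally match a planted
  pattern is rewritten (a rejection step), so the truth record lists
  *exactly* the matches present and recovery tests can be exact rather
  than statistical.

* :func:`paper_fixture` packages short peptides and residue coordinates
  reported in the extracellular-phosphorylation literature (e.g. the
  PEDF-binding motif IKGHRGFSGL of collagen α1(I), the collagen XVII
  shedding site S544 five residues downstream of the TACE bond, the
  procollagen N- and C-propeptide cleavage offsets).  Printed residue
  numbers are preserved by embedding them in synthetic stubs padded with
  glycine, so no full database sequence is shipped; every stub is
  synthetic and labelled as such.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core_io import (
    AMINO_ACIDS,
    PhosmapError,
    PhosphoSite,
    ProteinRecord,
    SequenceFeature,
    SiteTable,
    write_fasta,
    write_feature_table,
    write_site_table,
)
from .motif_scan import ANY, MotifPattern, parse_literal, parse_pattern, scan

SOURCE_A = "SynthDB-A"
SOURCE_B = "SynthDB-B"
_AGENTS = ("BMP1", "ADAMTS2", "meprin", "TACE")
_SPECIES_CYCLE = ("human", "mouse", "rat")


class FixtureError(PhosmapError):
    pass


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------


@dataclass
class SyntheticBundle:
    """Generated inputs plus the exact ground truth used to make them."""

    proteins: list[ProteinRecord]
    source_tables: dict[str, list[PhosphoSite]]
    features: list[SequenceFeature]
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA + per-source site TSVs + feature TSV + truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "proteins.fa",
            "sites_a": outdir / "sites_synthA.tsv",
            "sites_b": outdir / "sites_synthB.tsv",
            "features": outdir / "features.tsv",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.proteins, paths["fasta"])
        write_site_table(SiteTable.from_sites(self.source_tables[SOURCE_A]), paths["sites_a"])
        write_site_table(SiteTable.from_sites(self.source_tables[SOURCE_B]), paths["sites_b"])
        write_feature_table(self.features, paths["features"])
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


def _structural(pattern: MotifPattern) -> MotifPattern:
    """The pattern with priming requirements ignored (sequence-only)."""
    if not pattern.primed_positions:
        return pattern
    return MotifPattern(
        pattern_id=pattern.pattern_id,
        elements=pattern.elements,
        primed_positions=frozenset(),
    )


def _parse_any(text: str) -> MotifPattern:
    return parse_pattern(text) if "-" in text else parse_literal(text)


def _reserve(
    rng: np.random.Generator,
    length: int,
    span: int,
    margin: int,
    reserved: list[tuple[int, int]],
    attempts: int = 2000,
) -> int:
    """Pick a 0-based start for a span keeping ``margin`` clearance."""
    for _ in range(attempts):
        start = int(rng.integers(0, length - span + 1))
        lo, hi = start - margin, start + span - 1 + margin
        if all(hi < r_lo or lo > r_hi for r_lo, r_hi in reserved):
            reserved.append((start, start + span - 1))
            return start
    raise FixtureError(
        f"cannot place a span of {span} residues in length {length}: "
        "too many planted elements for the sequence length"
    )


def generate_synthetic(
    n_proteins: int = 6,
    length_range: tuple[int, int] = (150, 250),
    n_sites_per_protein: int = 8,
    planted_motifs: Sequence[tuple[str, int]] = (("S-x-E", 2), ("RGD", 1)),
    planted_cleavages: int = 2,
    seed: int = 0,
    overlap_fraction: float = 0.5,
    corruption_fraction: float = 0.2,
    window: int = 35,
) -> SyntheticBundle:
    """Emulate multi-source phosphosite exports with exact ground truth.

    Deterministic given ``seed``.  Per protein: a uniform-random sequence
    of the 20 letters, ``n_sites_per_protein`` planted S/T/Y sites,
    planted motif instances, and ``planted_cleavages`` cleavage bonds.
    Planted items keep a clearance of the longest pattern between them,
    and a rewrite pass mutates any background window that accidentally
    matches a planted pattern, so the truth record is exhaustive.

    ``overlap_fraction`` of each protein's sites is reported by both
    synthetic sources (known duplicate count); ``corruption_fraction`` of
    all sites is reported with a wrong residue letter (known
    residue-mismatch tally for validation).
    """
    if n_proteins < 1 or n_sites_per_protein < 0:
        raise FixtureError("counts must be positive")
    rng = np.random.default_rng(seed)
    patterns = [_parse_any(text) for text, _ in planted_motifs]
    counts = [count for _, count in planted_motifs]
    max_len = max((len(p) for p in patterns), default=1)
    if any(len(p) >= length_range[0] for p in patterns):
        raise FixtureError("pattern length must be below the minimum length")
    alphabet = sorted(AMINO_ACIDS)
    pattern_letters = set().union(
        *(el for p in patterns for el in p.elements if el is not ANY)
    ) if patterns else set()
    # letters that can never complete a planted pattern at a literal slot:
    # mutating to one of these only destroys matches, never creates one
    safe = sorted(AMINO_ACIDS - pattern_letters - {"S", "T", "Y"}) or ["G"]

    proteins: list[ProteinRecord] = []
    truth_sites: list[dict] = []
    truth_motifs: list[dict] = []
    truth_cleavages: list[dict] = []
    truth_adjacency: list[dict] = []
    features: list[SequenceFeature] = []
    site_rows: list[PhosphoSite] = []

    for index in range(n_proteins):
        accession = f"SYN{index + 1:03d}"
        species = _SPECIES_CYCLE[index % len(_SPECIES_CYCLE)]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = list(rng.choice(alphabet, size=length))
        reserved: list[tuple[int, int]] = []

        # plant motif instances
        planted_spans: list[tuple[MotifPattern, int]] = []
        for pattern, count in zip(patterns, counts):
            for _ in range(count):
                start0 = _reserve(rng, length, len(pattern), max_len, reserved)
                for offset, element in enumerate(pattern.elements):
                    letters = sorted(element)
                    seq[start0 + offset] = str(rng.choice(letters))
                planted_spans.append((pattern, start0))

        # plant phosphosites (length-1 spans, same clearance)
        site_positions: list[int] = []
        for _ in range(n_sites_per_protein):
            start0 = _reserve(rng, length, 1, max_len, reserved)
            seq[start0] = str(rng.choice(["S", "T", "Y"]))
            site_positions.append(start0 + 1)
        site_positions.sort()

        # rewrite background windows that accidentally match a pattern
        protected = {
            pos
            for pattern, start0 in planted_spans
            for pos in range(start0, start0 + len(pattern))
        } | {p - 1 for p in site_positions}
        planted_keys = {(p.pattern_id, s0) for p, s0 in planted_spans}
        for _ in range(200):
            record = ProteinRecord(
                accession=accession, species=species, sequence="".join(seq)
            )
            accidental = [
                (pattern, hit.start - 1)
                for pattern in patterns
                for hit in scan(record, _structural(pattern))
                if (pattern.pattern_id, hit.start - 1) not in planted_keys
            ]
            if not accidental:
                break
            pattern, start0 = accidental[0]
            breakable = [
                i
                for i, element in enumerate(pattern.elements)
                if element is not ANY and (start0 + i) not in protected
            ]
            if not breakable:
                raise FixtureError(
                    f"{accession}: accidental match at {start0 + 1} cannot "
                    "be rewritten without touching planted material"
                )
            seq[start0 + breakable[0]] = str(rng.choice(safe))
        else:
            raise FixtureError(f"{accession}: rewrite pass did not converge")

        protein = ProteinRecord(
            accession=accession,
            name=f"synthetic protein {index + 1}",
            species=species,
            sequence="".join(seq),
        )
        proteins.append(protein)

        for pattern, start0 in sorted(planted_spans, key=lambda x: x[1]):
            truth_motifs.append(
                {
                    "accession": accession,
                    "pattern": pattern.pattern_id,
                    "start": start0 + 1,
                    "end": start0 + len(pattern),
                    "matched": protein.sequence[start0 : start0 + len(pattern)],
                }
            )

        # cleavage bonds (kept clear of sequence ends)
        bond_p1s = sorted(
            int(p)
            for p in rng.choice(
                np.arange(10, length - 10), size=planted_cleavages, replace=False
            )
        )
        for bond_index, p1 in enumerate(bond_p1s):
            agent = _AGENTS[bond_index % len(_AGENTS)]
            label = f"{agent}-{bond_index + 1}"
            feature = SequenceFeature(
                accession=accession,
                kind="cleavage_site",
                start=p1,
                end=p1 + 1,
                label=label,
                agent=agent,
            )
            features.append(feature)
            truth_cleavages.append(
                {"accession": accession, "p1": p1, "agent": agent, "label": label}
            )
            for position in site_positions:
                offset = position - p1 if position > p1 else position - (p1 + 1)
                truth_adjacency.append(
                    {
                        "accession": accession,
                        "position": position,
                        "label": label,
                        "offset": offset,
                        "within_window": abs(offset) <= window,
                    }
                )

        for position in site_positions:
            truth_sites.append(
                {
                    "accession": accession,
                    "position": position,
                    "residue": protein.sequence[position - 1],
                    "species": species,
                }
            )

    # corruption: flip the claimed residue letter of a known subset
    n_total = len(truth_sites)
    n_corrupt = int(round(corruption_fraction * n_total))
    corrupt_indices = set(
        int(i)
        for i in rng.choice(np.arange(n_total), size=n_corrupt, replace=False)
    ) if n_corrupt else set()
    for i, entry in enumerate(truth_sites):
        entry["corrupted"] = i in corrupt_indices
        if i in corrupt_indices:
            wrong = [r for r in "STY" if r != entry["residue"]]
            entry["claimed_residue"] = str(rng.choice(wrong))
        else:
            entry["claimed_residue"] = entry["residue"]

    # split sites between the two sources with a known duplicate count
    tables: dict[str, list[PhosphoSite]] = {SOURCE_A: [], SOURCE_B: []}
    n_duplicates = 0
    by_protein: dict[str, list[dict]] = {}
    for entry in truth_sites:
        by_protein.setdefault(entry["accession"], []).append(entry)
    for accession in sorted(by_protein):
        entries = by_protein[accession]
        n_shared = int(round(overlap_fraction * len(entries)))
        n_duplicates += n_shared
        for j, entry in enumerate(entries):
            site = PhosphoSite(
                accession=entry["accession"],
                position=entry["position"],
                residue=entry["claimed_residue"],
                species=entry["species"],
                sources=frozenset([SOURCE_A]),
                evidence="verified",
            )
            if j < n_shared:
                tables[SOURCE_A].append(site)
                tables[SOURCE_B].append(
                    PhosphoSite(
                        accession=site.accession,
                        position=site.position,
                        residue=site.residue,
                        species=site.species,
                        sources=frozenset([SOURCE_B]),
                        evidence="verified",
                    )
                )
            elif j % 2 == 0:
                tables[SOURCE_A].append(site)
            else:
                tables[SOURCE_B].append(
                    PhosphoSite(
                        accession=site.accession,
                        position=site.position,
                        residue=site.residue,
                        species=site.species,
                        sources=frozenset([SOURCE_B]),
                        evidence="verified",
                    )
                )

    truth = {
        "seed": int(seed),
        "window": int(window),
        "n_proteins": n_proteins,
        "n_sites": n_total,
        "n_corrupted": n_corrupt,
        "n_duplicates": n_duplicates,
        "proteins": [
            {"accession": p.accession, "length": p.length, "species": p.species}
            for p in proteins
        ],
        "sites": truth_sites,
        "motifs": truth_motifs,
        "cleavages": truth_cleavages,
        "adjacency": truth_adjacency,
        "patterns": [text for text, _ in planted_motifs],
    }
    return SyntheticBundle(
        proteins=proteins, source_tables=tables, features=features, truth=truth
    )


# ---------------------------------------------------------------------------
# Literature fixtures
# ---------------------------------------------------------------------------


def _stub(
    accession: str,
    name: str,
    species: str,
    length: int,
    letters: dict[int, str] | None = None,
    substrings: dict[int, str] | None = None,
) -> ProteinRecord:
    """Synthetic glycine-padded stub preserving printed residue numbers."""
    seq = ["G"] * length
    for start, text in (substrings or {}).items():
        for offset, ch in enumerate(text):
            seq[start - 1 + offset] = ch
    for position, ch in (letters or {}).items():
        seq[position - 1] = ch
    return ProteinRecord(
        accession=accession,
        name=f"{name} [synthetic stub]",
        species=species,
        sequence="".join(seq),
    )


@dataclass
class PaperBundle:
    """Curated peptides, coordinate stubs, sites and features.

    ``peptides`` use peptide-local 1-based coordinates; ``proteins`` are
    glycine-padded stubs preserving the literature residue numbering.
    ``priming_site`` is the second serine of the furin recognition
    sequence of BMP1 (S118 in R-S-R-S-R-R | A-A), supplied separately so
    primed-motif behaviour can be tested with and without it.
    """

    peptides: list[ProteinRecord]
    proteins: list[ProteinRecord]
    sites: SiteTable
    features: list[SequenceFeature]
    priming_site: PhosphoSite

    @property
    def rgd_peptides(self) -> list[ProteinRecord]:
        return [p for p in self.peptides if "RGD" in p.sequence]

    def protein(self, accession: str) -> ProteinRecord:
        for record in self.proteins + self.peptides:
            if record.accession == accession:
                return record
        raise KeyError(accession)

    def feature(self, accession: str, label: str) -> SequenceFeature:
        for feature in self.features:
            if feature.accession == accession and feature.label == label:
                return feature
        raise KeyError((accession, label))

    def features_for(self, accession: str) -> list[SequenceFeature]:
        return [f for f in self.features if f.accession == accession]


_SOURCE = frozenset(["curated-literature"])


def _site(acc: str, pos: int, res: str, species: str = "human") -> PhosphoSite:
    return PhosphoSite(
        accession=acc,
        position=pos,
        residue=res,
        species=species,
        sources=_SOURCE,
        evidence="verified",
    )


def paper_fixture() -> PaperBundle:
    """Bundle of reported peptides, phosphosites and cleavage coordinates.

    Includes: the six reported RGD-context peptides (one RGD each); the
    PEDF-binding motif IKGHRGFSGL of collagen α1(I), which contains the
    heparin motif KGHRG(F/Y); the furin recognition sequence of BMP1 with
    its internal S-x-S motif; stubs for vitronectin, PEDF, MMP2, collagen
    XVII and procollagens α1(I)/α2(I)/α1(II)/α1(III) whose cleavage bonds
    are placed so that every reported site-to-bond offset is reproduced
    exactly (e.g. three α1(I) N-telopeptide sites 10/11/15 residues
    downstream of the ADAMTS2 bond and 4/5/9 downstream of the meprin
    bond six residues further along).
    """
    peptides = [
        # RGD-context peptides with their reported phosphoacceptor
        _stub("COL4A2_pep", "collagen alpha2(IV) S1446 context", "human", 9,
              substrings={1: "SAVPGFRGD"}),
        _stub("COL4A3_pep", "collagen alpha3(IV) S1435 context", "human", 4,
              substrings={1: "RGDS"}),
        _stub("COL5A2_pep", "collagen alpha2(V) S137 context", "mouse", 7,
              substrings={1: "SQGPRGD"}),
        _stub("COL6A3_pep", "collagen alpha3(VI) S2048 context", "human", 11,
              substrings={1: "RGDRGPIGSIG"}),
        _stub("COL11A2_pep", "collagen alpha2(XI) T576 context", "human", 4,
              substrings={1: "RGDT"}),
        _stub("COL22A1_pep", "collagen alpha1(XXII) S1038 context", "human", 4,
              substrings={1: "SRGD"}),
        # PEDF / heparin binding motif of collagen alpha1(I)
        _stub("COL1A1_pep", "collagen alpha1(I) PEDF-binding motif", "human", 10,
              substrings={1: "IKGHRGFSGL"}),
        # furin recognition sequence of BMP1 (bond after the sixth residue)
        _stub("BMP1_pep", "BMP1 furin recognition context", "human", 8,
              substrings={1: "RSRSRRAA"}),
    ]
    peptide_sites = [
        _site("COL4A2_pep", 1, "S"),
        _site("COL4A3_pep", 4, "S"),
        _site("COL5A2_pep", 1, "S", "mouse"),
        _site("COL6A3_pep", 9, "S"),
        _site("COL11A2_pep", 4, "T"),
        _site("COL22A1_pep", 1, "S"),
    ]

    proteins = [
        _stub("VTN", "vitronectin", "human", 380,
              letters={50: "T", 57: "T", 378: "S"},
              substrings={45: "RGD"}),
        _stub("PEDF", "pigment epithelium-derived factor", "human", 230,
              letters={24: "S", 114: "S", 227: "S"}),
        _stub("MMP2", "MMP-2 (gelatinase A)", "human", 660,
              letters={250: "T", 271: "Y", 365: "S"}),
        _stub("COL17A1", "collagen alpha1(XVII)", "human", 1497,
              letters={544: "S"}),
        _stub("COL1A1", "procollagen alpha1(I)", "human", 1400,
              letters={171: "S", 172: "S", 176: "S", 1068: "S", 1216: "S"},
              substrings={1050: "IKGHRGFSGL"}),
        _stub("COL1A2", "procollagen alpha2(I)", "human", 1366,
              letters={1115: "S", 1148: "T", 1151: "S", 1157: "S"}),
        _stub("COL2A1", "procollagen alpha1(II)", "human", 1400,
              letters={60: "S", 1390: "S"}),
        _stub("COL3A1", "procollagen alpha1(III)", "human", 1466,
              letters={1237: "S"}),
        _stub("BMP1", "BMP-1 (procollagen C-proteinase)", "human", 320,
              substrings={115: "RSRSRRAA"}),
    ]
    protein_sites = [
        _site("VTN", 50, "T"),
        _site("VTN", 57, "T"),
        _site("VTN", 378, "S"),
        _site("PEDF", 24, "S"),
        _site("PEDF", 114, "S"),
        _site("PEDF", 227, "S"),
        _site("MMP2", 250, "T"),
        _site("MMP2", 271, "Y"),
        _site("MMP2", 365, "S"),
        _site("COL17A1", 544, "S"),
        _site("COL1A1", 171, "S"),
        _site("COL1A1", 172, "S"),
        _site("COL1A1", 176, "S"),
        _site("COL1A1", 1068, "S"),
        _site("COL1A1", 1216, "S"),
        _site("COL1A2", 1115, "S"),
        _site("COL1A2", 1148, "T"),
        _site("COL1A2", 1151, "S"),
        _site("COL1A2", 1157, "S"),
        _site("COL2A1", 60, "S"),
        _site("COL2A1", 1390, "S"),
        _site("COL3A1", 1237, "S"),
    ]

    def bond(acc: str, p1: int, label: str, agent: str, note: str) -> SequenceFeature:
        return SequenceFeature(
            accession=acc, kind="cleavage_site", start=p1, end=p1 + 1,
            label=label, agent=agent, note=note,
        )

    features = [
        SequenceFeature("VTN", "motif_interval", 45, 47, "RGD",
                        note="integrin-binding tripeptide; T50/T57 nearby"),
        bond("COL17A1", 539, "TACE", "TACE",
             "ectodomain shedding bond; S544 is 5 residues downstream"),
        bond("COL1A1", 161, "ADAMTS2", "ADAMTS2",
             "N-propeptide bond; sites 10/11/15 residues downstream"),
        bond("COL1A1", 167, "meprin-N", "meprin",
             "N-propeptide bond; the same sites 4/5/9 residues downstream"),
        bond("COL1A1", 1200, "BMP1", "BMP1",
             "C-propeptide bond; one site 16 residues downstream"),
        bond("COL1A1", 1209, "meprin-C", "meprin",
             "C-propeptide bond; the same site 7 residues downstream"),
        SequenceFeature("COL1A1", "binding_region", 1201, 1235, "PCPE1-binding",
                        agent="PCPE-1",
                        note="35 residues downstream of the BMP1 bond are "
                             "critical for PCPE-1 binding"),
        SequenceFeature("COL1A1", "binding_region", 1050, 1059, "PEDF-binding",
                        agent="PEDF",
                        note="IKGHRGFSGL; one site 9 residues downstream"),
        bond("COL1A2", 1119, "meprin-C", "meprin",
             "C-propeptide bond; one site 5 residues upstream"),
        bond("COL1A2", 1129, "BMP1", "BMP1",
             "C-propeptide bond; one site 15 residues upstream, "
             "others 19/22/28 downstream"),
        bond("COL2A1", 161, "ADAMTS2", "ADAMTS2",
             "N-propeptide bond; verified sites lie far from it"),
        bond("COL2A1", 1200, "BMP1", "BMP1",
             "C-propeptide bond; verified sites lie far from it"),
        bond("COL3A1", 1221, "BMP1", "BMP1",
             "C-propeptide bond; one site 16 residues downstream"),
        bond("COL3A1", 1221, "meprin-C", "meprin",
             "meprin cuts the same bond as BMP1 here"),
        bond("BMP1", 120, "furin", "furin",
             "activation bond R120|A121 inside R-S-R-S-R-R"),
        SequenceFeature("BMP1", "motif_interval", 115, 120, "furin-recognition",
                        agent="furin",
                        note="contains an S-x-S motif; the second serine "
                             "would need to be phosphorylated to prime it"),
    ]

    priming_site = _site("BMP1", 118, "S")

    return PaperBundle(
        peptides=peptides,
        proteins=proteins,
        sites=SiteTable.from_sites(peptide_sites + protein_sites),
        features=features,
        priming_site=priming_site,
    )
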