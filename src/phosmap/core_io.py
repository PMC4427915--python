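"""Domain types and readers/writers for the phosphosite-mapping pipeline.

All coordinates in this package are 1-based and inclusive, matching the
residue numbering used in the phosphoproteomics literature (a site written
"S544" is the serine at sequence position 544).  The feature-table format
therefore deliberately diverges from 0-based half-open BED; its header
comment says so.

A proteolytic cleavage site is stored as the scissile *bond* between the
P1 residue (upstream) and the P1' residue (downstream), never as a single
residue, so that "k residues downstream of the cleavage site" is
unambiguous.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment

logger = logging.getLogger("phosmap")

#: The 20 standard amino-acid letters.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Letters accepted in a sequence: the 20 standard residues plus the
#: unknown-residue placeholder X (X never matches any scan pattern).
SEQUENCE_LETTERS = AMINO_ACIDS | {"X"}

#: Closed species vocabulary.  Phosphosite maps in this field colour-code
#: sites by species (human / mouse / rat); anything else is "other" and is
#: kept, never dropped.
SPECIES = ("human", "mouse", "rat", "other")

_SPECIES_ALIASES = {
    "human": "human",
    "homo sapiens": "human",
    "h. sapiens": "human",
    "hsapiens": "human",
    "mouse": "mouse",
    "mus musculus": "mouse",
    "m. musculus": "mouse",
    "rat": "rat",
    "rattus norvegicus": "rat",
    "r. norvegicus": "rat",
}

PHOSPHO_RESIDUES = frozenset("STY")
EVIDENCE_LEVELS = ("verified", "predicted")
FEATURE_KINDS = ("cleavage_site", "motif_interval", "binding_region", "domain_segment")

#: Fixed vocabulary of domain-segment labels used by architecture records.
DOMAIN_LABELS = (
    "signal_peptide",
    "N_propeptide",
    "triple_helix",
    "interruption",
    "C_propeptide",
    "NC_domain",
    "ectodomain",
    "cytoplasmic",
    "transmembrane",
    "other",
)


class PhosmapError(Exception):
    """Base class for all phosmap errors."""


class FastaError(PhosmapError):
    pass


class SiteTableFormatError(PhosmapError):
    pass


class FeatureTableError(PhosmapError):
    pass


class AlignmentError(PhosmapError):
    pass


def normalize_species(value: str | None) -> str:
    """Map a free-text organism string onto the closed species vocabulary."""
    if value is None:
        return "other"
    return _SPECIES_ALIASES.get(str(value).strip().lower(), "other")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with identity and species; positions are 1-based."""

    accession: str
    name: str = ""
    gene: str = ""
    species: str = "other"
    sequence: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if self.species not in SPECIES:
            object.__setattr__(self, "species", normalize_species(self.species))
        bad = [i for i, ch in enumerate(seq, start=1) if ch not in SEQUENCE_LETTERS]
        if bad:
            raise FastaError(
                f"record {self.accession!r}: invalid residue "
                f"{seq[bad[0] - 1]!r} at position {bad[0]}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def residue_at(self, position: int) -> str:
        """Residue letter at a 1-based position."""
        if not 1 <= position <= self.length:
            raise PhosmapError(
                f"position {position} outside [1, {self.length}] "
                f"for {self.accession}"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class PhosphoSite:
    """One modified residue with multi-source provenance."""

    accession: str
    position: int
    residue: str
    species: str = "other"
    sources: frozenset[str] = frozenset()
    evidence: str = "verified"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise PhosmapError(
                f"site position must be >= 1, got {self.position} "
                f"on {self.accession}"
            )
        if self.residue not in PHOSPHO_RESIDUES:
            raise PhosmapError(
                f"phosphosite residue must be S, T or Y, got {self.residue!r} "
                f"at {self.accession}:{self.position}"
            )
        if self.evidence not in EVIDENCE_LEVELS:
            raise PhosmapError(f"unknown evidence level {self.evidence!r}")
        if not isinstance(self.sources, frozenset):
            object.__setattr__(self, "sources", frozenset(self.sources))
        if not self.sources:
            raise PhosmapError(
                f"site {self.accession}:{self.residue}{self.position} "
                "has no source"
            )
        if self.species not in SPECIES:
            object.__setattr__(self, "species", normalize_species(self.species))

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.accession, self.position, self.residue)


@dataclass(frozen=True)
class SequenceFeature:
    """A cleavage bond, motif interval, binding region or domain segment.

    For ``cleavage_site`` features ``end == start + 1`` and the feature
    denotes the scissile bond between residues ``start`` (P1) and ``end``
    (P1'); all other kinds are 1-based inclusive intervals.
    """

    accession: str
    kind: str
    start: int
    end: int
    label: str
    agent: str | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise FeatureTableError(f"unknown feature kind {self.kind!r}")
        if self.kind == "cleavage_site":
            if self.end != self.start + 1:
                raise FeatureTableError(
                    f"cleavage_site {self.label!r} on {self.accession}: "
                    f"end must equal start + 1 (scissile bond), got "
                    f"{self.start}..{self.end}"
                )
        elif not 1 <= self.start <= self.end:
            raise FeatureTableError(
                f"feature {self.label!r} on {self.accession}: require "
                f"1 <= start <= end, got {self.start}..{self.end}"
            )
        if self.start < 1:
            raise FeatureTableError(
                f"feature {self.label!r} on {self.accession}: start < 1"
            )

    @property
    def p1(self) -> int:
        """P1 residue of a cleavage bond."""
        if self.kind != "cleavage_site":
            raise PhosmapError(f"{self.label!r} is not a cleavage site")
        return self.start

    @property
    def p1_prime(self) -> int:
        if self.kind != "cleavage_site":
            raise PhosmapError(f"{self.label!r} is not a cleavage site")
        return self.end


class SiteTable:
    """A deduplicated phosphosite table keyed on (accession, position, residue).

    The provenance index maps each key to the union of database sources
    that reported the site.
    """

    def __init__(self, rows: Iterable[PhosphoSite] = ()) -> None:
        self._rows: dict[tuple[str, int, str], PhosphoSite] = {}
        for site in rows:
            if site.key in self._rows:
                raise PhosmapError(
                    f"duplicate site key {site.key}; use SiteTable.from_sites "
                    "to union provenance"
                )
            self._rows[site.key] = site

    @classmethod
    def from_sites(cls, sites: Iterable[PhosphoSite]) -> "SiteTable":
        """Build a table, unioning sources for identical (acc, pos, residue)."""
        merged: dict[tuple[str, int, str], PhosphoSite] = {}
        for site in sites:
            prev = merged.get(site.key)
            if prev is None:
                merged[site.key] = site
            else:
                evidence = (
                    "verified"
                    if "verified" in (prev.evidence, site.evidence)
                    else prev.evidence
                )
                species = min(
                    (prev.species, site.species), key=SPECIES.index
                )
                merged[site.key] = replace(
                    prev,
                    sources=prev.sources | site.sources,
                    evidence=evidence,
                    species=species,
                )
        table = cls.__new__(cls)
        table._rows = merged
        return table

    @property
    def rows(self) -> list[PhosphoSite]:
        return sorted(self._rows.values(), key=lambda s: s.key)

    @property
    def provenance_index(self) -> dict[tuple[str, int, str], frozenset[str]]:
        return {key: site.sources for key, site in self._rows.items()}

    def for_accession(self, accession: str) -> "SiteTable":
        return SiteTable(s for s in self.rows if s.accession == accession)

    def verified_positions(self, accession: str) -> frozenset[int]:
        """Positions of verified sites on one protein."""
        return frozenset(
            s.position
            for s in self._rows.values()
            if s.accession == accession and s.evidence == "verified"
        )

    def accessions(self) -> list[str]:
        return sorted({s.accession for s in self._rows.values()})

    def get(self, key: tuple[str, int, str]) -> PhosphoSite | None:
        return self._rows.get(key)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "accession": s.accession,
                    "position": s.position,
                    "residue": s.residue,
                    "species": s.species,
                    "source": ",".join(sorted(s.sources)),
                    "evidence": s.evidence,
                }
                for s in self.rows
            ],
            columns=["accession", "position", "residue", "species", "source", "evidence"],
        )

    def __len__(self) -> int:
        return len(self._rows)

    def __iter__(self) -> Iterator[PhosphoSite]:
        return iter(self.rows)

    def __contains__(self, key: tuple[str, int, str]) -> bool:
        return key in self._rows

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SiteTable):
            return NotImplemented
        return self._rows == other._rows

    def __repr__(self) -> str:
        return f"SiteTable({len(self)} sites, {len(self.accessions())} proteins)"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _parse_fasta_header(header: str) -> tuple[str, str, str]:
    """Split an ``accession|name|species`` header; fall back gracefully."""
    parts = header.split("|")
    accession = parts[0].strip()
    name = parts[1].strip() if len(parts) > 1 else ""
    species = normalize_species(parts[2]) if len(parts) > 2 else "other"
    return accession, name, species


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from FASTA.

    Headers of the form ``>accession|name|species`` populate all identity
    fields; any other header is taken whole as the accession with species
    ``other``.  Sequences are uppercased; residue letters outside the 20
    standard amino acids plus X raise :class:`FastaError` naming the record
    and offset.
    """
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        accession, name, species = _parse_fasta_header(entry.description)
        records.append(
            ProteinRecord(
                accession=accession,
                name=name,
                species=species,
                sequence=str(entry.seq),
            )
        )
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f"{rec.accession}|{rec.name}|{rec.species}"
            fh.write(f">{header}\n")
            for i in range(0, rec.length, 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Site tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteDialect:
    """Column mapping for one site-table dialect.

    ``site_column`` holds combined strings like ``"S544"`` (split into
    residue and position); otherwise ``position_column`` and
    ``residue_column`` are separate.  ``site_strip_suffixes`` removes
    modification suffixes such as ``"-p"`` before splitting.
    """

    accession_column: str
    species_column: str | None = None
    position_column: str | None = None
    residue_column: str | None = None
    site_column: str | None = None
    source_column: str | None = None
    evidence_column: str | None = None
    default_source: str = "unknown"
    default_evidence: str = "verified"
    site_strip_suffixes: tuple[str, ...] = ()

    @property
    def mandatory_columns(self) -> tuple[str, ...]:
        cols = [self.accession_column]
        if self.site_column:
            cols.append(self.site_column)
        else:
            cols.extend([self.position_column, self.residue_column])
        return tuple(c for c in cols if c)


DIALECTS: Mapping[str, SiteDialect] = {
    "unified": SiteDialect(
        accession_column="accession",
        species_column="species",
        position_column="position",
        residue_column="residue",
        source_column="source",
        evidence_column="evidence",
    ),
    "phosphositeplus_like": SiteDialect(
        accession_column="ACC_ID",
        species_column="ORGANISM",
        site_column="MOD_RSD",
        default_source="PhosphoSitePlus",
        site_strip_suffixes=("-p",),
    ),
    "uniprot_like": SiteDialect(
        accession_column="Accession",
        species_column="Species",
        site_column="Site",
        source_column="Source",
        evidence_column="Evidence",
        default_source="UniProt",
    ),
}


@dataclass(frozen=True)
class ParseIssue:
    """One malformed row, skipped with a diagnostic."""

    line: int
    message: str


class SiteReadResult(list):
    """List of :class:`PhosphoSite` plus the parse issues encountered."""

    def __init__(self, sites: Iterable[PhosphoSite], errors: list[ParseIssue]):
        super().__init__(sites)
        self.errors = list(errors)


def _split_site_string(text: str, strip_suffixes: tuple[str, ...]) -> tuple[str, int]:
    """Split ``"S544"`` into ``("S", 544)``."""
    text = str(text).strip()
    for suffix in strip_suffixes:
        if text.endswith(suffix):
            text = text[: -len(suffix)]
    if len(text) < 2 or text[0].upper() not in PHOSPHO_RESIDUES:
        raise ValueError(f"cannot parse site string {text!r}")
    return text[0].upper(), int(text[1:])


def read_site_table(
    path: str | Path,
    dialect: str = "unified",
    strict: bool = False,
) -> SiteReadResult:
    """Read a phosphosite TSV in one of the supported dialects.

    Malformed rows (unparsable position, non-STY residue) are skipped and
    collected as :class:`ParseIssue` diagnostics on the returned list's
    ``errors`` attribute; ``strict=True`` upgrades the first such row to a
    :class:`SiteTableFormatError`.  A missing mandatory column always
    raises, naming the column.
    """
    if dialect not in DIALECTS:
        raise SiteTableFormatError(
            f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}"
        )
    spec = DIALECTS[dialect]
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    for column in spec.mandatory_columns:
        if column not in frame.columns:
            raise SiteTableFormatError(
                f"{path}: missing mandatory column {column!r} "
                f"for dialect {dialect!r}"
            )

    sites: list[PhosphoSite] = []
    errors: list[ParseIssue] = []
    for idx, row in frame.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            accession = str(row[spec.accession_column]).strip()
            if not accession:
                raise ValueError("empty accession")
            if spec.site_column:
                residue, position = _split_site_string(
                    row[spec.site_column], spec.site_strip_suffixes
                )
            else:
                residue = str(row[spec.residue_column]).strip().upper()
                position = int(str(row[spec.position_column]).strip())
            species = (
                normalize_species(row[spec.species_column])
                if spec.species_column and spec.species_column in frame.columns
                else "other"
            )
            if spec.source_column and spec.source_column in frame.columns:
                raw = str(row[spec.source_column]).strip()
                sources = frozenset(
                    s.strip() for s in raw.split(",") if s.strip()
                ) or frozenset([spec.default_source])
            else:
                sources = frozenset([spec.default_source])
            if spec.evidence_column and spec.evidence_column in frame.columns:
                evidence = str(row[spec.evidence_column]).strip().lower() or spec.default_evidence
            else:
                evidence = spec.default_evidence
            sites.append(
                PhosphoSite(
                    accession=accession,
                    position=position,
                    residue=residue,
                    species=species,
                    sources=sources,
                    evidence=evidence,
                )
            )
        except (ValueError, PhosmapError) as exc:
            if strict:
                raise SiteTableFormatError(f"{path}:{line}: {exc}") from exc
            errors.append(ParseIssue(line=line, message=str(exc)))
            logger.warning("%s:%d: skipped row (%s)", path, line, exc)
    return SiteReadResult(sites, errors)


def write_site_table(table: SiteTable, path: str | Path) -> None:
    """Write a unified-dialect TSV, rows ordered by (accession, position).

    ``read_site_table(write_site_table(t), "unified")`` reproduces ``t``
    row for row.
    """
    frame = table.to_frame()
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

FEATURE_TABLE_HEADER_COMMENT = (
    "# phosmap feature table: 1-based INCLUSIVE coordinates "
    "(not 0-based half-open BED); cleavage_site rows denote the scissile "
    "bond between residues start (P1) and end (P1')."
)

_FEATURE_COLUMNS = ("accession", "kind", "start", "end", "label")


def read_feature_table(path: str | Path) -> list[SequenceFeature]:
    """Read a BED-like TSV of features with explicit 1-based coordinates.

    Columns: accession, kind, start, end, label, and optionally agent and
    note.  Invariants are enforced on every row: a cleavage_site must span
    exactly one bond (end = start + 1) and intervals must satisfy
    1 <= start <= end.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    for column in _FEATURE_COLUMNS:
        if column not in frame.columns:
            raise FeatureTableError(f"{path}: missing mandatory column {column!r}")
    features = []
    for idx, row in frame.iterrows():
        try:
            start = int(row["start"])
            end = int(row["end"])
        except ValueError as exc:
            raise FeatureTableError(f"{path}: row {int(idx) + 2}: {exc}") from exc
        features.append(
            SequenceFeature(
                accession=row["accession"].strip(),
                kind=row["kind"].strip(),
                start=start,
                end=end,
                label=row["label"].strip(),
                agent=row.get("agent", "").strip() or None if "agent" in frame.columns else None,
                note=row.get("note", "").strip() or None if "note" in frame.columns else None,
            )
        )
    return features


def write_feature_table(features: Sequence[SequenceFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(FEATURE_TABLE_HEADER_COMMENT + "\n")
        fh.write("accession\tkind\tstart\tend\tlabel\tagent\tnote\n")
        for f in sorted(features, key=lambda f: (f.accession, f.start, f.label)):
            fh.write(
                f"{f.accession}\t{f.kind}\t{f.start}\t{f.end}\t{f.label}\t"
                f"{f.agent or ''}\t{f.note or ''}\n"
            )


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


def read_alignment(path: str | Path) -> MultipleSeqAlignment:
    """Read an aligned FASTA; ragged rows raise :class:`AlignmentError`."""
    try:
        alignment = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise AlignmentError(f"{path}: {exc}") from exc
    return alignment
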