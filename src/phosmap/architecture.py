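"""Domain architectures and per-domain phosphosite tallies.

The collagen family has 28 types (44 α-chains) falling into structural
classes — fibrillar, FACIT (fibril-associated with interrupted triple
helices), network-forming, short-chain, membrane-associated, multiplexin
— each with a characteristic block architecture (signal peptide,
propeptides, triple-helical and non-collagenous domains).  This module
loads a registry of such architectures, assigns each phosphosite to the
domain containing it, and computes class-level census statements such as
"every membrane-collagen chain carries at least one ectodomain site".

The packaged registry stores simplified block architectures (the level of
detail of schematic domain diagrams), not curation-grade boundaries; each
segment records a provenance note so curated coordinates can be
substituted.  MMP and BMP records use the same segment vocabulary with
finer names (propeptide, catalytic, hemopexin) carried in the note field
of ``other``-labelled segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .core_io import (
    DOMAIN_LABELS,
    PhosmapError,
    PhosphoSite,
    SequenceFeature,
    SiteTable,
)

COLLAGEN_CLASSES = (
    "fibrillar",
    "FACIT",
    "network",
    "membrane",
    "multiplexin",
    "short_chain",
    "other",
    "not_collagen",
)

#: Packaged registry of simplified block architectures.
DEFAULT_REGISTRY = "collagen_registry.tsv"


class RegistryError(PhosmapError):
    pass


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered, contiguous domain segments covering [1, length]."""

    accession: str
    name: str
    collagen_class: str
    family: str
    segments: tuple[SequenceFeature, ...]

    def __post_init__(self) -> None:
        if self.collagen_class not in COLLAGEN_CLASSES:
            raise RegistryError(
                f"{self.accession}: unknown collagen class {self.collagen_class!r}"
            )
        ordered = tuple(sorted(self.segments, key=lambda s: s.start))
        object.__setattr__(self, "segments", ordered)
        if not ordered:
            raise RegistryError(f"{self.accession}: architecture has no segments")
        if ordered[0].start != 1:
            raise RegistryError(
                f"{self.accession}: segments must start at residue 1, "
                f"got {ordered[0].start}"
            )
        previous_end = 0
        for segment in ordered:
            if segment.label not in DOMAIN_LABELS:
                raise RegistryError(
                    f"{self.accession}: unknown domain label {segment.label!r}"
                )
            if segment.start <= previous_end:
                raise RegistryError(
                    f"{self.accession}: segments overlap at position {segment.start}"
                )
            if segment.start != previous_end + 1:
                raise RegistryError(
                    f"{self.accession}: gap between positions "
                    f"{previous_end} and {segment.start}"
                )
            previous_end = segment.end

    @property
    def length(self) -> int:
        return self.segments[-1].end


class Registry(dict):
    """Mapping accession -> :class:`DomainArchitecture` with census helpers."""

    @property
    def n_collagen_types(self) -> int:
        """Number of distinct collagen types (families) covered."""
        return len(
            {a.family for a in self.values() if a.collagen_class != "not_collagen"}
        )

    @property
    def family_map(self) -> dict[str, str]:
        return {acc: arch.family for acc, arch in self.items()}

    def chains_of_class(self, collagen_class: str) -> list[DomainArchitecture]:
        return sorted(
            (a for a in self.values() if a.collagen_class == collagen_class),
            key=lambda a: a.accession,
        )


def load_registry(path: str | Path | None = None) -> Registry:
    """Load a domain-architecture registry from TSV.

    Columns: accession, name, class, family, start, end, label, note.
    One row per segment; segments of one accession must be contiguous and
    non-overlapping from residue 1.  ``path=None`` loads the packaged
    registry covering the 28 collagen types plus MMP/BMP records.
    """
    if path is None:
        source = resources.files("phosmap.data").joinpath(DEFAULT_REGISTRY)
        with resources.as_file(source) as p:
            frame = pd.read_csv(p, sep="\t", dtype=str, comment="#")
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"accession", "name", "class", "family", "start", "end", "label"}
    missing = required - set(frame.columns)
    if missing:
        raise RegistryError(f"registry missing columns: {sorted(missing)}")
    registry = Registry()
    for accession, group in frame.groupby("accession", sort=True):
        first = group.iloc[0]
        segments = tuple(
            SequenceFeature(
                accession=str(accession),
                kind="domain_segment",
                start=int(row["start"]),
                end=int(row["end"]),
                label=str(row["label"]),
                note=(str(row["note"]) if "note" in group.columns and pd.notna(row["note"]) else None),
            )
            for _, row in group.iterrows()
        )
        registry[str(accession)] = DomainArchitecture(
            accession=str(accession),
            name=str(first["name"]),
            collagen_class=str(first["class"]),
            family=str(first["family"]),
            segments=segments,
        )
    return registry


def assign_segment(
    position: int, arch: DomainArchitecture
) -> SequenceFeature:
    """The unique segment containing a 1-based position."""
    if not 1 <= position <= arch.length:
        raise PhosmapError(
            f"position {position} outside [1, {arch.length}] for {arch.accession}"
        )
    for segment in arch.segments:
        if segment.start <= position <= segment.end:
            return segment
    raise RegistryError(
        f"{arch.accession}: no segment covers position {position}"
    )  # unreachable for a valid architecture


def assign_domain(site: PhosphoSite | int, arch: DomainArchitecture) -> str:
    """Domain label of the segment containing a site (or raw position)."""
    position = site if isinstance(site, int) else site.position
    return assign_segment(position, arch).label


@dataclass(frozen=True)
class ClassSummary:
    collagen_class: str
    n_chains: int
    n_chains_with_sites: int
    chains_without_sites: tuple[str, ...]
    sites_per_domain: Mapping[str, int]
    #: census predicates: domain label -> "every chain of this class has
    #: at least one site in that domain"
    predicates: Mapping[str, bool]

    def to_dict(self) -> dict:
        return {
            "class": self.collagen_class,
            "n_chains": self.n_chains,
            "n_chains_with_sites": self.n_chains_with_sites,
            "chains_without_sites": list(self.chains_without_sites),
            "sites_per_domain": dict(self.sites_per_domain),
            "predicates": dict(self.predicates),
        }


def class_summary(
    registry: Registry, table: SiteTable
) -> dict[str, ClassSummary]:
    """Per-class tallies and census predicates.

    ``sites_per_domain`` sums site counts over the chains of the class;
    the sum over domains equals the class's total retained sites.  The
    predicate for domain D is true iff *every* chain of the class has at
    least one site in a D-labelled segment (false on an empty table).
    """
    summaries: dict[str, ClassSummary] = {}
    classes = sorted({a.collagen_class for a in registry.values()})
    for collagen_class in classes:
        chains = registry.chains_of_class(collagen_class)
        domain_labels = sorted({s.label for a in chains for s in a.segments})
        sites_per_domain: dict[str, int] = {label: 0 for label in domain_labels}
        per_chain_domains: dict[str, set[str]] = {a.accession: set() for a in chains}
        chains_with_sites: set[str] = set()
        for arch in chains:
            for site in table.for_accession(arch.accession):
                label = assign_domain(site, arch)
                sites_per_domain[label] += 1
                per_chain_domains[arch.accession].add(label)
                chains_with_sites.add(arch.accession)
        predicates = {
            label: bool(chains)
            and all(label in per_chain_domains[a.accession] for a in chains)
            for label in domain_labels
        }
        summaries[collagen_class] = ClassSummary(
            collagen_class=collagen_class,
            n_chains=len(chains),
            n_chains_with_sites=len(chains_with_sites),
            chains_without_sites=tuple(
                sorted(a.accession for a in chains if a.accession not in chains_with_sites)
            ),
            sites_per_domain=sites_per_domain,
            predicates=predicates,
        )
    return summaries
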