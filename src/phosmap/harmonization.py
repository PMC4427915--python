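"""Merge phosphosites from multiple database exports into one validated table.

Public phosphosite resources report overlapping but inconsistent site
lists.  This module (a) validates every claimed site against the protein
sequence — the claimed residue letter must match the sequence at the
claimed 1-based position — and (b) merges per-source tables into a single
deduplicated table keyed on (accession, position, residue), with the set
of reporting databases kept as provenance.

Only experimentally verified sites survive validation by default;
predicted sites are dropped (and tallied) unless explicitly retained for
exploratory runs.  Orthologous sites are never merged across species:
human and mouse orthologs carry different accessions and stay distinct
rows, mirroring the species colour-coding of published site maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

from .core_io import PhosmapError, PhosphoSite, ProteinRecord, SiteTable


class ValidationError(PhosmapError):
    pass


@dataclass
class ValidationReport:
    """Exact partition of the input sites by validation outcome.

    Invariant: ``n_input == n_retained + n_residue_mismatch +
    n_out_of_range + n_predicted_dropped``.
    """

    n_input: int = 0
    n_retained: int = 0
    n_residue_mismatch: int = 0
    n_out_of_range: int = 0
    n_predicted_dropped: int = 0
    mismatches: list[tuple[str, int, str, str]] = field(default_factory=list)

    def check(self) -> None:
        total = (
            self.n_retained
            + self.n_residue_mismatch
            + self.n_out_of_range
            + self.n_predicted_dropped
        )
        if total != self.n_input:
            raise ValidationError(
                f"validation tallies do not partition the input: "
                f"{total} != {self.n_input}"
            )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_residue_mismatch": self.n_residue_mismatch,
            "n_out_of_range": self.n_out_of_range,
            "n_predicted_dropped": self.n_predicted_dropped,
            "mismatches": [list(m) for m in self.mismatches],
        }


def validate_sites(
    sites: Iterable[PhosphoSite],
    proteins: Sequence[ProteinRecord],
    keep_predicted: bool = False,
    strict: bool = False,
) -> tuple[SiteTable, ValidationReport]:
    """Validate claimed sites against protein sequences.

    A site is retained iff its evidence is verified (or ``keep_predicted``),
    its accession resolves to a protein, its position lies in [1, length],
    and the sequence residue at that position equals the claimed residue
    letter.  Failures are tallied, never raised, unless ``strict``:

    * unknown accession or out-of-range position -> ``n_out_of_range``
    * sequence/claim residue disagreement        -> ``n_residue_mismatch``
      (recorded as (accession, position, claimed, actual))
    * predicted evidence without ``keep_predicted`` -> ``n_predicted_dropped``
    """
    by_accession = {p.accession: p for p in proteins}
    report = ValidationReport()
    retained: list[PhosphoSite] = []
    for site in sites:
        report.n_input += 1
        if site.evidence == "predicted" and not keep_predicted:
            report.n_predicted_dropped += 1
            continue
        protein = by_accession.get(site.accession)
        if protein is None or not 1 <= site.position <= protein.length:
            report.n_out_of_range += 1
            if strict:
                raise ValidationError(
                    f"site {site.accession}:{site.residue}{site.position} "
                    "does not resolve to a sequence position"
                )
            continue
        actual = protein.residue_at(site.position)
        if actual != site.residue:
            report.n_residue_mismatch += 1
            report.mismatches.append(
                (site.accession, site.position, site.residue, actual)
            )
            if strict:
                raise ValidationError(
                    f"residue mismatch at {site.accession}:{site.position}: "
                    f"claimed {site.residue}, sequence has {actual}"
                )
            continue
        report.n_retained += 1
        retained.append(site)
    report.check()
    return SiteTable.from_sites(retained), report


class MergeResult(NamedTuple):
    table: SiteTable
    conflicts: list[tuple[str, int, frozenset[str]]]


def merge_sources(tables: Sequence[SiteTable]) -> MergeResult:
    """Union site tables from multiple databases into one.

    One output row per (accession, position, residue) with sources unioned
    over inputs.  Two claims at the same (accession, position) with
    *different* residue letters cannot both be right and the method gives
    no arbitration rule, so both are dropped and the conflict recorded as
    (accession, position, {letters}).

    The merge is idempotent and insensitive to the order of input tables.
    """
    all_sites = [site for table in tables for site in table]
    by_position: dict[tuple[str, int], set[str]] = {}
    for site in all_sites:
        by_position.setdefault((site.accession, site.position), set()).add(site.residue)
    conflicts = sorted(
        (acc, pos, frozenset(letters))
        for (acc, pos), letters in by_position.items()
        if len(letters) > 1
    )
    conflict_keys = {(acc, pos) for acc, pos, _ in conflicts}
    clean = [s for s in all_sites if (s.accession, s.position) not in conflict_keys]
    return MergeResult(SiteTable.from_sites(clean), conflicts)


@dataclass(frozen=True)
class FamilySummaryRow:
    family: str
    n_chains: int
    n_chains_with_sites: int
    chains_without_sites: tuple[str, ...]


def family_summary(
    proteins: Sequence[ProteinRecord],
    table: SiteTable,
    family_map: Mapping[str, str],
) -> list[FamilySummaryRow]:
    """Per-family phosphorylation census.

    For each family (e.g. a collagen type): how many chains it has, how
    many carry at least one retained site, and which chains carry none —
    the census behind statements like "all but three chains of the family
    are phosphorylated".
    """
    with_sites = {s.accession for s in table}
    families: dict[str, list[ProteinRecord]] = {}
    for protein in proteins:
        family = family_map.get(protein.accession)
        if family is None:
            continue
        families.setdefault(family, []).append(protein)
    rows = []
    for family in sorted(families):
        chains = families[family]
        zero = tuple(
            sorted(p.accession for p in chains if p.accession not in with_sites)
        )
        rows.append(
            FamilySummaryRow(
                family=family,
                n_chains=len(chains),
                n_chains_with_sites=len(chains) - len(zero),
                chains_without_sites=zero,
            )
        )
    return rows
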