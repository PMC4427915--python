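"""Project phosphosites and motif hits onto a multiple sequence alignment.

Computing the alignment is out of scope — an aligned FASTA is the input
(any standard aligner's output works).  The module builds a gap-aware
bijection between each row's 1-based residue positions and alignment
columns, then reports per-column co-occurrence: which sequences carry a
verified phosphosite in a column, which carry a motif hit starting there,
and whether the column falls in a marked region (e.g. the discontinuous
chain recognition sequence of fibrillar procollagen C-propeptides).

A column is called conserved-phospho when at least ``min_sequences``
aligned rows carry a verified site in it (default 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Align import MultipleSeqAlignment

from .core_io import (
    AlignmentError,
    ProteinRecord,
    SiteTable,
    _parse_fasta_header,
    read_alignment,
)
from .motif_scan import MotifHit

GAP_CHARACTERS = frozenset("-.")


@dataclass(frozen=True)
class AlignmentRegion:
    """A labelled alignment-column interval (1-based inclusive columns)."""

    label: str
    start_column: int
    end_column: int

    def __contains__(self, column: int) -> bool:
        return self.start_column <= column <= self.end_column


@dataclass
class AlignmentProjection:
    """Mutually inverse maps between residue positions and columns.

    ``column_map[accession][position]`` is the 1-based alignment column of
    the residue at 1-based ``position``; ``inverse_map`` inverts it on
    non-gap columns.
    """

    column_map: dict[str, dict[int, int]]
    inverse_map: dict[str, dict[int, int]]
    n_columns: int

    def accessions(self) -> list[str]:
        return sorted(self.column_map)


def build_projection(
    aligned: MultipleSeqAlignment | str | Path,
    sequences: Sequence[ProteinRecord] | None = None,
) -> AlignmentProjection:
    """Build position<->column maps from an aligned FASTA.

    If ``sequences`` is given, each row's degapped sequence must equal
    the corresponding :class:`ProteinRecord` sequence; a mismatch raises
    :class:`AlignmentError` naming the row.
    """
    if not isinstance(aligned, MultipleSeqAlignment):
        aligned = read_alignment(aligned)
    by_accession = {p.accession: p for p in sequences} if sequences else {}
    n_columns = aligned.get_alignment_length()
    column_map: dict[str, dict[int, int]] = {}
    inverse_map: dict[str, dict[int, int]] = {}
    for row in aligned:
        accession, _, _ = _parse_fasta_header(row.description)
        text = str(row.seq).upper()
        if len(text) != n_columns:
            raise AlignmentError(f"row {accession!r}: ragged alignment")
        forward: dict[int, int] = {}
        backward: dict[int, int] = {}
        position = 0
        for column0, ch in enumerate(text):
            if ch in GAP_CHARACTERS:
                continue
            position += 1
            forward[position] = column0 + 1
            backward[column0 + 1] = position
        degapped = "".join(ch for ch in text if ch not in GAP_CHARACTERS)
        if by_accession:
            record = by_accession.get(accession)
            if record is None:
                raise AlignmentError(
                    f"row {accession!r}: no matching sequence record"
                )
            if degapped != record.sequence:
                raise AlignmentError(
                    f"row {accession!r}: degapped row does not equal the "
                    "input sequence"
                )
        column_map[accession] = forward
        inverse_map[accession] = backward
    return AlignmentProjection(
        column_map=column_map, inverse_map=inverse_map, n_columns=n_columns
    )


@dataclass(frozen=True)
class ColumnReport:
    column: int
    site_accessions: tuple[str, ...]
    motif_accessions: tuple[str, ...]
    regions: tuple[str, ...]
    conserved_phospho: bool

    def to_dict(self) -> dict:
        return {
            "column": self.column,
            "site_accessions": list(self.site_accessions),
            "motif_accessions": list(self.motif_accessions),
            "regions": list(self.regions),
            "conserved_phospho": self.conserved_phospho,
        }


def column_cooccurrence(
    projection: AlignmentProjection,
    table: SiteTable,
    hits: Iterable[MotifHit] = (),
    regions: Sequence[AlignmentRegion] = (),
    min_sequences: int = 2,
) -> list[ColumnReport]:
    """Per-column co-occurrence of verified sites and motif starts.

    ``table`` may contain sites for all aligned accessions; positions not
    covered by an aligned row are ignored.  A motif hit is projected via
    its start position.  Returns one report per alignment column.
    """
    site_columns: dict[int, set[str]] = {}
    for site in table:
        forward = projection.column_map.get(site.accession)
        if forward is None or site.evidence != "verified":
            continue
        column = forward.get(site.position)
        if column is not None:
            site_columns.setdefault(column, set()).add(site.accession)
    motif_columns: dict[int, set[str]] = {}
    for hit in hits:
        forward = projection.column_map.get(hit.accession)
        if forward is None:
            continue
        column = forward.get(hit.start)
        if column is not None:
            motif_columns.setdefault(column, set()).add(hit.accession)
    reports = []
    for column in range(1, projection.n_columns + 1):
        with_sites = tuple(sorted(site_columns.get(column, ())))
        with_motifs = tuple(sorted(motif_columns.get(column, ())))
        labels = tuple(r.label for r in regions if column in r)
        reports.append(
            ColumnReport(
                column=column,
                site_accessions=with_sites,
                motif_accessions=with_motifs,
                regions=labels,
                conserved_phospho=len(with_sites) >= min_sequences,
            )
        )
    return reports


def read_region_table(path: str | Path) -> list[AlignmentRegion]:
    """Read labelled column intervals from a sidecar TSV.

    Columns: label, start_column, end_column (1-based inclusive).
    """
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"label", "start_column", "end_column"}
    missing = required - set(frame.columns)
    if missing:
        raise AlignmentError(f"region table missing columns: {sorted(missing)}")
    return [
        AlignmentRegion(
            label=str(row["label"]),
            start_column=int(row["start_column"]),
            end_column=int(row["end_column"]),
        )
        for _, row in frame.iterrows()
    ]
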