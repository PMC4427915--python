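"""Signed residue offsets between phosphosites and sequence features.

A phosphosite next to a proteolytic cleavage site can promote or hinder
enzyme binding, so the residue distance between a site and the scissile
bond is the central quantity here.  The offset convention:

* the k-th residue *after* the bond (i.e. after P1, starting at P1') has
  offset +k: ``offset = position - P1``;
* the k-th residue *before* the bond (starting at P1) has offset -k:
  ``offset = position - P1'``;
* there is no offset 0 — the bond sits between residues.

This is the only convention simultaneously consistent with two enzymes
cutting the same region at bonds a fixed number of residues apart: if
bond B lies d residues C-terminal of bond A, every site downstream of
both has ``offset_A - offset_B == d`` exactly.

For interval features (binding regions, motif intervals) the relation is
``within`` (distance 0), ``downstream`` (residues past the interval end)
or ``upstream`` (residues before the interval start).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .core_io import PhosmapError, PhosphoSite, SequenceFeature, SiteTable

#: Default proximity window in residues: the extent of the PCPE-1 binding
#: region downstream of the BMP1 cleavage site on fibrillar procollagens.
DEFAULT_WINDOW = 35


class ProximityError(PhosmapError):
    pass


@dataclass(frozen=True)
class ProximityAnnotation:
    """Signed residue offset of one site relative to one feature."""

    site: PhosphoSite
    feature: SequenceFeature
    offset: int
    relation: str  # upstream | downstream | within
    within_window: bool

    @property
    def distance(self) -> int:
        return abs(self.offset)


def signed_offset(
    position: int,
    cleavage: SequenceFeature,
    protein_length: int | None = None,
) -> int:
    """Signed residue offset of a position from a scissile bond.

    +k for the k-th residue downstream of the bond, -k for the k-th
    residue upstream; never 0.
    """
    if cleavage.kind != "cleavage_site":
        raise ProximityError(
            f"signed_offset requires a cleavage_site, got {cleavage.kind!r}"
        )
    if position < 1 or (protein_length is not None and position > protein_length):
        raise ProximityError(
            f"position {position} outside the protein for {cleavage.accession}"
        )
    if position > cleavage.p1:
        return position - cleavage.p1
    return position - cleavage.p1_prime


def interval_offset(
    position: int, interval: SequenceFeature
) -> tuple[str, int]:
    """Relation and unsigned residue distance of a position to an interval.

    within -> 0; downstream -> residues past the interval end; upstream ->
    residues before the interval start.
    """
    if interval.kind == "cleavage_site":
        raise ProximityError("interval_offset does not accept cleavage sites")
    if interval.start <= position <= interval.end:
        return ("within", 0)
    if position > interval.end:
        return ("downstream", position - interval.end)
    return ("upstream", interval.start - position)


def annotate_proximity(
    table: SiteTable,
    features: Sequence[SequenceFeature],
    window: int = DEFAULT_WINDOW,
) -> list[ProximityAnnotation]:
    """Annotate every (site, feature) pair sharing an accession.

    Sites and features on different accessions never pair, even for
    chains of the same trimer.  ``within_window`` is true iff the
    unsigned offset (cleavage bonds) or distance (intervals) is at most
    ``window`` residues.  Output is sorted by accession, feature label,
    then offset.
    """
    annotations: list[ProximityAnnotation] = []
    for site in table:
        for feature in features:
            if feature.accession != site.accession:
                continue
            if feature.kind == "cleavage_site":
                offset = signed_offset(site.position, feature)
                relation = "downstream" if offset > 0 else "upstream"
                within = abs(offset) <= window
            else:
                relation, distance = interval_offset(site.position, feature)
                offset = {
                    "within": 0,
                    "downstream": distance,
                    "upstream": -distance,
                }[relation]
                within = distance <= window
            annotations.append(
                ProximityAnnotation(
                    site=site,
                    feature=feature,
                    offset=offset,
                    relation=relation,
                    within_window=within,
                )
            )
    annotations.sort(
        key=lambda a: (a.site.accession, a.feature.label, a.offset, a.site.position)
    )
    return annotations


def dual_enzyme_consistency(
    table: SiteTable,
    bond_a: SequenceFeature,
    bond_b: SequenceFeature,
) -> int:
    """Constant offset difference between two bonds cutting the same region.

    For every site downstream of both bonds, ``offset_a - offset_b`` must
    equal the bond separation ``P1_b - P1_a``; the constant is returned.
    A violation means the two features are not on a shared coordinate
    system and raises :class:`ProximityError`.
    """
    for bond in (bond_a, bond_b):
        if bond.kind != "cleavage_site":
            raise ProximityError("dual_enzyme_consistency requires cleavage bonds")
    expected = bond_b.p1 - bond_a.p1
    for site in table:
        if site.accession != bond_a.accession:
            continue
        offset_a = signed_offset(site.position, bond_a)
        offset_b = signed_offset(site.position, bond_b)
        if offset_a > 0 and offset_b > 0 and offset_a - offset_b != expected:
            raise ProximityError(
                f"inconsistent offsets at {site.accession}:{site.position}: "
                f"{offset_a} - {offset_b} != {expected}"
            )
    return expected
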