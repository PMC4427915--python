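"""Textual/JSON site-map rendering (lollipop-style per-protein maps)."""

from __future__ import annotations

from typing import Iterable, Sequence

from .architecture import DomainArchitecture, assign_domain
from .core_io import ProteinRecord, SiteTable
from .motif_scan import MotifHit

#: Species -> display colour, following the convention of published
#: phosphosite maps: red (human), blue (mouse), black (rat); gray otherwise.
SPECIES_COLORS = {"human": "red", "mouse": "blue", "rat": "black", "other": "gray"}


def render_map(
    protein: ProteinRecord,
    arch: DomainArchitecture | None,
    table: SiteTable,
    hits: Sequence[MotifHit] = (),
) -> dict:
    """A JSON-able lollipop map: domain segments, site ticks, motif glyphs.

    Ordering is deterministic: segments by start, sites by position, hits
    by (start, pattern).  Sites are coloured by species; starred hits
    (motifs known to be phosphorylated) carry ``starred: true``.
    """
    segments = []
    if arch is not None:
        segments = [
            {
                "start": s.start,
                "end": s.end,
                "label": s.label,
                "note": s.note,
            }
            for s in arch.segments
        ]
    sites = []
    for site in table.for_accession(protein.accession):
        entry = {
            "position": site.position,
            "residue": site.residue,
            "species": site.species,
            "color": SPECIES_COLORS.get(site.species, "gray"),
            "sources": sorted(site.sources),
            "evidence": site.evidence,
        }
        if arch is not None:
            entry["domain"] = assign_domain(site, arch)
        sites.append(entry)
    glyphs = [
        {
            "pattern": h.pattern_id,
            "start": h.start,
            "end": h.end,
            "matched": h.matched,
            "primed": h.primed,
            "starred": h.starred,
        }
        for h in sorted(
            (h for h in hits if h.accession == protein.accession),
            key=lambda h: (h.start, h.pattern_id),
        )
    ]
    return {
        "accession": protein.accession,
        "name": protein.name,
        "species": protein.species,
        "length": protein.length,
        "segments": segments,
        "sites": sites,
        "motif_hits": glyphs,
    }
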