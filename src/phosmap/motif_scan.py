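"""Kinase recognition-motif scanning.

The secreted kinase FAM20C phosphorylates serines in the S-x-E motif
(serine, any residue, glutamate).  A second, "primed" variant, S-x-pS,
replaces the glutamate with a serine that must itself already carry a
verified phosphosite — so whether a window matches depends on the site
table, not just on the sequence.  The same scanner also handles literal
binding motifs with alternatives, such as the integrin-binding tripeptide
RGD or the heparin/heparan-sulfate motif KGHRG(F/Y).

Conventions:

* "x" matches any single standard residue, including S and E.
* X (unknown residue) matches nothing — not even "x" — so unknown
  residues can never create hits.
* All matching windows are reported, overlaps included.
* Coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .core_io import AMINO_ACIDS, PhosmapError, ProteinRecord, SiteTable

#: Residue set meaning "any standard residue" (X excluded by construction).
ANY = AMINO_ACIDS


class PatternError(PhosmapError):
    pass


@dataclass(frozen=True)
class MotifPattern:
    """An ordered list of residue sets, with optional priming requirements.

    ``primed_positions`` holds 0-based element indices at which the matched
    residue must be S or T *and* carry a verified phosphosite at its
    absolute sequence position.
    """

    pattern_id: str
    elements: tuple[frozenset[str], ...]
    primed_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not self.elements:
            raise PatternError(f"pattern {self.pattern_id!r} has no elements")
        for element in self.elements:
            if not element or not element <= AMINO_ACIDS:
                raise PatternError(
                    f"pattern {self.pattern_id!r}: residue sets must be "
                    "non-empty subsets of the 20 standard letters"
                )
        for idx in self.primed_positions:
            if not 0 <= idx < len(self.elements):
                raise PatternError(
                    f"pattern {self.pattern_id!r}: primed index {idx} out of range"
                )

    def __len__(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class MotifHit:
    """One match of a pattern on a protein, 1-based inclusive coordinates."""

    accession: str
    pattern_id: str
    start: int
    end: int
    matched: str
    primed: bool = False
    priming_site: int | None = None
    starred: bool = False


def parse_pattern(text: str, pattern_id: str | None = None) -> MotifPattern:
    """Parse dash syntax like ``"S-x-E"``, ``"S-x-Sp"`` or ``"S-x-(E/D)"``.

    Tokens: a single residue letter; ``x`` for any residue; ``(A/B)`` for
    alternatives; a letter followed by ``p`` (e.g. ``Sp``) for a residue
    that must carry a verified phosphosite (priming).
    """
    tokens = [t.strip() for t in text.split("-")]
    if not all(tokens):
        raise PatternError(f"cannot parse pattern {text!r}")
    elements: list[frozenset[str]] = []
    primed: set[int] = set()
    for i, token in enumerate(tokens):
        if token.lower() == "x":
            elements.append(ANY)
        elif token.startswith("(") and token.endswith(")"):
            letters = frozenset(p.strip().upper() for p in token[1:-1].split("/"))
            elements.append(letters)
        elif len(token) == 2 and token[1] == "p":
            elements.append(frozenset(token[0].upper()))
            primed.add(i)
        elif len(token) == 1:
            elements.append(frozenset(token.upper()))
        else:
            raise PatternError(f"cannot parse pattern token {token!r} in {text!r}")
    return MotifPattern(
        pattern_id=pattern_id or text,
        elements=tuple(elements),
        primed_positions=frozenset(primed),
    )


def parse_literal(literal: str, pattern_id: str | None = None) -> MotifPattern:
    """Parse a literal motif with alternatives, e.g. ``"KGHRG(F/Y)"``."""
    elements: list[frozenset[str]] = []
    i = 0
    while i < len(literal):
        ch = literal[i]
        if ch == "(":
            close = literal.find(")", i)
            if close < 0:
                raise PatternError(f"unbalanced parenthesis in {literal!r}")
            letters = frozenset(
                p.strip().upper() for p in literal[i + 1 : close].split("/")
            )
            elements.append(letters)
            i = close + 1
        else:
            elements.append(frozenset(ch.upper()))
            i += 1
    if not elements:
        raise PatternError("empty literal motif")
    return MotifPattern(pattern_id=pattern_id or literal, elements=tuple(elements))


def scan(
    protein: ProteinRecord,
    pattern: MotifPattern,
    sites: SiteTable | None = None,
) -> list[MotifHit]:
    """Report every window of the sequence matching the pattern.

    Overlapping matches are all reported, sorted by start.  For patterns
    with priming requirements, a window matches only if the residue at
    each primed index is S or T and carries a verified phosphosite at its
    absolute 1-based position in ``sites``.  A pattern longer than the
    sequence yields an empty list.
    """
    seq = protein.sequence
    width = len(pattern)
    verified = (
        sites.verified_positions(protein.accession)
        if sites is not None
        else frozenset()
    )
    hits: list[MotifHit] = []
    for start0 in range(len(seq) - width + 1):
        window = seq[start0 : start0 + width]
        if any(window[i] not in pattern.elements[i] for i in range(width)):
            continue
        priming_site = None
        if pattern.primed_positions:
            primed_ok = True
            for idx in sorted(pattern.primed_positions):
                abs_pos = start0 + idx + 1
                if window[idx] not in ("S", "T") or abs_pos not in verified:
                    primed_ok = False
                    break
                if priming_site is None:
                    priming_site = abs_pos
            if not primed_ok:
                continue
        hits.append(
            MotifHit(
                accession=protein.accession,
                pattern_id=pattern.pattern_id,
                start=start0 + 1,
                end=start0 + width,
                matched=window,
                primed=bool(pattern.primed_positions),
                priming_site=priming_site,
            )
        )
    return hits


def scan_literal(protein: ProteinRecord, literal: str) -> list[MotifHit]:
    """Scan for a literal motif with alternatives, e.g. ``"RGD"``."""
    return scan(protein, parse_literal(literal))


def cross_reference_hits(
    hits: Iterable[MotifHit],
    sites: SiteTable,
    star_anywhere: bool = False,
) -> list[MotifHit]:
    """Flag hits whose motif is known to be phosphorylated.

    By default a hit is starred iff its *first* residue is S or T and
    carries a verified phosphosite at that position (the motif's
    phosphoacceptor); ``star_anywhere=True`` relaxes this to a verified
    S/T site anywhere inside the hit window.
    """
    annotated = []
    for hit in hits:
        verified = sites.verified_positions(hit.accession)
        if star_anywhere:
            starred = any(
                pos in verified and hit.matched[pos - hit.start] in ("S", "T")
                for pos in range(hit.start, hit.end + 1)
            )
        else:
            starred = hit.matched[0] in ("S", "T") and hit.start in verified
        annotated.append(replace(hit, starred=starred))
    return annotated
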