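"""Motif scanning: S-x-E / phospho-primed S-x-pS and literal motifs."""

import itertools
import random

import pytest

from phosmap.core_io import PhosphoSite, ProteinRecord, SiteTable
from phosmap.motif_scan import (
    ANY,
    MotifPattern,
    PatternError,
    cross_reference_hits,
    parse_literal,
    parse_pattern,
    scan,
    scan_literal,
)


def record(seq, acc="P1"):
    return ProteinRecord(accession=acc, sequence=seq)


def table_with(acc, *positions, residue="S"):
    return SiteTable.from_sites(
        PhosphoSite(acc, p, residue, "human", frozenset(["DB"]), "verified")
        for p in positions
    )


def naive_scan(seq, pattern, verified=frozenset()):
    """Brute-force all-windows oracle, independent of the scanner."""
    hits = []
    w = len(pattern.elements)
    for start in range(1, len(seq) - w + 2):
        window = seq[start - 1 : start - 1 + w]
        if all(window[i] in pattern.elements[i] for i in range(w)):
            if all(
                window[i] in "ST" and (start + i) in verified
                for i in pattern.primed_positions
            ):
                hits.append((start, start + w - 1, window))
    return hits


class TestParsing:
    def test_dash_syntax(self):
        p = parse_pattern("S-x-E")
        assert p.elements == (frozenset("S"), ANY, frozenset("E"))
        assert not p.primed_positions

    def test_primed_token(self):
        p = parse_pattern("S-x-Sp")
        assert p.elements[2] == frozenset("S")
        assert p.primed_positions == frozenset({2})

    def test_literal_with_alternatives(self):
        p = parse_literal("KGHRG(F/Y)")
        assert len(p) == 6
        assert p.elements[5] == frozenset("FY")

    @pytest.mark.parametrize("bad", ["", "S--E", "S-xx-E", "KGHRG(F/Y"])
    def test_malformed_patterns_rejected(self, bad):
        with pytest.raises(PatternError):
            (parse_literal if "(" in bad or "-" not in bad else parse_pattern)(bad)


class TestScan:
    def test_single_sxe_hit(self):
        (hit,) = scan(record("ASAEG"), parse_pattern("S-x-E"))
        assert (hit.start, hit.end, hit.matched) == (2, 4, "SAE")

    def test_all_windows_reported_overlaps_included(self):
        # SSEE matches S-x-E at both 1-3 and 2-4 (overlap by two residues)
        hits = scan(record("SSEE"), parse_pattern("S-x-E"))
        assert [(h.start, h.end) for h in hits] == [(1, 3), (2, 4)]

    def test_x_matches_s_and_e_themselves(self):
        hits = scan(record("SSESE"), parse_pattern("S-x-E"))
        assert [(h.start, h.end) for h in hits] == [(1, 3)]

    def test_unknown_residue_never_matches(self):
        assert scan(record("SXE"), parse_pattern("S-x-E")) == []

    def test_pattern_longer_than_sequence_is_empty_not_error(self):
        assert scan(record("SE"), parse_pattern("S-x-E")) == []

    def test_primed_hit_requires_verified_site_at_second_serine(self):
        # furin recognition context of BMP1: R-S-R-S-R-R
        seq = record("RSRSRR")
        pattern = parse_pattern("S-x-Sp")
        assert scan(seq, pattern, SiteTable()) == []
        (hit,) = scan(seq, pattern, table_with("P1", 4))
        assert (hit.start, hit.end, hit.matched) == (2, 4, "SRS")
        assert hit.primed and hit.priming_site == 4

    def test_threonine_does_not_prime_a_second_serine_slot(self):
        # the primed slot is {S}: a verified T at that position cannot match
        seq = record("STSTT")
        hits = scan(seq, parse_pattern("S-x-Sp"), table_with("P1", 4, residue="T"))
        assert hits == []

    def test_priming_is_monotone_in_the_site_table(self):
        seq = record("SASASAS")
        pattern = parse_pattern("S-x-Sp")
        small = table_with("P1", 3)
        large = table_with("P1", 3, 5, 7)
        hits_small = {(h.start, h.end) for h in scan(seq, pattern, small)}
        hits_large = {(h.start, h.end) for h in scan(seq, pattern, large)}
        assert hits_small <= hits_large


class TestScanLiteral:
    def test_heparin_motif_inside_pedf_binding_sequence(self):
        (hit,) = scan_literal(record("IKGHRGFSGL"), "KGHRG(F/Y)")
        assert (hit.start, hit.end, hit.matched) == (2, 7, "KGHRGF")

    def test_rgd_in_reported_context(self):
        (hit,) = scan_literal(record("SAVPGFRGD"), "RGD")
        assert (hit.start, hit.end) == (7, 9)

    def test_absent_motif_yields_empty(self):
        assert scan_literal(record("AAAA"), "RGD") == []

    @pytest.mark.parametrize("seed", range(10))
    def test_hit_count_equals_substring_count(self, seed):
        rng = random.Random(seed)
        seq = "".join(rng.choices("RGDA", k=60))
        hits = scan_literal(record(seq), "RGD")
        expected = sum(1 for i in range(len(seq) - 2) if seq[i : i + 3] == "RGD")
        assert len(hits) == expected


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(50))
    def test_scan_equals_naive_all_windows_checker(self, seed):
        rng = random.Random(seed)
        seq = "".join(rng.choices("ACDEFGHIKLMNPQRSTVWYX", k=rng.randrange(5, 200)))
        width = rng.randrange(1, 6)
        elements = tuple(
            ANY if rng.random() < 0.3
            else frozenset(rng.sample("ACDEFGHIKLMNPQRSTVWY", rng.randrange(1, 4)))
            for _ in range(width)
        )
        primed = frozenset(
            i for i in range(width) if rng.random() < 0.15
        )
        pattern = MotifPattern("rnd", elements, primed)
        verified = frozenset(rng.sample(range(1, len(seq) + 1), min(10, len(seq))))
        sites = SiteTable.from_sites(
            PhosphoSite("P1", p, seq[p - 1], "human", frozenset(["DB"]), "verified")
            for p in verified
            if seq[p - 1] in "STY"
        )
        got = [(h.start, h.end, h.matched) for h in scan(record(seq), pattern, sites)]
        want = naive_scan(seq, pattern, sites.verified_positions("P1"))
        assert got == want


class TestCrossReference:
    def test_star_requires_site_at_first_position(self):
        hits = scan(record("ASAEG"), parse_pattern("S-x-E"))
        starred = cross_reference_hits(hits, table_with("P1", 2))
        assert starred[0].starred
        not_starred = cross_reference_hits(hits, table_with("P1", 4))
        assert not not_starred[0].starred

    def test_empty_site_table_stars_nothing(self):
        hits = scan(record("SAESAE"), parse_pattern("S-x-E"))
        assert not any(h.starred for h in cross_reference_hits(hits, SiteTable()))

    def test_star_anywhere_option(self):
        seq = record("SSE")  # single hit at 1-3, internal serine at 2
        hits = scan(seq, parse_pattern("S-x-E"))
        by_default = cross_reference_hits(hits, table_with("P1", 2))
        assert not by_default[0].starred
        anywhere = cross_reference_hits(hits, table_with("P1", 2), star_anywhere=True)
        assert anywhere[0].starred
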