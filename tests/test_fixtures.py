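"""Synthetic-bundle generator and curated literature fixtures."""

import json

import pytest

from phosmap.core_io import SiteTable, read_fasta, read_feature_table, read_site_table
from phosmap.fixtures import FixtureError, generate_synthetic, paper_fixture
from phosmap.harmonization import merge_sources, validate_sites
from phosmap.motif_scan import parse_literal, parse_pattern, scan, scan_literal
from phosmap.proximity import signed_offset


class TestGenerateSynthetic:
    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        a = generate_synthetic(seed=7).write(tmp_path / "a")
        b = generate_synthetic(seed=7).write(tmp_path / "b")
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes()

    def test_different_seeds_differ(self):
        a = generate_synthetic(seed=1)
        b = generate_synthetic(seed=2)
        assert [p.sequence for p in a.proteins] != [p.sequence for p in b.proteins]

    def test_duplicate_count_matches_overlap_fraction(self):
        bundle = generate_synthetic(
            n_proteins=2, n_sites_per_protein=10, overlap_fraction=0.5, seed=11
        )
        assert bundle.truth["n_duplicates"] == 10  # 5 per protein

    def test_merge_recovers_exact_planted_count(self, synthetic):
        tables = [SiteTable.from_sites(v) for v in synthetic.source_tables.values()]
        merged, conflicts = merge_sources(tables)
        assert not conflicts
        assert len(merged) == synthetic.truth["n_sites"]

    def test_corruption_count_equals_validation_mismatch_tally(self):
        bundle = generate_synthetic(
            n_proteins=2, n_sites_per_protein=10, corruption_fraction=0.2, seed=5
        )
        assert bundle.truth["n_corrupted"] == 4
        merged, _ = merge_sources(
            [SiteTable.from_sites(v) for v in bundle.source_tables.values()]
        )
        _, report = validate_sites(merged, bundle.proteins)
        assert report.n_residue_mismatch == bundle.truth["n_corrupted"]

    def test_truth_record_lists_exactly_the_matches_present(self, synthetic):
        for protein in synthetic.proteins:
            for text in synthetic.truth["patterns"]:
                pattern = parse_pattern(text) if "-" in text else parse_literal(text)
                found = {
                    (h.start, h.end)
                    for h in scan(protein, pattern)
                }
                planted = {
                    (m["start"], m["end"])
                    for m in synthetic.truth["motifs"]
                    if m["accession"] == protein.accession
                    and m["pattern"] == pattern.pattern_id
                }
                assert found == planted

    def test_written_bundle_reads_back(self, synthetic_dir):
        proteins = read_fasta(synthetic_dir["fasta"])
        sites = read_site_table(synthetic_dir["sites_a"])
        features = read_feature_table(synthetic_dir["features"])
        truth = json.loads(synthetic_dir["truth"].read_text())
        assert len(proteins) == truth["n_proteins"]
        assert sites and features

    def test_infeasible_planting_errors(self):
        with pytest.raises(FixtureError):
            generate_synthetic(
                n_proteins=1,
                length_range=(30, 30),
                n_sites_per_protein=2,
                planted_motifs=(("S-x-E", 12),),
                seed=0,
            )


class TestFullPipelineRecovery:
    @pytest.mark.parametrize("seed", range(50))
    def test_planted_sites_motifs_and_adjacency_recovered_exactly(self, seed):
        bundle = generate_synthetic(
            n_proteins=3, n_sites_per_protein=6, seed=seed
        )
        tables = [SiteTable.from_sites(v) for v in bundle.source_tables.values()]
        merged, conflicts = merge_sources(tables)
        assert not conflicts
        table, report = validate_sites(merged, bundle.proteins)
        clean = {
            (s["accession"], s["position"], s["residue"])
            for s in bundle.truth["sites"]
            if not s["corrupted"]
        }
        assert {s.key for s in table} == clean
        assert report.n_residue_mismatch == bundle.truth["n_corrupted"]
        for protein in bundle.proteins:
            for text in bundle.truth["patterns"]:
                pattern = parse_pattern(text) if "-" in text else parse_literal(text)
                found = {(h.start, h.end) for h in scan(protein, pattern, table)}
                planted = {
                    (m["start"], m["end"])
                    for m in bundle.truth["motifs"]
                    if m["accession"] == protein.accession
                    and m["pattern"] == pattern.pattern_id
                }
                assert found == planted
        bonds = {
            (f.accession, f.label): f
            for f in bundle.features
            if f.kind == "cleavage_site"
        }
        for entry in bundle.truth["adjacency"]:
            bond = bonds[(entry["accession"], entry["label"])]
            offset = signed_offset(entry["position"], bond)
            assert offset == entry["offset"]
            assert (abs(offset) <= bundle.truth["window"]) == entry["within_window"]


class TestPaperFixture:
    def test_each_rgd_peptide_has_exactly_one_rgd(self, bundle):
        assert len(bundle.rgd_peptides) == 6
        for peptide in bundle.rgd_peptides:
            assert len(scan_literal(peptide, "RGD")) == 1

    def test_pedf_sites_validate_against_the_stub(self, bundle):
        pedf = bundle.protein("PEDF")
        sites = [s for s in bundle.sites if s.accession == "PEDF"]
        assert sorted(s.position for s in sites) == [24, 114, 227]
        table, report = validate_sites(sites, [pedf])
        assert report.n_retained == 3

    def test_mmp2_collagen_binding_domain_sites_validate(self, bundle):
        mmp2 = bundle.protein("MMP2")
        sites = [s for s in bundle.sites if s.accession == "MMP2"]
        table, report = validate_sites(sites, [mmp2])
        assert report.n_retained == 3
        assert sorted((s.residue, s.position) for s in table) == [
            ("S", 365), ("T", 250), ("Y", 271)
        ]

    def test_all_packaged_sites_validate_against_their_stubs(self, bundle):
        table, report = validate_sites(
            list(bundle.sites), bundle.proteins + bundle.peptides
        )
        assert report.n_retained == report.n_input
        assert report.mismatches == []

    def test_furin_context_primed_hit_toggles_with_site(self, bundle):
        bmp1 = bundle.protein("BMP1")
        pattern = parse_pattern("S-x-Sp")
        without = scan(bmp1, pattern, bundle.sites)
        assert without == []
        with_site = SiteTable.from_sites(list(bundle.sites) + [bundle.priming_site])
        (hit,) = scan(bmp1, pattern, with_site)
        assert (hit.start, hit.end) == (116, 118)
        assert hit.primed and hit.priming_site == 118
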