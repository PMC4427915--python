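"""Readers/writers: FASTA, site-table dialects, feature tables."""

import pytest

from phosmap.core_io import (
    FastaError,
    FeatureTableError,
    PhosphoSite,
    ProteinRecord,
    SequenceFeature,
    SiteTable,
    SiteTableFormatError,
    normalize_species,
    read_fasta,
    read_feature_table,
    read_site_table,
    write_site_table,
)


def make_site(acc="P1", pos=5, res="S", species="human", sources=("DB1",), evidence="verified"):
    return PhosphoSite(acc, pos, res, species, frozenset(sources), evidence)


class TestFasta:
    def test_header_parsed_into_identity_fields(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">P1|test|human\nASAEG\n")
        (rec,) = read_fasta(p)
        assert (rec.accession, rec.name, rec.species) == ("P1", "test", "human")
        assert rec.length == 5

    def test_lowercase_body_is_uppercased(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">P1|t|human\nasaeg\n")
        assert read_fasta(p)[0].sequence == "ASAEG"

    def test_plain_header_falls_back_to_accession_only(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">justanid\nAAAA\n")
        (rec,) = read_fasta(p)
        assert rec.accession == "justanid" and rec.species == "other"

    def test_invalid_residue_names_record_and_position(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">P9|t|human\nASBEG\n")
        with pytest.raises(FastaError, match=r"P9.*position 3"):
            read_fasta(p)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(FastaError):
            read_fasta(p)


@pytest.mark.parametrize(
    "raw,expected",
    [("Homo sapiens", "human"), ("mouse", "mouse"), ("Rattus norvegicus", "rat"),
     ("zebrafish", "other"), (None, "other")],
)
def test_species_normalization(raw, expected):
    assert normalize_species(raw) == expected


class TestSiteTableIO:
    def test_unified_row_becomes_one_site(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "accession\tposition\tresidue\tspecies\tsource\tevidence\n"
            "P1\t544\tS\thuman\tPhosphoSitePlus\tverified\n"
        )
        (site,) = read_site_table(p)
        assert site.position == 544 and site.residue == "S"
        assert site.sources == frozenset({"PhosphoSitePlus"})

    def test_combined_site_string_is_split(self, tmp_path):
        # a site written "T1148" carries both residue and position
        p = tmp_path / "s.tsv"
        p.write_text("Accession\tSpecies\tSite\nCOL1A2\tHomo sapiens\tT1148\n")
        (site,) = read_site_table(p, dialect="uniprot_like")
        assert (site.residue, site.position, site.species) == ("T", 1148, "human")
        assert site.sources == frozenset({"UniProt"})

    def test_phosphositeplus_dialect_strips_mod_suffix(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("ACC_ID\tORGANISM\tMOD_RSD\nP1\thuman\tS544-p\n")
        (site,) = read_site_table(p, dialect="phosphositeplus_like")
        assert (site.residue, site.position) == ("S", 544)
        assert site.sources == frozenset({"PhosphoSitePlus"})

    def test_malformed_rows_are_skipped_and_counted(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "accession\tposition\tresidue\tspecies\tsource\tevidence\n"
            "P1\t10\tS\thuman\tDB\tverified\n"
            "P1\txx\tS\thuman\tDB\tverified\n"
            "P1\t20\tB\thuman\tDB\tverified\n"
            "P1\t30\tT\thuman\tDB\tverified\n"
        )
        result = read_site_table(p)
        assert len(result) == 2
        assert len(result.errors) == 2

    def test_strict_upgrades_bad_row_to_error(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "accession\tposition\tresidue\tspecies\tsource\tevidence\n"
            "P1\txx\tS\thuman\tDB\tverified\n"
        )
        with pytest.raises(SiteTableFormatError):
            read_site_table(p, strict=True)

    def test_missing_mandatory_column_names_it(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("accession\tresidue\nP1\tS\n")
        with pytest.raises(SiteTableFormatError, match="position"):
            read_site_table(p)

    def test_empty_table_round_trips_as_header_only(self, tmp_path):
        p = tmp_path / "out.tsv"
        write_site_table(SiteTable(), p)
        assert p.read_text().strip() == "accession\tposition\tresidue\tspecies\tsource\tevidence"
        assert list(read_site_table(p)) == []

    def test_rows_written_in_accession_position_order(self, tmp_path):
        table = SiteTable([make_site("B", 5), make_site("A", 9), make_site("A", 2)])
        p = tmp_path / "out.tsv"
        write_site_table(table, p)
        lines = p.read_text().strip().splitlines()[1:]
        assert [l.split("\t")[:2] for l in lines] == [["A", "2"], ["A", "9"], ["B", "5"]]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_reproduces_table(self, tmp_path, seed):
        import random

        rng = random.Random(seed)
        sites = [
            make_site(
                acc=f"P{rng.randrange(3)}",
                pos=rng.randrange(1, 500),
                res=rng.choice("STY"),
                species=rng.choice(["human", "mouse", "rat", "other"]),
                sources=tuple(rng.sample(["DB1", "DB2", "DB3"], rng.randrange(1, 3))),
                evidence=rng.choice(["verified", "predicted"]),
            )
            for _ in range(30)
        ]
        table = SiteTable.from_sites(sites)
        p = tmp_path / "rt.tsv"
        write_site_table(table, p)
        assert SiteTable.from_sites(read_site_table(p)) == table


class TestSiteTable:
    def test_duplicate_keys_rejected_by_plain_constructor(self):
        with pytest.raises(Exception):
            SiteTable([make_site(), make_site(sources=("DB2",))])

    def test_from_sites_unions_provenance(self):
        t = SiteTable.from_sites([make_site(), make_site(sources=("DB2",))])
        assert len(t) == 1
        assert t.provenance_index[("P1", 5, "S")] == frozenset({"DB1", "DB2"})

    def test_provenance_index_keys_cover_rows_exactly(self):
        t = SiteTable.from_sites([make_site(), make_site(pos=9)])
        assert set(t.provenance_index) == {s.key for s in t}

    def test_position_one_is_a_valid_site(self):
        # sentinel against any 0-based interpretation creeping in
        rec = ProteinRecord(accession="P1", sequence="SAAAA")
        site = make_site(pos=1)
        assert rec.residue_at(site.position) == "S"


class TestFeatureTable:
    def test_cleavage_row_denotes_scissile_bond(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text(
            "accession\tkind\tstart\tend\tlabel\nP1\tcleavage_site\t100\t101\tBMP1\n"
        )
        (f,) = read_feature_table(p)
        assert (f.p1, f.p1_prime) == (100, 101)

    def test_interval_row_has_inclusive_coordinates(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text(
            "accession\tkind\tstart\tend\tlabel\nP1\tmotif_interval\t45\t47\tRGD\n"
        )
        (f,) = read_feature_table(p)
        assert f.end - f.start + 1 == 3

    def test_wide_cleavage_site_rejected(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text(
            "accession\tkind\tstart\tend\tlabel\nP1\tcleavage_site\t100\t105\tBMP1\n"
        )
        with pytest.raises(FeatureTableError):
            read_feature_table(p)

    def test_inverted_interval_rejected(self):
        with pytest.raises(FeatureTableError):
            SequenceFeature("P1", "binding_region", 50, 40, "oops")

    def test_unknown_kind_rejected(self):
        with pytest.raises(FeatureTableError):
            SequenceFeature("P1", "exon", 1, 10, "x")
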