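"""Domain types, file readers/writers and packaged fixture integrity."""

import numpy as np
import pytest

from nappan.core_model import (NAP_FAMILIES, DomainHit, GeneFeature,
                               InvariantError, ParseError, Replicon,
                               Thresholds, load_fixture, read_bedgraph,
                               read_domain_hits, read_gene_table,
                               write_bedgraph, write_domain_hits,
                               write_gene_table)


class TestGeneTable:
    def test_gff3_cds_maps_to_feature(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text("##gff-version 3\n"
                       "chr1\tsrc\tCDS\t100\t400\t.\t+\t0\tID=geneA;product=HU\n")
        feats = read_gene_table(gff, format="gff3")
        assert len(feats) == 1
        g = feats[0]
        assert (g.gene_id, g.start, g.end, g.strand, g.product) == ("geneA", 100, 400, "+", "HU")

    def test_empty_file_gives_empty_list(self, tmp_path):
        gff = tmp_path / "empty.gff3"
        gff.write_text("")
        assert read_gene_table(gff, format="gff3") == []

    def test_inverted_coordinates_raise_with_line_number(self, tmp_path):
        gff = tmp_path / "bad.gff3"
        gff.write_text("chr1\tsrc\tCDS\t500\t200\t.\t+\t0\tID=bad\n")
        with pytest.raises(InvariantError, match=":1"):
            read_gene_table(gff, format="gff3")

    def test_malformed_line_names_line_number(self, tmp_path):
        gff = tmp_path / "bad.gff3"
        gff.write_text("chr1\tsrc\tCDS\t100\t400\t.\t+\t0\tID=a\nchr1\tonly-two\n")
        with pytest.raises(ParseError, match=":2"):
            read_gene_table(gff, format="gff3")

    def test_features_sorted_by_replicon_and_start(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text("chr2\tsrc\tCDS\t10\t20\t.\t+\t0\tID=c\n"
                       "chr1\tsrc\tCDS\t500\t900\t.\t-\t0\tID=b\n"
                       "chr1\tsrc\tCDS\t5\t50\t.\t+\t0\tID=a\n")
        feats = read_gene_table(gff, format="gff3")
        assert [f.gene_id for f in feats] == ["a", "b", "c"]

    def test_tsv_round_trip(self, tmp_path):
        feats = [GeneFeature("g1", "chr", 5, 900, "-", "HU protein", "K04764", "MKKA"),
                 GeneFeature("g2", "chr", 2000, 2600, "+", "", None, None)]
        path = tmp_path / "genes.tsv"
        write_gene_table(feats, path)
        assert read_gene_table(path, format="tsv") == feats


class TestDomainHits:
    def test_basic_row_parses(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("protein_id\tprofile_id\tevalue\tprobability\tcoverage\n"
                     "p1\tHU\t1e-20\t99.0\t0.95\n")
        hits = read_domain_hits(p)
        assert hits == [DomainHit("p1", "HU", 1e-20, 99.0, 0.95)]

    def test_empty_probability_parses_as_absent(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("protein_id\tprofile_id\tevalue\tprobability\tcoverage\n"
                     "p1\tFis\t1e-8\t\t\n")
        (hit,) = read_domain_hits(p)
        assert hit.probability is None and hit.coverage is None

    def test_negative_evalue_rejected(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("protein_id\tprofile_id\tevalue\tprobability\tcoverage\n"
                     "p2\tFis\t-1\t\t\n")
        with pytest.raises(InvariantError):
            read_domain_hits(p)

    def test_unknown_column_warns_and_is_ignored(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("protein_id\tprofile_id\tevalue\tbitscore\n" "p1\tHU\t1e-20\t55\n")
        with pytest.warns(UserWarning, match="bitscore"):
            hits = read_domain_hits(p)
        assert hits[0].evalue == 1e-20

    def test_round_trip(self, tmp_path):
        hits = [DomainHit("p1", "HU", 1.5e-21, 99.5, 0.91),
                DomainHit("p2", "Fis", 1e-9, None, None)]
        path = tmp_path / "hits.tsv"
        write_domain_hits(hits, path)
        assert read_domain_hits(path) == hits


class TestBedgraph:
    def test_round_trip_and_zero_based_conversion(self, tmp_path):
        depth = np.array([0.0, 0.0, 5.0, 5.0, 5.0, 2.0], dtype=float)
        path = tmp_path / "cov.bedgraph"
        write_bedgraph({"chr": depth}, path)
        text = path.read_text()
        assert "chr\t2\t5\t5\n" in text  # 0-based half-open on disk
        back = read_bedgraph(path)
        np.testing.assert_array_equal(back["chr"], depth)


class TestInvariants:
    @pytest.mark.parametrize("kwargs", [
        dict(replicon_id="r", length_bp=0),
        dict(replicon_id="r", length_bp=100, ori_pos=101),
        dict(replicon_id="r", length_bp=100, topology="weird"),
    ])
    def test_replicon_invariants(self, kwargs):
        with pytest.raises(InvariantError):
            Replicon(**kwargs)

    def test_threshold_bounds(self):
        with pytest.raises(InvariantError):
            Thresholds(core_occupancy=1.5)
        with pytest.raises(InvariantError):
            Thresholds(vicinity_window_bp=0)

    def test_threshold_yaml_round_trip(self, tmp_path):
        th = Thresholds(validation_evalue=1e-6, core_occupancy=0.95)
        path = tmp_path / "th.yaml"
        th.to_yaml(path)
        assert Thresholds.from_yaml(path) == th


class TestFixtures:
    def test_census_has_16_lineages_and_12_families(self, table1_census):
        assert len(table1_census.n_genomes) == 16
        assert set(table1_census.cells["family"]) == set(NAP_FAMILIES)

    def test_lineage_sizes_sum_to_93(self, table1_census):
        assert sum(table1_census.n_genomes.values()) == 93

    def test_family_totals_sum_to_1197(self, table1_census):
        assert table1_census.grand_total == 1197

    def test_specific_cells(self):
        t1 = load_fixture("table1_census")
        afe_ebfc = t1[(t1.lineage_id == "AFE") & (t1.family == "EbfC")].iloc[0]
        assert (afe_ebfc.n_genomes, afe_ebfc.total, afe_ebfc.dose_min, afe_ebfc.dose_max) == (14, 14, 1, 1)
        fca_lrp = t1[(t1.lineage_id == "FCA") & (t1.family == "Lrp")].iloc[0]
        assert fca_lrp.total == 0

    def test_plasmid_fixture(self, table3):
        assert len(table3) == 8
        row = table3[table3.plasmid == "pACA1.1"].iloc[0]
        assert row.size_kb == 27.5 and row.n_naps == 2

    def test_imge_fixture(self, table4):
        assert len(table4) == 8
        row = table4[table4.element == "ICEAfe2"].iloc[0]
        assert row.families.split(";") == ["IHF_A", "HU"]

    def test_unknown_fixture_name(self):
        with pytest.raises(KeyError):
            load_fixture("no_such_table")
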