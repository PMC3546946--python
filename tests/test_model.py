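"""Data model, annotation-table I/O, validation and coverage arithmetic."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocomp import (
    Feature,
    FeatureTable,
    MitoGenome,
    ReadStats,
    compare_gene_order,
    coverage_summary,
    extract_feature_sequence,
    genome_length_from_table,
    validate_feature_table,
)
from mitocomp import io as mio
from mitocomp.model import reverse_complement


class TestMitoGenome:
    def test_length_matches_sequence(self):
        g = MitoGenome(id="t", sequence="acgt")
        assert g.length == 4
        assert g.sequence == "ACGT"      # uppercased

    def test_non_iupac_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 3"):
            MitoGenome(id="t", sequence="ACJT")

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            MitoGenome(id="t", sequence="")


class TestFastaIO:
    def test_roundtrip_and_circularity_token(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">xb circular Xenopus borealis\nACGTACGT\n>lin linear\nACGT\n")
        genomes = mio.read_genome_fasta(p)
        assert genomes[0].circular and genomes[0].length == 8
        assert not genomes[1].circular
        out = tmp_path / "o.fasta"
        mio.write_genome_fasta(genomes, out)
        again = mio.read_genome_fasta(out)
        assert [g.sequence for g in again] == [g.sequence for g in genomes]
        assert [g.circular for g in again] == [True, False]

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "e.fasta"
        p.write_text("")
        with pytest.raises(ValueError):
            mio.read_genome_fasta(p)

    def test_bad_character_names_offset(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">x\nACJT\n")
        with pytest.raises(ValueError, match="position 3"):
            mio.read_genome_fasta(p)


class TestFeatureTableIO:
    def test_published_lengths_from_coordinates(self, published_tables):
        xl = published_tables["XL"].get("nad5")
        assert (xl.start, xl.end, xl.declared_length) == (11720, 13534, 1815)
        assert xl.end - xl.start + 1 == 1815
        xb = published_tables["XB"].get("D-loop")
        assert xb.declared_length == 1909
        assert xb.end - xb.start + 1 == 1909

    def test_legacy_c_marker_maps_to_light_strand(self, tmp_path):
        p = tmp_path / "t.tsv"
        header = ("genome_id\tkind\tname\tstrand\tstart\tend\tdeclared_length"
                  "\tstart_codon\tstop_codon\tpctA\tpctC\tpctG\tpctT\n")
        p.write_text(header + "X\ttRNA\ttrnQ [C]\t\t10\t80\t71\t\t\t25\t25\t25\t25\n")
        t = mio.read_feature_table(p)
        assert t.features[0].strand == "L"
        assert t.features[0].name == "trnQ"

    def test_zero_start_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        header = ("genome_id\tkind\tname\tstrand\tstart\tend\tdeclared_length"
                  "\tstart_codon\tstop_codon\tpctA\tpctC\tpctG\tpctT\n")
        p.write_text(header + "X\tgene\tnad1\tH\t0\t9\t10\tATG\tTAA\t25\t25\t25\t25\n")
        with pytest.raises(ValueError, match="1-based"):
            mio.read_feature_table(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("genome_id\tkind\tname\nX\tgene\tnad1\n")
        with pytest.raises(ValueError, match="missing columns"):
            mio.read_feature_table(p)

    def test_canonical_roundtrip_byte_identical(self, published_tables, tmp_path):
        t = published_tables["XB"]
        p1 = tmp_path / "a.tsv"
        p2 = tmp_path / "b.tsv"
        mio.write_feature_table(t, p1)
        mio.write_feature_table(mio.read_feature_table(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestExtractFeatureSequence:
    def test_heavy_strand(self):
        g = MitoGenome(id="t", sequence="AAACCC")
        f = Feature(kind="tRNA", name="x", strand="H", start=2, end=4,
                    declared_length=3)
        assert extract_feature_sequence(g, f) == "AAC"

    def test_light_strand_is_reverse_complement(self):
        g = MitoGenome(id="t", sequence="AAACCC")
        f = Feature(kind="tRNA", name="x", strand="L", start=2, end=4,
                    declared_length=3)
        assert extract_feature_sequence(g, f) == "GTT"

    def test_wrap_matches_rotation_oracle(self):
        g = MitoGenome(id="t", sequence="AAACCC", circular=True)
        f = Feature(kind="control_region", name="cr", strand="H",
                    start=5, end=2, declared_length=4)
        got = extract_feature_sequence(g, f)
        # oracle: rotate so start becomes first position, take the span
        rotated = g.sequence[f.start - 1:] + g.sequence[:f.start - 1]
        assert got == rotated[:4] == "CCAA"

    def test_wrap_on_linear_rejected(self):
        g = MitoGenome(id="t", sequence="AAACCC", circular=False)
        f = Feature(kind="control_region", name="cr", strand="H",
                    start=5, end=2, declared_length=4)
        with pytest.raises(ValueError, match="linear"):
            extract_feature_sequence(g, f)

    def test_light_equals_revcomp_of_heavy_everywhere(self, synthetic_genome):
        genome, table = synthetic_genome
        for f in table:
            h = Feature(kind=f.kind, name=f.name, strand="H", start=f.start,
                        end=f.end, declared_length=f.declared_length,
                        start_codon=f.start_codon, stop_codon=f.stop_codon)
            l = Feature(kind=f.kind, name=f.name, strand="L", start=f.start,
                        end=f.end, declared_length=f.declared_length,
                        start_codon=f.start_codon, stop_codon=f.stop_codon)
            assert extract_feature_sequence(genome, l) == reverse_complement(
                extract_feature_sequence(genome, h))


class TestGenomeLength:
    def test_published_totals(self, published_tables):
        assert genome_length_from_table(published_tables["XB"]) == 17474
        assert genome_length_from_table(published_tables["XV"]) == 17716

    def test_single_feature(self):
        t = FeatureTable("x", [Feature(kind="tRNA", name="trnF", strand="H",
                                       start=1, end=68, declared_length=68)])
        assert genome_length_from_table(t) == 68

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            genome_length_from_table(FeatureTable("x", []))

    def test_matches_synthetic_genome_length(self, synthetic_genome):
        genome, table = synthetic_genome
        assert genome_length_from_table(table) == genome.length


class TestGeneOrder:
    def test_published_species_share_order(self, published_tables):
        ref = published_tables["XL"]
        for sp in ("ST", "XB", "XV"):
            assert compare_gene_order(ref, published_tables[sp])["identical"]

    def test_self_identity(self, published_tables):
        t = published_tables["XB"]
        assert compare_gene_order(t, t)["identical"]

    def test_moved_gene_detected(self, published_tables):
        t = published_tables["XB"]
        feats = [f for f in t.sorted().features if f.name != "nad6"]
        moved = Feature(kind="gene", name="nad6", strand="L", start=1, end=519,
                        declared_length=519, start_codon="ATG", stop_codon="TAA")
        t2 = FeatureTable("XBmod", [moved] + feats)
        res = compare_gene_order(t, t2)
        assert not res["identical"]
        assert res["first_divergence"] is not None


class TestValidation:
    def test_published_nad5_length_consistent(self, published_tables):
        v = validate_feature_table(published_tables["XL"])
        assert not any(x.code == "LENGTH_MISMATCH" and x.feature == "nad5"
                       for x in v)

    def test_overlaps_are_info_not_error(self, published_tables):
        v = validate_feature_table(published_tables["XL"])
        overlaps = [x for x in v if x.code == "OVERLAP"]
        assert any(x.feature == "atp6" for x in overlaps)   # atp8/atp6 junction
        assert all(x.severity == "INFO" for x in overlaps)

    def test_duplicate_span_flagged_as_warn(self, published_tables):
        # XL tRNA-Tyr duplicates the tRNA-Ser(UCN) coordinates in the
        # published table (suspected typo)
        v = validate_feature_table(published_tables["XL"])
        dups = [x for x in v if x.code == "DUPLICATE_SPAN"]
        assert dups and all(x.severity == "WARN" for x in dups)

    def test_bad_start_codon_flagged(self):
        t = FeatureTable("x", [Feature(kind="gene", name="nad1", strand="H",
                                       start=1, end=9, declared_length=9,
                                       start_codon="CTG", stop_codon="TAA")])
        v = validate_feature_table(t)
        assert any(x.code == "START_CODON" for x in v)

    def test_synthetic_table_validates_cleanly(self, synthetic_genome):
        genome, table = synthetic_genome
        assert validate_feature_table(table, genome) == []


class TestCoverage:
    def test_published_values(self, published_read_stats):
        xb = coverage_summary(published_read_stats["XB"])
        assert xb == {"pct_reads_mapped": 97.95, "pct_nt_mapped": 99.75,
                      "mean_doc": 9823}
        xv = coverage_summary(published_read_stats["XV"])
        assert xv["pct_reads_mapped"] == 67.18

    def test_fully_mapped(self):
        s = ReadStats("x", 100, 100, 50000, 50000, 500)
        out = coverage_summary(s)
        assert out["pct_reads_mapped"] == 100.0
        assert out["pct_nt_mapped"] == 100.0
        assert out["mean_doc"] == 100

    @given(k=st.integers(min_value=1, max_value=1000))
    @settings(max_examples=25, deadline=None)
    def test_percentages_scale_invariant(self, k):
        base = ReadStats("x", 1000, 750, 600000, 480000, 17000)
        scaled = ReadStats("x", 1000 * k, 750 * k, 600000 * k, 480000 * k, 17000)
        a, b = coverage_summary(base), coverage_summary(scaled)
        assert a["pct_reads_mapped"] == b["pct_reads_mapped"]
        assert a["pct_nt_mapped"] == b["pct_nt_mapped"]

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            ReadStats("x", 10, 11, 100, 50, 10)
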