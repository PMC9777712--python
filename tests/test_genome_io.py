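import pytest
from hypothesis import given, strategies as st

from mitochar.genome_io import (
    AnnotationTable,
    AnnotationValidationError,
    CircularGenome,
    FeatureRecord,
    GenomeFormatError,
    extract_region,
    linearize,
    read_annotation_table,
    read_fasta,
    read_genbank_features,
    reverse_complement,
    write_annotation_table,
)

dna = st.text(alphabet="ACGTN", max_size=200)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_case_normalization(self, tmp_path):
        g = read_fasta(_write(tmp_path, "a.fa", ">x\nacgt\n"))
        assert (g.length, g.sequence) == (4, "ACGT")

    def test_rna_converted_to_dna(self, tmp_path):
        g = read_fasta(_write(tmp_path, "a.fa", ">x\nACGU\n"))
        assert g.sequence == "ACGT"

    def test_empty_file_rejected(self, tmp_path):
        with pytest.raises(GenomeFormatError):
            read_fasta(_write(tmp_path, "a.fa", ""))

    def test_multi_record_rejected(self, tmp_path):
        with pytest.raises(GenomeFormatError, match="2"):
            read_fasta(_write(tmp_path, "a.fa", ">x\nACGT\n>y\nACGT\n"))

    def test_illegal_character_named_with_position(self, tmp_path):
        with pytest.raises(GenomeFormatError, match=r"'R'.*position 3"):
            read_fasta(_write(tmp_path, "a.fa", ">x\nACRT\n"))


class TestExtractRegion:
    g = CircularGenome(id="g", sequence="ACGTAC")

    def test_direct_slice(self):
        assert extract_region(self.g, 2, 4, "J") == "CGT"

    def test_minus_strand_is_reverse_complement(self):
        assert extract_region(self.g, 2, 4, "N") == "ACG"

    def test_wrap_matches_doubled_sequence_oracle(self):
        # oracle: double the sequence and slice across the origin
        doubled = self.g.sequence * 2
        expected = doubled[4 : 2 + 6]  # start=5 .. end=2 (wrapped)
        assert extract_region(self.g, 5, 2, "J") == expected == "ACAC"

    @pytest.mark.parametrize("start,end", [(2, 5), (1, 6), (4, 2)])
    def test_wrap_length_contract(self, start, end):
        got = extract_region(self.g, start, end, "J")
        expected_len = end - start + 1 if start <= end else end + 6 - start + 1
        assert len(got) == expected_len

    def test_wrap_rejected_on_linear_genome(self):
        lin = CircularGenome(id="g", sequence="ACGTAC", is_circular=False)
        with pytest.raises(IndexError):
            extract_region(lin, 5, 2, "J")

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            extract_region(self.g, 0, 3, "J")


class TestReverseComplement:
    def test_examples(self):
        assert reverse_complement("ATGC") == "GCAT"
        assert reverse_complement("") == ""
        assert reverse_complement("N") == "N"

    def test_illegal_character(self):
        with pytest.raises(GenomeFormatError):
            reverse_complement("AXGT")

    @given(dna)
    def test_involution_and_length(self, s):
        rc = reverse_complement(s)
        assert len(rc) == len(s)
        assert reverse_complement(rc) == s


class TestAnnotationTable:
    def test_reference_layout(self, reference_table):
        t = reference_table
        assert len(t) == 38
        assert len(t.of_class("PCG")) == 13
        assert len(t.of_class("tRNA")) == 22
        assert len(t.of_class("rRNA")) == 2
        assert len(t.of_class("CR")) == 1
        nad2 = t.get("nad2")
        assert (nad2.start, nad2.end, nad2.strand) == (206, 1234, "J")
        assert nad2.declared_start_codon == "ATA"

    def test_thousands_separators_and_location_column(self, tmp_path):
        p = _write(
            tmp_path,
            "t.tsv",
            "Gene\tStrand\tLocation\tAnticodon\tStartCodon\tStopCodon\n"
            "nad1\tN\t11,620–12,570\t\tTTG\tTAG\n",
        )
        t = read_annotation_table(p, genome_length=16137)
        f = t.get("nad1")
        assert (f.start, f.end) == (11620, 12570)

    def test_start_after_end_rejected_with_row(self, tmp_path):
        p = _write(
            tmp_path,
            "t.tsv",
            "Gene\tStrand\tStart\tEnd\nnad2\tJ\t1234\t206\n",
        )
        with pytest.raises(AnnotationValidationError, match="nad2"):
            read_annotation_table(p)

    def test_trna_requires_anticodon(self):
        with pytest.raises(AnnotationValidationError):
            FeatureRecord("trnX", "tRNA", "J", 1, 65)

    def test_duplicate_names_rejected(self):
        f1 = FeatureRecord("nad2", "PCG", "J", 1, 9)
        f2 = FeatureRecord("nad2", "PCG", "J", 20, 28)
        with pytest.raises(AnnotationValidationError, match="duplicate"):
            AnnotationTable("g", [f1, f2], 100)

    def test_round_trip(self, reference_table, tmp_path):
        p = tmp_path / "out.tsv"
        write_annotation_table(reference_table, p)
        back = read_annotation_table(p, genome_length=reference_table.genome_length)
        assert back.features == reference_table.features


GENBANK = """LOCUS       TEST                      40 bp    DNA     circular INV 01-JAN-2000
FEATURES             Location/Qualifiers
     tRNA            1..20
                     /gene="trnI(gat)"
     CDS             21..32
                     /gene="nad2"
     rRNA            complement(33..36)
                     /gene="rrnL"
     D-loop          37..40
ORIGIN
        1 atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc
//
"""


def test_genbank_feature_import(tmp_path):
    g, t = read_genbank_features(_write(tmp_path, "t.gb", GENBANK))
    assert g.length == 40
    names = {f.name: f for f in t}
    assert names["trnI(gat)"].feature_class == "tRNA"
    assert names["trnI(gat)"].anticodon == "GAT"
    assert names["nad2"].feature_class == "PCG"
    assert names["rrnL"].strand == "N"
    assert names["CR"].feature_class == "CR"


def test_linearize_rotates_origin():
    g = CircularGenome(id="g", sequence="ACGTAC")
    assert linearize(g, 3).sequence == "GTACAC"
    assert linearize(g, 1).sequence == g.sequence
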