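import math

import pytest
from Bio.Seq import Seq
from hypothesis import given, strategies as st

from mitochar.codon_usage import (
    CodingSequence,
    CodonUsageTable,
    classify_start_stop,
    count_codons,
    extract_all_cds,
    extract_cds,
    rscu,
    rscu_table,
    synonymous_families,
    translate,
)


class TestTranslate:
    @pytest.mark.parametrize(
        "codon,aa", [("TGA", "W"), ("AGA", "S"), ("AGG", "S"), ("ATA", "M")]
    )
    def test_invertebrate_mito_reassignments(self, codon, aa):
        assert translate(codon) == aa

    def test_standard_codons_and_stop(self):
        assert translate("ATGAAATAA") == "MK*"

    def test_codon_with_n_is_x(self):
        assert translate("ATGANA") == "MX"

    def test_length_error(self):
        with pytest.raises(ValueError):
            translate("ATGA")

    @given(st.lists(st.sampled_from("ACGT"), min_size=3, max_size=60))
    def test_matches_biopython_oracle(self, bases):
        seq = "".join(bases)[: len(bases) // 3 * 3]
        if not seq:
            return
        expected = str(Seq(seq).translate(table=5))
        assert translate(seq) == expected


class TestExtractCds:
    def test_cox1_incomplete_stop(self, synthetic_bundle):
        genome, table, _ = synthetic_bundle
        cds = extract_cds(genome, table, "cox1")
        assert len(cds.nucleotides) == 1540
        assert cds.stop_codon == "T" and not cds.stop_complete
        assert cds.n_internal_codons == 1540 // 3 - 1

    def test_nad1_ttg_start(self, synthetic_bundle):
        genome, table, _ = synthetic_bundle
        assert extract_cds(genome, table, "nad1").start_codon == "TTG"

    def test_non_pcg_rejected(self, synthetic_bundle):
        genome, table, _ = synthetic_bundle
        with pytest.raises(ValueError):
            extract_cds(genome, table, "trnI")

    def test_frame_property(self, synthetic_bundle):
        # complete-stop genes are 0 mod 3; the four T-stop genes are 1 mod 3
        genome, table, _ = synthetic_bundle
        for cds in extract_all_cds(genome, table):
            rem = len(cds.nucleotides) % 3
            assert rem == (0 if cds.stop_complete else 1)

    def test_internal_codon_accounting(self):
        cds = CodingSequence("x", "ATGAAATAA", "ATG", "TAA", True)
        assert cds.n_internal_codons == 1
        assert cds.internal_codons == ["AAA"]

    def test_no_internal_stops_on_synthetic(self, synthetic_bundle):
        genome, table, _ = synthetic_bundle
        for cds in extract_all_cds(genome, table):
            n_full = len(cds.nucleotides) // 3
            frame = cds.nucleotides[: 3 * n_full]
            aa = translate(frame)
            body = aa[:-1] if cds.stop_complete else aa
            assert "*" not in body, cds.gene


class TestStartStopTallies:
    def test_reference_pattern_on_synthetic(self, synthetic_bundle):
        genome, table, _ = synthetic_bundle
        tallies = classify_start_stop(extract_all_cds(genome, table))
        assert tallies["starts"] == {"ATA": 1, "ATT": 5, "ATG": 5, "ATC": 1, "TTG": 1}
        assert tallies["stops"] == {"TAA": 6, "TAG": 3, "T": 4}

    def test_empty(self):
        assert classify_start_stop([]) == {"starts": {}, "stops": {}}


class TestCountCodons:
    def test_single_cds(self):
        t = count_codons([CodingSequence("x", "ATGTTTTAA", "ATG", "TAA", True)])
        assert t.total_internal_codons == 1
        assert t.codon_counts["TTT"] == 1

    def test_total_is_3714_on_reference_layout(self, synthetic_bundle):
        genome, table, _ = synthetic_bundle
        t = count_codons(extract_all_cds(genome, table))
        assert t.total_internal_codons == 3714

    def test_counts_match_generator_manifest(self, synthetic_bundle):
        genome, table, manifest = synthetic_bundle
        t = count_codons(extract_all_cds(genome, table))
        for codon, n in t.codon_counts.items():
            assert n == manifest.codon_counts.get(codon, 0), codon

    def test_conservation(self, synthetic_bundle):
        genome, table, _ = synthetic_bundle
        t = count_codons(extract_all_cds(genome, table))
        assert sum(t.codon_counts.values()) == t.total_internal_codons


def _table_from_counts(counts):
    full = {c: 0 for f in synonymous_families().values() for c in f}
    full.update(counts)
    return CodonUsageTable(5, full, sum(full.values()))


class TestRscu:
    def test_two_codon_family_analytic(self):
        t = _table_from_counts({"GAA": 30, "GAG": 10})  # Glu family
        v = rscu(t)
        assert v["GAA"] == pytest.approx(1.5)
        assert v["GAG"] == pytest.approx(0.5)

    def test_uniform_family_is_one(self):
        t = _table_from_counts({"CGA": 5, "CGC": 5, "CGG": 5, "CGT": 5})  # Arg
        v = rscu(t)
        assert all(v[c] == pytest.approx(1.0) for c in ("CGA", "CGC", "CGG", "CGT"))

    def test_printed_leucine_example(self):
        # UUA count 434 within a six-codon Leu family totaling 576
        counts = {"TTA": 434, "TTG": 40, "CTA": 40, "CTC": 20, "CTG": 20, "CTT": 22}
        v = rscu(_table_from_counts(counts))
        assert round(v["TTA"], 3) == 4.521

    def test_unused_family_is_nan(self):
        v = rscu(_table_from_counts({}))
        assert math.isnan(v["GAA"])

    def test_met_family_is_atg_and_ata_under_code_5(self):
        fams = synonymous_families(5)
        assert sorted(fams["M"]) == ["ATA", "ATG"]
        # code 5: Leu keeps its six codons; Ser gains AGA/AGG for eight
        assert len(fams["L"]) == 6 and len(fams["S"]) == 8
        assert {"AGA", "AGG"} <= set(fams["S"])

    def test_family_sum_equals_family_size(self, synthetic_bundle):
        genome, table, _ = synthetic_bundle
        t = count_codons(extract_all_cds(genome, table))
        v = rscu(t)
        for aa, codons in synonymous_families().items():
            total = sum(t.codon_counts[c] for c in codons)
            if total:
                assert sum(v[c] for c in codons) == pytest.approx(len(codons))


def test_rscu_table_uses_rna_alphabet(synthetic_bundle):
    genome, table, _ = synthetic_bundle
    df = rscu_table(count_codons(extract_all_cds(genome, table)))
    assert df["Codon"].str.contains("U").any()
    assert not df["Codon"].str.contains("T").any()
    assert len(df) == 62  # 64 minus the two stop codons of code 5
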