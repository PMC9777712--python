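import numpy as np
import pytest
from hypothesis import given, strategies as st

from mitochar.repeat_scan import (
    RepeatScanParams,
    cr_report,
    find_microsatellites,
    find_tandem_repeats,
    longest_homopolymer,
)


class TestParams:
    def test_trf_string_parsing(self):
        p = RepeatScanParams.from_trf_string("2 7 7 80 10 50 500")
        assert (p.match_weight, p.mismatch_penalty, p.indel_penalty) == (2, 7, 7)
        assert (p.min_alignment_score, p.max_period) == (50, 500)

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            RepeatScanParams.from_trf_string("2 7 7")


class TestFindTandemRepeats:
    def test_planted_array_with_one_mismatch(self):
        motif = "TGGCCAAAATGT"  # period 12, no internal near-periodicity
        arr = list(motif * 4)
        arr[17] = "C" if arr[17] != "C" else "A"
        seq = "A" * 10 + "".join(arr) + "T" * 10
        reps = find_tandem_repeats(seq)
        assert len(reps) == 1
        r = reps[0]
        assert r.period == 12
        assert r.copy_number == pytest.approx(4.0, abs=0.2)
        # score formula: +2 per consensus match, -7 per mismatch
        matches = round(r.percent_identity * r.length)
        assert r.score == 2 * matches - 7 * (r.length - matches)

    def test_short_sequence_yields_nothing(self):
        assert find_tandem_repeats("ACGT") == []

    def test_empty_sequence(self):
        assert find_tandem_repeats("") == []

    def test_perfect_ta24(self):
        seq = "CGGC" + "TA" * 24 + "CGGC"
        reps = find_tandem_repeats(seq)
        assert len(reps) == 1
        r = reps[0]
        assert (r.period, r.copy_number, r.percent_identity) == (2, 24.0, 1.0)

    def test_low_scoring_array_filtered(self):
        # 10 copies x 2 bp = 20 matches = score 40 < 50
        assert find_tandem_repeats("G" + "TA" * 10 + "G") == []

    def test_strand_mirror(self):
        from mitochar.genome_io import reverse_complement

        motif = "TGGCCAAAATGT"
        seq = "CCGG" + motif * 4 + "GGCC"
        fwd = find_tandem_repeats(seq)
        rev = find_tandem_repeats(reverse_complement(seq))
        assert len(fwd) == len(rev) == 1
        L = len(seq)
        assert (rev[0].start, rev[0].end) == (L - fwd[0].end + 1, L - fwd[0].start + 1)

    @pytest.mark.parametrize("period", [4, 7, 12, 25, 60, 100])
    def test_planted_recovery_across_periods(self, period):
        rng = np.random.default_rng(period)
        bases = "ACGT"
        # enough copies that an array at ~90% identity clears the score
        # threshold even for short periods (score 50 needs ~25+ matches)
        copies = max(4.5, 48 / period)
        while True:
            cons = "".join(rng.choice(list(bases), size=period))
            arr = (cons * (int(copies) + 2))[: int(period * copies)]
            # require a non-degenerate consensus (no smaller effective period)
            if all(
                sum(a != b for a, b in zip(arr, arr[d:])) / (len(arr) - d) > 0.3
                for d in range(1, period)
            ):
                break
        arr = list(arr)
        n_mm = max(1, int(len(arr) * 0.08))  # identity >= 0.9
        for pos in np.linspace(3, len(arr) - 4, n_mm).astype(int):
            arr[pos] = bases[(bases.index(arr[pos]) + 1) % 4]
        flank1 = "".join(rng.choice(list(bases), size=60))
        flank2 = "".join(rng.choice(list(bases), size=60))
        seq = flank1 + "".join(arr) + flank2
        planted = (len(flank1) + 1, len(flank1) + len(arr))
        reps = find_tandem_repeats(seq)
        hits = []
        for r in reps:
            overlap = min(r.end, planted[1]) - max(r.start, planted[0]) + 1
            if overlap >= 0.8 * (planted[1] - planted[0] + 1):
                hits.append(r)
        assert hits, f"period-{period} array not recovered"
        periods_ok = [
            r.period == period
            or (r.period % period == 0)
            or (period % r.period == 0)
            for r in hits
        ]
        assert any(periods_ok)


class TestLongestHomopolymer:
    def test_examples(self):
        assert longest_homopolymer("TTTATT", "T") == (1, 3)
        assert longest_homopolymer("AAAA", "T") == (None, 0)

    def test_leftmost_on_tie(self):
        assert longest_homopolymer("TTATT", "T") == (1, 2)

    @given(st.text(alphabet="ACGT", max_size=200), st.sampled_from("ACGT"))
    def test_brute_force_oracle(self, s, base):
        # oracle: inspect every run directly
        best_pos, best_len = None, 0
        for i in range(len(s)):
            if s[i] == base and (i == 0 or s[i - 1] != base):
                j = i
                while j < len(s) and s[j] == base:
                    j += 1
                if j - i > best_len:
                    best_pos, best_len = i + 1, j - i
        assert longest_homopolymer(s, base) == (best_pos, best_len)


class TestFindMicrosatellites:
    def test_simple_hit(self):
        hits = find_microsatellites("TATATATA", {"TA"}, min_copies=3)
        assert len(hits) == 1
        assert hits[0].copies == 4

    def test_interrupted_below_threshold(self):
        assert find_microsatellites("TATGTATA", {"TA"}, min_copies=4) == []

    def test_near_perfect_merge(self):
        seq = "TA" * 5 + "G" + "TA" * 5
        hits = find_microsatellites(seq, {"TA"}, min_copies=10)
        assert len(hits) == 1
        assert hits[0].copies == 10 and hits[0].interruptions == 1

    def test_left_flank_attached(self):
        seq = "C" * 5 + "T" * 19 + "C" + "TA" * 12
        hits = find_microsatellites(seq, {"TA"}, min_copies=10)
        assert "T" * 19 in hits[0].left_flank

    def test_motif_length_bounds(self):
        with pytest.raises(ValueError):
            find_microsatellites("ACGT", {"ACGTACG"}, 2)


class TestCrReport:
    def test_matches_generator_manifest(self, synthetic_bundle):
        genome, table, manifest = synthetic_bundle
        rep = cr_report(genome, table)
        assert rep.cr_length == 1327
        assert rep.longest_poly_t == manifest.poly_t
        assert len(rep.repeats) == len(manifest.repeats)
        for det, planted in zip(rep.repeats, manifest.repeats):
            overlap = min(det.end, planted.cr_end) - max(det.start, planted.cr_start) + 1
            assert overlap >= 0.8 * planted.length
            assert (
                det.period == planted.period
                or det.period % planted.period == 0
                or planted.period % det.period == 0
            )
        motif, copies, start = manifest.microsatellite
        ms = rep.microsatellites
        assert [(m.motif, m.copies, m.start) for m in ms] == [(motif, copies, start)]
        # the conserved poly-T stretch sits in the microsatellite's left flank
        assert "T" * manifest.poly_t[1] in ms[0].left_flank

    def test_tr_totals(self, synthetic_bundle):
        genome, table, manifest = synthetic_bundle
        rep = cr_report(genome, table)
        assert rep.tr_total_bp == sum(r.length for r in manifest.repeats) == 238
        assert rep.tr_fraction_of_cr == pytest.approx(238 / 1327)

    def test_missing_cr_raises(self, synthetic_bundle):
        from mitochar.genome_io import AnnotationTable

        genome, table, _ = synthetic_bundle
        no_cr = AnnotationTable(
            "g", [f for f in table if f.feature_class != "CR"], table.genome_length
        )
        with pytest.raises(KeyError):
            cr_report(genome, no_cr)
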