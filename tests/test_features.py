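import math
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from arfusion.features import (
    BackgroundModel,
    candidate_word,
    compute_density,
    compute_occurrence,
    compute_position,
    compute_significance_score,
    gc_content,
    revcomp,
    scan_candidates,
    zcurve,
    zscore_from_expected,
)
from arfusion.io_formats import ExpressionRecord, GeneModel, SequenceRecord

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


def seqs(*strings):
    return [SequenceRecord(f"s{i}", s) for i, s in enumerate(strings)]


class TestScanCandidates:
    def test_forward_hits_with_tight_window(self):
        cands = scan_candidates(seqs("TGTCAAATGTC"), core="TGTC", window=4)
        assert [(c.core_start, c.strand) for c in cands] == [(0, "+"), (7, "+")]

    def test_reverse_hit_via_reverse_complement(self):
        (cand,) = scan_candidates(seqs("GACA"), core="TGTC", window=4)
        assert cand.strand == "-" and cand.core_start == 0

    def test_no_core_no_candidates(self):
        assert scan_candidates(seqs("AAAA"), core="TGTC", window=4) == []

    def test_edge_clipped_windows_dropped(self):
        # core at position 0 cannot carry a centred 10 bp window
        assert scan_candidates(seqs("TGTCAA"), core="TGTC", window=10) == []

    def test_empty_sequence_set_rejected(self):
        with pytest.raises(ValueError):
            scan_candidates([], core="TGTC")

    def test_n_windows_skipped(self):
        assert scan_candidates(seqs("AANTGTCAA"), core="TGTC", window=8) == []

    @given(dna)
    def test_reverse_complement_mirror(self, seq):
        """Scanning the reverse complement swaps strands and mirrors coordinates."""
        fwd = scan_candidates(seqs(seq), core="TGTC", window=4)
        rev = scan_candidates(seqs(revcomp(seq)), core="TGTC", window=4)
        mirrored = sorted(
            (len(seq) - c.end, "-" if c.strand == "+" else "+") for c in fwd
        )
        assert mirrored == sorted((c.start, c.strand) for c in rev)

    def test_core_hits_collects_neighbours_both_strands(self):
        seq = "A" * 6 + "TGTC" + "AA" + "GACA" + "A" * 6
        (first, *_) = scan_candidates(seqs(seq), core="TGTC", window=16)
        assert [s for _, s in first.core_hits] == ["+", "-"]


class TestCandidateWord:
    def test_plus_strand_extends_downstream(self):
        cands = scan_candidates(seqs("AAATGTCTCAAA"), core="TGTC", window=10)
        plus = [c for c in cands if c.strand == "+"]
        assert candidate_word(plus[0], 6) == "TGTCTC"

    def test_minus_strand_word_starts_with_core(self):
        # GAGACA on the forward strand is TGTCTC on the reverse
        (cand,) = scan_candidates(seqs("AAGAGACAAA"), core="TGTC", window=8)
        assert cand.strand == "-"
        assert candidate_word(cand, 6) == "TGTCTC"


class TestPosition:
    def test_upstream_is_negative(self):
        (cand,) = scan_candidates(seqs("TGTC" + "A" * 10), core="TGTC", window=4)
        gene = GeneModel("g", "s0", "+", cds_start=10)
        assert compute_position(cand, gene) == -10

    def test_motif_at_the_atg_is_zero(self):
        (cand,) = scan_candidates(seqs("AATGTCAA"), core="TGTC", window=4)
        gene = GeneModel("g", "s0", "+", cds_start=2)
        assert compute_position(cand, gene) == 0

    def test_minus_strand_gene_mirrors_sign(self):
        # motif start 10 bp downstream (genomic) of a '-' gene ATG -> upstream
        (cand,) = scan_candidates(seqs("A" * 15 + "TGTC" + "A" * 5), core="TGTC", window=4)
        gene = GeneModel("g", "s0", "-", cds_start=5)
        assert compute_position(cand, gene) == -10

    def test_chromosome_mismatch_rejected(self):
        (cand,) = scan_candidates(seqs("TGTC"), core="TGTC", window=4)
        with pytest.raises(ValueError):
            compute_position(cand, GeneModel("g", "other", "+", 0))


class TestSignificanceScore:
    def test_observed_equals_expected_is_zero(self):
        assert zscore_from_expected(4, 4) == 0.0

    def test_hand_value(self):
        assert zscore_from_expected(16, 4) == pytest.approx(6.0)

    def test_zero_observed(self):
        assert zscore_from_expected(0, 4) == pytest.approx(-2.0)

    def test_expectation_floor(self):
        # E below 0.5 is floored before dividing
        assert zscore_from_expected(1, 0.001) == pytest.approx((1 - 0.5) / math.sqrt(0.5))

    def test_against_markov_background(self):
        bg = BackgroundModel.fit(seqs("ACGT" * 100), order=0)
        sc = compute_significance_score(10, bg, 100, word="TGTC")
        # uniform composition: E = 100 * 2 * (1/4)^4
        e = 100 * 2 * 0.25**4
        assert sc == pytest.approx(zscore_from_expected(10, e))

    def test_missing_context_rejected(self):
        bg = BackgroundModel.fit(seqs("AAAA" * 10), order=2)
        with pytest.raises(ValueError, match="context"):
            bg.word_probability("TGTC")

    def test_transitions_sum_to_one(self):
        bg = BackgroundModel.fit(seqs("ACGTTGCAACGT" * 5), order=2)
        for ctx, probs in bg.transitions.items():
            assert sum(probs.values()) == pytest.approx(1.0)


class TestOccurrence:
    def test_manual_scan(self):
        assert compute_occurrence("TGTC", seqs("TGTCAAATGTC")) == 2

    def test_one_hit_per_strand(self):
        assert compute_occurrence("TGTC", seqs("TGTCGACA")) == 2

    def test_absent_word(self):
        assert compute_occurrence("TGTC", seqs("AAAA")) == 0

    @given(dna)
    def test_palindrome_counts_both_strands(self, seq):
        word = "ACGT"  # its own reverse complement
        fwd = sum(
            1 for i in range(len(seq) - 3) if seq[i : i + 4] == word
        )
        assert compute_occurrence(word, seqs(seq)) == 2 * fwd


class TestDensity:
    EXPR = [ExpressionRecord(f"s{i}", 2.0) for i in range(4)]

    def test_fraction_of_responsive_promoters(self):
        proms = seqs("TGTCAA", "AATGTC", "GACAAA", "AAAAAA")
        assert compute_density("TGTC", proms, self.EXPR) == 0.75

    def test_zero_when_absent(self):
        assert compute_density("TGTC", seqs("AAAA", "CCCC"), self.EXPR[:2]) == 0.0

    def test_boundary_fc_counts_as_responsive(self):
        proms = seqs("TGTCAA")
        expr = [ExpressionRecord("s0", 1.0)]  # exactly log2(2)
        assert compute_density("TGTC", proms, expr, fc_threshold=2.0) == 1.0

    def test_no_responsive_genes_is_an_error(self):
        expr = [ExpressionRecord("s0", 0.1)]
        with pytest.raises(ValueError, match="responsive"):
            compute_density("TGTC", seqs("TGTC"), expr)

    @given(st.lists(st.floats(-4, 4, allow_nan=False), min_size=3, max_size=8))
    def test_responsive_core_count_shrinks_with_threshold(self, fcs):
        """Raising the fold-change cut-off can only remove promoters from the
        responsive pool, so the absolute count of core-bearing responsive
        promoters (density numerator) is non-increasing."""
        proms = seqs(*["TGTCAA" if i % 2 else "AAAAAA" for i in range(len(fcs))])
        expr = [ExpressionRecord(f"s{i}", fc) for i, fc in enumerate(fcs)]
        counts = []
        for thr in (1.5, 2.0, 3.0):
            cut = math.log2(thr)
            resp = [p for p, e in zip(proms, expr) if abs(e.log2_fc) >= cut]
            try:
                d = compute_density("TGTC", proms, expr, fc_threshold=thr)
            except ValueError:
                counts.append(0)
                continue
            counts.append(round(d * len(resp)))
        assert counts == sorted(counts, reverse=True)


class TestZcurveGc:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ACGT", (0, 0, 0)), ("AAAA", (1, 1, 1)), ("GGCC", (0, 0, -1))],
    )
    def test_hand_values(self, seq, expected):
        assert zcurve(seq) == pytest.approx(expected)

    @pytest.mark.parametrize("seq,expected", [("GGCC", 1.0), ("AATT", 0.0), ("ACGT", 0.5)])
    def test_gc_hand_values(self, seq, expected):
        assert gc_content(seq) == expected

    @given(dna)
    def test_case_and_shuffle_invariance(self, seq):
        shuffled = "".join(random.Random(0).sample(seq, len(seq)))
        assert zcurve(seq) == pytest.approx(zcurve(shuffled))
        assert zcurve(seq) == pytest.approx(zcurve(seq.lower()))
        assert gc_content(seq) == pytest.approx(gc_content(shuffled))

    @given(dna)
    def test_zcurve_bounded(self, seq):
        assert all(-1 <= v <= 1 for v in zcurve(seq))

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            zcurve("NNN")
        with pytest.raises(ValueError):
            gc_content("NNN")
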