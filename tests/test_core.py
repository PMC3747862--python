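"""Core model: alphabet, frequency estimation, pair-aware scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lasagna.core import (
    Alignment,
    AlphabetError,
    FrequencyModel,
    PSSM,
    Site,
    best_alignment_scores,
    column_stats,
    reverse_complement,
    small_sample_correction,
)

from _oracles import (
    brute_column_frequencies,
    brute_pair_frequencies,
    brute_plain_score,
    brute_sliding,
    random_alignment,
    random_pssm,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=30)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ACGT", "ACGT"), ("AAAC", "GTTT"), ("-AC", "GT-"), ("--A-", "-T--")],
    )
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    @settings(derandomize=True, max_examples=50)
    @given(dna)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_rejects_unknown_letters(self):
        with pytest.raises(AlphabetError):
            reverse_complement("ACGN")


class TestSite:
    def test_interior_gap_rejected(self):
        with pytest.raises(ValueError):
            Site("x", "AC-GT")

    def test_original_round_trip(self):
        site = Site("x", "--ACGG-", source_strand="-")
        assert site.ungapped == "ACGG"
        assert site.original() == "CCGT"


class TestAlignment:
    def test_rejects_ragged_rows(self):
        with pytest.raises(ValueError):
            Alignment([Site("a", "ACGT"), Site("b", "ACG")])

    def test_rejects_all_gap_column(self):
        with pytest.raises(ValueError):
            Alignment([Site("a", "A-GT"), Site("b", "C-GT")])


class TestFrequencyModel:
    def test_degenerate_column(self):
        aln = Alignment([Site(str(i), "ACGT") for i in range(4)])
        freq = FrequencyModel.from_alignment(aln, pseudocount=0.0)
        assert freq.probs[0, 0] == 1.0  # column 1 is all A

    def test_pair_probability_degenerate(self):
        aln = Alignment([Site("a", "AC"), Site("b", "AC")])
        freq = FrequencyModel.from_alignment(aln, K=1, pseudocount=0.0, pair_pseudocount=0.0)
        assert freq.pair_probs[1][0, 0, 1] == 1.0  # (A, C) at positions (1, 2)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(7)
        aln = random_alignment(rng, 4, 6)
        freq = FrequencyModel.from_alignment(aln, K=2, pseudocount=0.25, pair_pseudocount=0.25)
        np.testing.assert_allclose(freq.probs, brute_column_frequencies(aln, 0.25))
        for k in (1, 2):
            np.testing.assert_allclose(
                freq.pair_probs[k], brute_pair_frequencies(aln, k, 0.25)
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_normalization_invariants(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, int(rng.integers(2, 8)), int(rng.integers(4, 10)))
        freq = FrequencyModel.from_alignment(aln, K=3)
        np.testing.assert_allclose(freq.probs.sum(axis=1), 1.0, atol=1e-9)
        assert abs(freq.background.sum() - 1.0) < 1e-9
        for p in freq.pair_probs.values():
            np.testing.assert_allclose(p.sum(axis=(1, 2)), 1.0, atol=1e-9)
        assert (freq.probs > 0).all() and (freq.background > 0).all()

    def test_background_defaults_to_pooled_counts(self):
        aln = Alignment([Site("a", "AAAA"), Site("b", "AAAC")])
        freq = FrequencyModel.from_alignment(aln, pseudocount=0.0)
        np.testing.assert_allclose(freq.background, [7 / 8, 1 / 8, 0, 0])


class TestPSSMConstruction:
    def test_identity_background_gives_zero_scores(self):
        freq = FrequencyModel(
            np.full((5, 4), 0.25), {}, np.full(4, 0.25), np.full(5, 10.0), 0.25, 0.0625
        )
        pssm = PSSM.from_frequencies(freq)
        np.testing.assert_allclose(pssm.scores, 0.0)

    def test_certain_letter_scores_two_bits(self):
        probs = np.full((1, 4), 1e-12)
        probs[0, 0] = 1.0
        freq = FrequencyModel(probs, {}, np.full(4, 0.25), np.array([8.0]), 0.25, 0.0625)
        assert PSSM.from_frequencies(freq).scores[0, 0] == pytest.approx(2.0)

    def test_gap_minimum_definition(self):
        pssm = random_pssm(np.random.default_rng(3), 6, 2)
        np.testing.assert_allclose(pssm.gap_single, pssm.scores.min(axis=1))
        np.testing.assert_allclose(pssm.gap_pair(1), pssm.pair_scores[1].min(axis=(1, 2)))

    def test_zero_probability_raises(self):
        aln = Alignment([Site("a", "AAAA")])
        with pytest.raises(ValueError, match="pseudocount"):
            PSSM.from_alignment(aln, pseudocount=0.0)


class TestScoring:
    def test_scope_zero_is_classical_additive_score(self):
        rng = np.random.default_rng(11)
        pssm = random_pssm(rng, 7, 0)
        for _ in range(20):
            codes = rng.integers(0, 4, size=7)
            expected = sum(pssm.scores[i, codes[i]] for i in range(7))
            assert pssm.score_window(codes) == pytest.approx(expected)

    def test_pair_term_count_small_window(self):
        # l = 3, K = 2: (3-1) + (3-2) = 3 pair terms on top of 3 single terms.
        scores = np.zeros((3, 4))
        pair = {1: np.ones((2, 4, 4)), 2: np.ones((1, 4, 4))}
        pssm = PSSM(scores, pair)
        assert pssm.score_window("ACG") == pytest.approx(3.0)

    def test_gapless_window_scores_identically_with_gap_awareness(self):
        rng = np.random.default_rng(5)
        pssm = random_pssm(rng, 6, 2)
        codes = rng.integers(0, 4, size=6)
        assert pssm.score_window(codes) == pytest.approx(
            pssm.score_window(codes, gap_aware=True)
        )

    def test_length_mismatch_raises(self):
        pssm = random_pssm(np.random.default_rng(0), 5, 0)
        with pytest.raises(ValueError):
            pssm.score_window("ACGT")

    def test_plain_scoring_rejects_gaps(self):
        pssm = random_pssm(np.random.default_rng(0), 4, 0)
        with pytest.raises(AlphabetError):
            pssm.score_window("-ACG")


class TestSliding:
    def test_window_count(self):
        rng = np.random.default_rng(2)
        for l, ls in [(6, 12), (4, 4), (8, 3), (5, 1)]:
            pssm = random_pssm(rng, l, min(2, l - 1))
            codes = rng.integers(0, 4, size=ls)
            assert pssm.sliding_scores(codes).shape[0] == l + ls - 1

    def test_max_property_and_bruteforce(self):
        rng = np.random.default_rng(13)
        pssm = random_pssm(rng, 6, 2)
        for _ in range(10):
            codes = rng.integers(0, 4, size=12)
            best, offset, scores = brute_sliding(pssm, codes)
            hit = pssm.sliding_score("".join("ACGT"[c] for c in codes))
            assert hit.score == pytest.approx(best)
            assert hit.offset == offset
            assert all(hit.score >= s - 1e-12 for s in scores)

    def test_leftmost_tie_break(self):
        # A flat PSSM scores every window identically: offset 0 must win.
        pssm = PSSM(np.zeros((4, 4)))
        assert pssm.sliding_score("ACGTACG").offset == 0

    def test_batch_sliding_matches_single(self):
        rng = np.random.default_rng(17)
        pssm = random_pssm(rng, 5, 1)
        windows = rng.integers(0, 4, size=(8, 9))
        batch = best_alignment_scores(pssm, windows)
        singles = [pssm.sliding_scores(w).max() for w in windows]
        np.testing.assert_allclose(batch, singles)


class TestStrandDuality:
    def test_score_matches_on_reverse_complemented_model(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            aln = random_alignment(rng, 5, 7)
            freq = FrequencyModel.from_alignment(aln, K=2)
            fwd = PSSM.from_frequencies(freq)
            rev = PSSM.from_frequencies(freq.reverse_complement())
            codes = rng.integers(0, 4, size=7)
            rc = np.array([3 - c for c in codes[::-1]])
            assert fwd.score_window(codes) == pytest.approx(rev.score_window(rc))
            assert brute_plain_score(fwd, codes) == pytest.approx(
                brute_plain_score(rev, rc)
            )


class TestColumnStats:
    def test_small_sample_correction_value(self):
        assert small_sample_correction(4) == pytest.approx(3 / (2 * math.log(2) * 4))
        assert small_sample_correction(4) == pytest.approx(0.5410, abs=5e-4)

    def test_uniform_column_clamps_to_zero(self):
        aln = Alignment([Site(str(i), c) for i, c in enumerate("ACGT" * 25)])
        _, ic = column_stats(aln)
        assert ic[0] == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_bounds(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, int(rng.integers(2, 10)), 8)
        coverage, ic = column_stats(aln)
        assert ((ic >= 0.0) & (ic <= 2.0)).all()
        assert ((coverage > 0.0) & (coverage <= 1.0)).all()

    def test_gap_aware_coverage(self):
        aln = Alignment([Site("a", "ACGT--"), Site("b", "--GTAC")])
        coverage, _ = column_stats(aln)
        np.testing.assert_allclose(coverage, [0.5, 0.5, 1.0, 1.0, 0.5, 0.5])
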