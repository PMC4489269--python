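import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motifkit import (
    Motif,
    SequenceRecord,
    SequenceSet,
    counts_to_motif,
    estimate_background,
    information_content,
    make_alphabet,
    motif_to_logodds,
    uniform_background,
)
from motifkit.core import Background, with_pseudocounts

from conftest import random_motif


class TestAlphabet:
    def test_dna_standard(self, dna):
        assert dna.core_symbols == "ACGT"
        assert dna.complement("A") == "T" and dna.complement("C") == "G"
        assert set(dna.ambiguity_map["N"]) == set("ACGT")
        assert set(dna.ambiguity_map["R"]) == {"A", "G"}

    def test_complement_is_involution(self, dna):
        for letter in dna.extended_symbols:
            assert dna.complement(dna.complement(letter)) == letter

    def test_protein_has_no_complement(self, protein):
        assert len(protein.core_symbols) == 20
        assert not protein.complement_map
        assert protein.wildcard == "X"
        with pytest.raises(ValueError):
            protein.complement("A")

    def test_ambiguity_sets_are_proper(self):
        for kind in ("DNA", "RNA", "protein"):
            alph = make_alphabet(kind)
            core = set(alph.core_symbols)
            for letter, exp in alph.ambiguity_map.items():
                if letter == alph.wildcard:
                    assert set(exp) == core
                else:
                    assert 2 <= len(exp) < len(core)
                    assert set(exp) <= core

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="peptide"):
            make_alphabet("peptide")


class TestBackground:
    def test_uniform_from_balanced_sequence(self, dna):
        seqs = SequenceSet(dna, (SequenceRecord("s", "ACGT"),))
        bg = estimate_background(seqs, pseudocount=0.0)
        assert np.allclose(bg.frequencies, 0.25)

    def test_zero_frequency_rejected_without_pseudocount(self, dna):
        seqs = SequenceSet(dna, (SequenceRecord("s", "AAAA"),))
        with pytest.raises(ValueError, match="pseudocount"):
            estimate_background(seqs, pseudocount=0.0)

    def test_pseudocount_arithmetic(self, dna):
        seqs = SequenceSet(dna, (SequenceRecord("s", "AAAA"),))
        bg = estimate_background(seqs, pseudocount=1.0)
        assert bg.frequency("A") == pytest.approx(5 / 8)
        for c in "CGT":
            assert bg.frequency(c) == pytest.approx(1 / 8)

    def test_ambiguity_contributes_fractionally(self, dna):
        seqs = SequenceSet(dna, (SequenceRecord("s", "RRRR"),))  # R = A/G
        bg = estimate_background(seqs, pseudocount=0.25)
        # R splits evenly between A and G: (2 + 0.25) / (4 + 1)
        assert bg.frequency("A") == pytest.approx(2.25 / 5)
        assert bg.frequency("A") == bg.frequency("G")
        assert bg.frequency("C") == pytest.approx(0.25 / 5)

    def test_strand_symmetrization(self, dna):
        seqs = SequenceSet(dna, (SequenceRecord("s", "AAAAAAAG"),))
        bg = estimate_background(seqs, pseudocount=0.5, use_both_strands=True)
        assert bg.frequency("A") == bg.frequency("T")
        assert bg.frequency("C") == bg.frequency("G")

    def test_invariants_enforced(self, dna):
        with pytest.raises(ValueError):
            Background(dna, np.array([0.5, 0.5, 0.0, 0.0]))
        with pytest.raises(ValueError):
            Background(dna, np.array([0.3, 0.3, 0.3, 0.3]))


class TestCountsToMotif:
    def test_forced_arithmetic(self, dna, uniform_dna_bg):
        m = counts_to_motif(np.array([[2, 0, 0, 2]]), uniform_dna_bg, 1.0)
        assert np.allclose(m.probabilities[0], [0.45, 0.05, 0.05, 0.45])
        assert m.nsites == 4

    def test_zero_pseudocount_identity(self, dna, uniform_dna_bg):
        counts = np.array([[1.0, 2.0, 3.0, 4.0]])
        m = counts_to_motif(counts, uniform_dna_bg, 0.0)
        assert np.allclose(m.probabilities[0], counts[0] / 10.0)

    def test_zero_count_with_zero_pseudocount_rejected(self, uniform_dna_bg):
        with pytest.raises(ValueError, match="pseudocount"):
            counts_to_motif(np.array([[2, 0, 0, 2]]), uniform_dna_bg, 0.0)

    def test_zero_row_rejected(self, uniform_dna_bg):
        with pytest.raises(ValueError, match="zero"):
            counts_to_motif(np.array([[1, 1, 1, 1], [0, 0, 0, 0]]),
                            uniform_dna_bg, 1.0)


class TestLogOdds:
    def test_background_motif_scores_zero(self, dna, uniform_dna_bg):
        m = Motif("flat", dna, np.full((3, 4), 0.25))
        lom = motif_to_logodds(m, uniform_dna_bg)
        assert np.allclose(lom.scores, 0.0)

    def test_doubling_is_one_bit(self, dna, uniform_dna_bg):
        m = Motif("m", dna, np.array([[0.5, 0.3, 0.1, 0.1]]))
        lom = motif_to_logodds(m, uniform_dna_bg)
        assert lom.scores[0, 0] == pytest.approx(1.0)

    def test_integer_roundtrip_within_half_quantum(self, dna, uniform_dna_bg):
        rng = np.random.default_rng(0)
        m = random_motif(7, dna, rng)
        lom = motif_to_logodds(m, uniform_dna_bg, quantization_bins=1000)
        approx = lom.integer_scores[:, :4] * lom.scale + lom.offset
        assert np.all(np.abs(approx - lom.scores) <= lom.scale / 2 + 1e-12)

    def test_zero_probability_rejected(self, dna, uniform_dna_bg):
        m = Motif("z", dna, np.array([[1.0, 0.0, 0.0, 0.0]]))
        with pytest.raises(ValueError, match="position 0"):
            motif_to_logodds(m, uniform_dna_bg)

    def test_pseudocounts_restore_positivity(self, dna, uniform_dna_bg):
        m = Motif("z", dna, np.array([[1.0, 0.0, 0.0, 0.0]]), nsites=10)
        padded = with_pseudocounts(m, uniform_dna_bg, 1.0)
        assert np.all(padded.probabilities > 0)
        motif_to_logodds(padded, uniform_dna_bg)  # no longer raises


class TestInformationContent:
    def test_uniform_is_zero(self, dna, uniform_dna_bg):
        m = Motif("flat", dna, np.full((4, 4), 0.25))
        per_pos, total = information_content(m, uniform_dna_bg)
        assert np.allclose(per_pos, 0.0) and total == 0.0

    def test_deterministic_column_is_two_bits(self, dna, uniform_dna_bg):
        m = Motif("det", dna, np.array([[1.0, 0.0, 0.0, 0.0]]))
        _, total = information_content(m, uniform_dna_bg)
        assert total == pytest.approx(2.0)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_non_negative_and_rc_invariant(self, seed):
        dna = make_alphabet("DNA")
        bg = uniform_background(dna)
        m = random_motif(5, dna, np.random.default_rng(seed))
        per_pos, total = information_content(m, bg)
        assert np.all(per_pos >= 0)
        _, total_rc = information_content(m.reverse_complement(), bg)
        assert total_rc == pytest.approx(total)


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2 ** 31 - 1))
def test_reverse_complement_is_involution(seed):
    dna = make_alphabet("DNA")
    m = random_motif(6, dna, np.random.default_rng(seed))
    back = m.reverse_complement().reverse_complement()
    assert np.allclose(back.probabilities, m.probabilities, atol=1e-12)
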