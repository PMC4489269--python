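import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motifkit import (
    MotifFile,
    make_alphabet,
    parse_meme_motifs,
    parse_typed_motifs,
    read_fasta,
    write_fasta,
    write_meme_motifs,
)
from motifkit.core import Background, Motif

from conftest import random_motif


class TestFasta:
    def test_lines_concatenated(self):
        seqs = read_fasta(">s1 some description\nACGT\nACGT\n")
        rec = seqs.records[0]
        assert rec.identifier == "s1"
        assert rec.description == "some description"
        assert rec.residues == "ACGTACGT"

    def test_roundtrip_identity(self, dna):
        text = ">a first\nACGTNNRY\n>b\nTTTTGGGGCCCCAAAA\n"
        seqs = read_fasta(text, dna)
        buf = io.StringIO()
        write_fasta(seqs, buf)
        again = read_fasta(buf.getvalue(), dna)
        assert again == seqs

    def test_invalid_letter_reported_with_line(self, dna):
        with pytest.raises(ValueError, match=r"'J'.*line 3"):
            read_fasta(">s1\nACGT\nACGJ\n", dna)

    def test_duplicate_identifier_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(">s1\nACGT\n>s1\nTTTT\n")

    def test_lowercase_uppercased(self, dna):
        seqs = read_fasta(">s\nacgtn\n", dna)
        assert seqs.records[0].residues == "ACGTN"

    @pytest.mark.parametrize(
        "body,expected",
        [("ACGTN", "DNA"), ("ACGUN", "RNA"), ("MKLVFW", "protein")],
    )
    def test_alphabet_inference(self, body, expected):
        assert read_fasta(f">s\n{body}\n").alphabet.name == expected


MINIMAL = """\
MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.300000 C 0.200000 G 0.200000 T 0.300000

MOTIF crp alt1
letter-probability matrix: alength= 4 w= 4 nsites= 20 E= 1.1e-5
0.100000 0.200000 0.300000 0.400000
0.250000 0.250000 0.250000 0.250000
0.970000 0.010000 0.010000 0.010000
0.400000 0.300000 0.200000 0.100000
"""


class TestMemeFormat:
    def test_header_fields_echoed(self):
        mf = parse_meme_motifs(MINIMAL)
        assert mf.version == "4"
        assert mf.alphabet.name == "DNA"
        assert mf.background.frequency("A") == pytest.approx(0.3)
        (m,) = mf.motifs
        assert (m.name, m.alt_name, m.width) == ("crp", "alt1", 4)
        assert m.nsites == 20
        assert m.evalue == pytest.approx(1.1e-5)

    def test_roundtrip_at_printed_precision(self):
        mf = parse_meme_motifs(MINIMAL)
        buf = io.StringIO()
        write_meme_motifs(mf, buf)
        again = parse_meme_motifs(buf.getvalue())
        assert np.allclose(again.motifs[0].probabilities,
                           mf.motifs[0].probabilities, atol=1e-6)
        # write . read . write is a fixed point
        buf2 = io.StringIO()
        write_meme_motifs(again, buf2)
        assert buf2.getvalue() == buf.getvalue()

    def test_bad_row_length_rejected(self):
        bad = MINIMAL.replace("0.250000 0.250000 0.250000 0.250000",
                              "0.2 0.2 0.2 0.2 0.2")
        with pytest.raises(ValueError, match="crp"):
            parse_meme_motifs(bad)

    def test_row_sum_rejected(self):
        bad = MINIMAL.replace("0.100000 0.200000 0.300000 0.400000",
                              "0.100000 0.200000 0.300000 0.500000")
        with pytest.raises(ValueError, match="row 0"):
            parse_meme_motifs(bad)

    def test_alength_mismatch_rejected(self):
        bad = MINIMAL.replace("alength= 4", "alength= 20")
        with pytest.raises(ValueError, match="alength"):
            parse_meme_motifs(bad)

    def test_missing_version_rejected(self):
        with pytest.raises(ValueError, match="MEME version"):
            parse_meme_motifs("ALPHABET= ACGT\n")

    def test_empty_motif_list_roundtrip(self, dna):
        mf = MotifFile(alphabet=dna)
        buf = io.StringIO()
        write_meme_motifs(mf, buf)
        again = parse_meme_motifs(buf.getvalue())
        assert again.motifs == []

    def test_biopython_reads_our_output(self, dna, uniform_dna_bg):
        """Independent cross-check with Bio.motifs' minimal-format parser."""
        from Bio import motifs as bio_motifs

        rng = np.random.default_rng(5)
        ours = [random_motif(6, dna, rng, name=f"m{i}") for i in range(3)]
        mf = MotifFile(alphabet=dna, motifs=ours, background=uniform_dna_bg)
        buf = io.StringIO()
        write_meme_motifs(mf, buf)
        buf.seek(0)
        theirs = bio_motifs.parse(buf, "minimal")
        assert len(theirs) == 3
        for mine, other in zip(ours, theirs):
            counts = np.array([[other.counts[c][i] for c in "ACGT"]
                               for i in range(mine.width)])
            # Bio.motifs stores integer counts (probabilities x nsites,
            # rounded); agreement to half a count
            assert np.all(np.abs(counts - mine.probabilities * 20) <= 0.51)


@settings(deadline=None, max_examples=30)
@given(st.integers(0, 2 ** 31 - 1), st.integers(1, 4))
def test_motif_file_roundtrip_property(seed, n_motifs):
    dna = make_alphabet("DNA")
    rng = np.random.default_rng(seed)
    motifs = [random_motif(int(rng.integers(1, 12)), dna, rng, name=f"m{i}")
              for i in range(n_motifs)]
    freqs = rng.dirichlet(np.ones(4) * 5)
    freqs = np.maximum(freqs, 1e-3)
    bg = Background(dna, freqs / freqs.sum())
    mf = MotifFile(alphabet=dna, motifs=motifs, background=bg)
    buf = io.StringIO()
    write_meme_motifs(mf, buf)
    again = parse_meme_motifs(buf.getvalue())
    assert [m.name for m in again.motifs] == [m.name for m in motifs]
    for mine, parsed in zip(motifs, again.motifs):
        assert np.allclose(parsed.probabilities, mine.probabilities, atol=2e-6)


class TestTypedMotifs:
    def test_aligned_sites(self, dna):
        (m,) = parse_typed_motifs("ACGT\nACGA", dna)
        assert m.width == 4
        assert m.nsites == 2
        a, t = dna.index("A"), dna.index("T")
        assert m.probabilities[3, a] == pytest.approx(0.5)
        assert m.probabilities[3, t] == pytest.approx(0.5)
        assert np.allclose(m.probabilities[0], [1, 0, 0, 0])

    def test_identical_sites_give_consensus(self, dna):
        motifs = parse_typed_motifs("TTGACA\nTTGACA\nTTGACA", dna)
        assert motifs[0].consensus == "TTGACA"
        assert motifs[0].nsites == 3

    def test_inconsistent_lengths_rejected(self, dna):
        with pytest.raises(ValueError, match="inconsistent lengths"):
            parse_typed_motifs("ACGT\nACG", dna)

    def test_unsupported_character_rejected(self, dna):
        with pytest.raises(ValueError, match="unsupported character"):
            parse_typed_motifs("ACGJ", dna)

    def test_iupac_sites_spread_fractionally(self, dna):
        (m,) = parse_typed_motifs("R", dna)
        assert m.probabilities[0, dna.index("A")] == pytest.approx(0.5)
        assert m.probabilities[0, dna.index("G")] == pytest.approx(0.5)

    def test_numeric_rows_as_letters(self, dna):
        # 4 rows x 6 columns, columns sum to 1 -> rows are letters, width 6
        rows = np.array([
            [0.1, 0.2, 0.7, 0.25, 0.25, 0.4],
            [0.2, 0.3, 0.1, 0.25, 0.25, 0.2],
            [0.3, 0.4, 0.1, 0.25, 0.25, 0.2],
            [0.4, 0.1, 0.1, 0.25, 0.25, 0.2],
        ])
        text = "\n".join(" ".join(f"{x:.3f}" for x in r) for r in rows)
        (m,) = parse_typed_motifs(text, dna)
        assert m.width == 6
        assert np.allclose(m.probabilities, rows.T, atol=1e-9)

    def test_square_tie_prefers_rows_as_positions(self, dna):
        text = "0.7 0.1 0.1 0.1\n0.1 0.7 0.1 0.1\n0.1 0.1 0.7 0.1\n0.1 0.1 0.1 0.7"
        (m,) = parse_typed_motifs(text, dna)
        assert m.width == 4
        assert m.consensus == "ACGT"

    def test_count_matrix_sets_nsites(self, dna):
        (m,) = parse_typed_motifs("5 3 1 1\n8 1 1 0", dna)
        assert m.width == 2
        assert m.nsites == pytest.approx(10.0)
        assert m.probabilities[0, 0] == pytest.approx(0.5)

    def test_blank_line_separates_motifs(self, dna):
        motifs = parse_typed_motifs("ACGT\nACGT\n\nTTTT\nTTTT", dna)
        assert len(motifs) == 2
        assert motifs[1].consensus == "TTTT"
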