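import numpy as np
import pytest

from motifkit import (
    PlantSpec,
    SequenceRecord,
    SequenceSet,
    SiteModel,
    discover_motifs,
    generate_planted_dataset,
    motif_significance,
    run_em,
    seed_starts,
    uniform_background,
)
from motifkit.discover_em import _WindowData, erase_and_repeat

from conftest import column_agreement, word_motif


class TestSeedStarts:
    def test_shared_word_becomes_top_seed(self, dna, uniform_dna_bg):
        word = "TTGACA"
        rng = np.random.default_rng(1)
        letters = np.array(list("ACGT"))
        records = []
        for i in range(5):
            flank = "".join(rng.choice(letters, size=20))
            records.append(SequenceRecord(f"s{i}", flank + word + flank))
        seqs = SequenceSet(dna, tuple(records))
        starts = seed_starts(seqs, 6, 1, uniform_dna_bg)
        assert starts[0].consensus in (word, dna.reverse_complement(word))

    def test_seed_matrices_stay_positive(self, planted_ttgaca, uniform_dna_bg):
        _, seqs, _ = planted_ttgaca
        for start in seed_starts(seqs, 6, 5, uniform_dna_bg):
            assert np.all(start.probabilities > 0)
            assert start.probabilities.max() == pytest.approx(0.7)

    def test_request_beyond_available_truncates(self, dna, uniform_dna_bg):
        seqs = SequenceSet(dna, (SequenceRecord("s", "ACGTACGT"),))
        starts = seed_starts(seqs, 4, 1000, uniform_dna_bg)
        assert len(starts) <= 5  # at most the distinct 4-mers present

    def test_too_wide_rejected(self, dna, uniform_dna_bg):
        seqs = SequenceSet(dna, (SequenceRecord("s", "ACGT"),))
        with pytest.raises(ValueError, match="width"):
            seed_starts(seqs, 10, 1, uniform_dna_bg)


class TestRunEM:
    def test_planted_sites_all_recovered(self, planted_ttgaca, uniform_dna_bg):
        motif, seqs, truth = planted_ttgaca
        (start,) = seed_starts(seqs, 6, 1, uniform_dna_bg)
        fit = run_em(seqs, start, SiteModel("OOPS"), uniform_dna_bg)
        found = {(s.sequence_id, s.offset) for s in fit.sites}
        want = {(t.sequence_id, t.offset) for t in truth}
        assert found == want
        assert column_agreement(fit.motif.consensus, "TTGACA", seqs.alphabet) == 6

    def test_objective_trace_monotone(self, planted_ttgaca, uniform_dna_bg):
        _, seqs, _ = planted_ttgaca
        for start in seed_starts(seqs, 6, 3, uniform_dna_bg):
            fit = run_em(seqs, start, SiteModel("OOPS"), uniform_dna_bg)
            assert np.all(np.diff(fit.trace) >= -1e-9)

    def test_fixed_point_changes_little(self, planted_ttgaca, uniform_dna_bg):
        _, seqs, _ = planted_ttgaca
        (start,) = seed_starts(seqs, 6, 1, uniform_dna_bg)
        fit = run_em(seqs, start, SiteModel("OOPS"), uniform_dna_bg, tol=1e-10)
        again = run_em(seqs, fit.motif, SiteModel("OOPS"), uniform_dna_bg,
                       max_iter=2, tol=1e-10)
        rel_change = abs(again.trace[-1] - again.trace[0]) / abs(again.trace[0])
        assert rel_change < 1e-6

    def test_oops_posteriors_normalize_per_sequence(self, planted_ttgaca,
                                                    uniform_dna_bg):
        _, seqs, _ = planted_ttgaca
        (start,) = seed_starts(seqs, 6, 1, uniform_dna_bg)
        fit = run_em(seqs, start, SiteModel("OOPS"), uniform_dna_bg)
        data = _WindowData(seqs, 6)
        post = fit.window_posteriors.reshape(2, data.n_windows)
        for a, b in data.seq_slices:
            assert post[:, a:b].sum() == pytest.approx(1.0, abs=1e-9)

    def test_zoops_finds_planted_subset(self, dna, uniform_dna_bg):
        """With sites in only half the sequences, ZOOPS recovers every
        planted site; gamma moves off its 0.5 start (its likelihood is
        nearly flat above the true site fraction, so only a lower bound
        is meaningful)."""
        motif = word_motif("TTGACAGG", dna, match=0.98)
        seqs, truth = generate_planted_dataset(
            20, 80, uniform_dna_bg, [PlantSpec(motif, occurrence=0.5)], seed=4
        )
        (start,) = seed_starts(seqs, 8, 1, uniform_dna_bg)
        fit = run_em(seqs, start, SiteModel("ZOOPS", 0.5), uniform_dna_bg)
        assert len(truth) / len(seqs) * 0.8 <= fit.model.gamma <= 1.0
        found = {(s.sequence_id, s.offset) for s in fit.sites}
        assert {(t.sequence_id, t.offset) for t in truth} <= found


class TestSignificance:
    def test_multiplicity_is_linear(self, planted_ttgaca):
        _, seqs, _ = planted_ttgaca
        e1 = motif_significance(30.0, 6, 10, 50, seqs)
        e2 = motif_significance(30.0, 6, 10, 100, seqs)
        assert e2 == pytest.approx(2 * e1)

    def test_background_motif_gets_maximal_evalue(self, planted_ttgaca):
        _, seqs, _ = planted_ttgaca
        assert motif_significance(0.0, 6, 10, 50, seqs) == pytest.approx(50.0)

    def test_monotone_decreasing_in_llr(self, planted_ttgaca):
        _, seqs, _ = planted_ttgaca
        es = [motif_significance(llr, 8, 10, 50, seqs)
              for llr in (0.0, 10.0, 25.0, 50.0)]
        assert all(a >= b for a, b in zip(es, es[1:]))

    def test_planted_beats_background(self, dna, uniform_dna_bg):
        """Same seeds with and without a planted motif: the planted run is
        strictly more significant."""
        motif = word_motif("TTGACAGC", dna, match=0.98)
        planted, _ = generate_planted_dataset(
            20, 100, uniform_dna_bg, [PlantSpec(motif)], seed=11
        )
        plain, _ = generate_planted_dataset(20, 100, uniform_dna_bg, [],
                                            seed=11)
        r1 = discover_motifs(planted, 8, 8, seed=2)
        r0 = discover_motifs(plain, 8, 8, seed=2)
        assert r1.motifs[0].evalue < r0.motifs[0].evalue


class TestEraseAndDiscover:
    def test_zero_posteriors_are_identity(self, planted_ttgaca, uniform_dna_bg):
        _, seqs, _ = planted_ttgaca
        (start,) = seed_starts(seqs, 6, 1, uniform_dna_bg)
        fit = run_em(seqs, start, SiteModel("OOPS"), uniform_dna_bg)
        fit.window_posteriors = np.zeros_like(fit.window_posteriors)
        weights = erase_and_repeat(seqs, fit)
        assert np.allclose(weights, 1.0)

    def test_weights_stay_in_unit_interval(self, planted_ttgaca,
                                           uniform_dna_bg):
        _, seqs, _ = planted_ttgaca
        (start,) = seed_starts(seqs, 6, 1, uniform_dna_bg)
        fit = run_em(seqs, start, SiteModel("OOPS"), uniform_dna_bg)
        weights = erase_and_repeat(seqs, fit)
        assert np.all(weights >= 0.0) and np.all(weights <= 1.0)
        # erased site positions are strongly down-weighted
        assert weights.min() < 0.05

    def test_second_motif_differs_from_first(self, dna, uniform_dna_bg):
        m1 = word_motif("TTGACA", dna, match=0.98)
        m2 = word_motif("GGGCCC", dna, match=0.98)
        seqs, _ = generate_planted_dataset(
            12, 100, uniform_dna_bg, [PlantSpec(m1), PlantSpec(m2)], seed=21
        )
        result = discover_motifs(seqs, 6, 6, n_motifs=2,
                                 model=SiteModel("ZOOPS"), seed=5)
        consensi = {r.consensus for r in result.motifs}
        rc = dna.reverse_complement
        found1 = any(column_agreement(c, "TTGACA", dna) >= 5 for c in consensi)
        found2 = any(column_agreement(c, "GGGCCC", dna) >= 5 for c in consensi)
        assert found1 and found2

    def test_determinism(self, planted_ttgaca):
        _, seqs, _ = planted_ttgaca
        r1 = discover_motifs(seqs, 6, 6, n_motifs=1, seed=9)
        r2 = discover_motifs(seqs, 6, 6, n_motifs=1, seed=9)
        assert np.array_equal(r1.motifs[0].probabilities,
                              r2.motifs[0].probabilities)
        assert r1.motifs[0].evalue == r2.motifs[0].evalue

    def test_invalid_requests_rejected(self, planted_ttgaca):
        _, seqs, _ = planted_ttgaca
        with pytest.raises(ValueError):
            discover_motifs(seqs, 6, 6, n_motifs=0)
        with pytest.raises(ValueError):
            discover_motifs(seqs, 8, 6)
        with pytest.raises(ValueError):
            discover_motifs(seqs, 6, 1000)


def test_strand_symmetry(dna, uniform_dna_bg):
    """Discovery on the reverse-complemented set yields the
    reverse-complemented motif."""
    motif = word_motif("TTGACA", dna, match=0.98)
    seqs, _ = generate_planted_dataset(10, 100, uniform_dna_bg,
                                       [PlantSpec(motif)], seed=77)
    rc_seqs = SequenceSet(
        dna,
        tuple(SequenceRecord(r.identifier,
                             dna.reverse_complement(r.residues))
              for r in seqs),
    )
    r1 = discover_motifs(seqs, 6, 6, seed=5)
    r2 = discover_motifs(rc_seqs, 6, 6, seed=5)
    assert np.allclose(
        r1.motifs[0].probabilities,
        r2.motifs[0].reverse_complement().probabilities,
        atol=1e-6,
    )


def test_protein_discovery_single_strand(protein):
    """Case-study-style protein block: OOPS recovery of an 11-wide block."""
    bg = uniform_background(protein)
    block = word_motif("DERILKQLEWK", protein, match=0.9)
    seqs, truth = generate_planted_dataset(
        5, 100, bg, [PlantSpec(block, mutation_rate=0.1)], seed=13
    )
    result = discover_motifs(seqs, 11, 11, model=SiteModel("OOPS"), seed=1)
    agree = column_agreement(result.motifs[0].consensus, "DERILKQLEWK")
    assert agree >= 9
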