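"""Occurrence-level motif scanning with exact p-values and BH q-values.

Window scores are integerized log-odds sums; their exact null distribution
under the zero-order background is computed by a position-wise convolution
(dynamic program over positions x integer scores), so every reported
p-value is exact up to quantization rather than asymptotic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    Background,
    LogOddsMatrix,
    Motif,
    SequenceSet,
    motif_to_logodds,
)

__all__ = [
    "ScoreDistribution",
    "MotifHit",
    "score_pvalue_table",
    "scan",
    "bh_qvalues",
    "window_integer_scores",
]

DEFAULT_P_THRESHOLD = 1e-4


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact null distribution of the integerized window score.

    ``pmf[s]`` is the probability that a background word of the motif's
    width attains total integer score ``s``; ``sf[s] = P(score >= s)`` is
    the p-value of integer score ``s``.
    """

    lom: LogOddsMatrix
    pmf: np.ndarray
    sf: np.ndarray

    def pvalue(self, integer_score: int | np.ndarray) -> np.ndarray:
        s = np.clip(integer_score, 0, len(self.sf) - 1)
        return self.sf[s]

    @property
    def min_pvalue(self) -> float:
        return float(self.sf[-1]) if self.pmf[-1] > 0 else float(
            self.sf[np.flatnonzero(self.pmf)[-1]]
        )


def score_pvalue_table(lom: LogOddsMatrix, background: Background | None = None
                       ) -> ScoreDistribution:
    """Exact pmf and right tail of the integer window score under the background.

    The DP convolves, position by position, the per-letter integer-score
    distribution weighted by background frequency; cost O(w^2 * bins).
    """
    if background is None:
        background = lom.background
    alph = lom.motif.alphabet
    ints = lom.integer_scores[:, : alph.size]
    freqs = background.frequencies
    max_total = int(ints.max(axis=1).sum())
    pmf = np.zeros(max_total + 1)
    pmf[0] = 1.0
    top = 0
    for i in range(lom.width):
        row_max = int(ints[i].max())
        new = np.zeros(top + row_max + 1)
        for a in range(alph.size):
            s = int(ints[i, a])
            new[s : s + top + 1] += freqs[a] * pmf[: top + 1]
        top += row_max
        pmf = np.zeros(max_total + 1)
        pmf[: top + 1] = new
    sf = np.minimum(np.cumsum(pmf[::-1])[::-1], 1.0)
    return ScoreDistribution(lom=lom, pmf=pmf, sf=sf)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence: 1-based inclusive forward-strand coordinates,
    score in bits, exact p-value and BH q-value."""

    motif_name: str
    sequence_id: str
    start: int
    stop: int
    strand: str
    score: float
    p_value: float
    q_value: float
    matched_sequence: str


def window_integer_scores(lom: LogOddsMatrix, encoded: np.ndarray) -> np.ndarray:
    """Total integer score of every window of an encoded sequence."""
    w = lom.width
    n_windows = len(encoded) - w + 1
    if n_windows <= 0:
        return np.zeros(0, dtype=np.int64)
    idx = np.arange(n_windows)[:, None] + np.arange(w)[None, :]
    return lom.integer_scores[np.arange(w)[None, :], encoded[idx]].sum(axis=1)


def scan(
    motifs: list[Motif] | Motif,
    seqs: SequenceSet,
    background: Background | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    both_strands: bool = True,
    skip_masked: bool = False,
    quantization_bins: int = 1000,
    motif_pseudocount: float = 0.1,
) -> list[MotifHit]:
    """Score every window of every sequence against every motif.

    Windows with exact p-value <= ``p_threshold`` are reported as hits.
    For nucleotide alphabets both strands are scanned by default; a minus
    strand match is reported in forward coordinates with its matched text
    reverse-complemented.  Each scored window (on each strand) counts as
    one test for the q-value computation, whether or not it was emitted.
    ``skip_masked`` drops windows with more than 50% wildcard letters.
    ``motif_pseudocount`` background-proportional pseudocounts are blended
    into each motif before log-odds conversion so matrices containing
    zeros (e.g. typed from aligned sites) remain scannable.
    """
    if isinstance(motifs, Motif):
        motifs = [motifs]
    if not motifs:
        return []
    alph = seqs.alphabet
    for m in motifs:
        if m.alphabet.is_nucleotide != alph.is_nucleotide:
            raise ValueError(
                f"motif {m.name!r} ({m.alphabet.name}) cannot scan "
                f"{alph.name} sequences"
            )
    from .core import uniform_background

    if background is None:
        background = uniform_background(alph)
    both = both_strands and alph.is_nucleotide
    wildcard_idx = alph.index(alph.wildcard)

    raw_hits: list[tuple] = []
    pvals: list[float] = []
    n_tests = 0
    encoded = {rec.identifier: alph.encode(rec.residues) for rec in seqs}

    from .core import with_pseudocounts

    for motif in motifs:
        padded = with_pseudocounts(motif, background, motif_pseudocount)
        strand_tables = [("+", motif_to_logodds(padded, background, quantization_bins))]
        if both:
            strand_tables.append(
                ("-", motif_to_logodds(padded.reverse_complement(), background,
                                       quantization_bins))
            )
        tables = [(s, lom, score_pvalue_table(lom)) for s, lom in strand_tables]
        w = motif.width
        for rec in seqs:
            enc = encoded[rec.identifier]
            if len(enc) < w:
                continue
            keep = None
            if skip_masked:
                is_wild = (enc == wildcard_idx).astype(np.int64)
                cum = np.concatenate([[0], np.cumsum(is_wild)])
                frac = (cum[w:] - cum[:-w]) / w
                keep = frac <= 0.5
            for strand, lom, table in tables:
                scores = window_integer_scores(lom, enc)
                if keep is not None:
                    mask = keep
                else:
                    mask = np.ones(len(scores), dtype=bool)
                n_tests += int(mask.sum())
                ps = table.pvalue(scores)
                sel = np.flatnonzero((ps <= p_threshold) & mask)
                for j in sel:
                    start = int(j) + 1
                    stop = start + w - 1
                    text = rec.residues[j : j + w]
                    if strand == "-":
                        text = alph.reverse_complement(text)
                    raw_hits.append(
                        (motif.name, rec.identifier, start, stop, strand,
                         lom.bits_from_integer(int(scores[j])), float(ps[j]), text)
                    )
                    pvals.append(float(ps[j]))

    qvals = bh_qvalues(pvals, m=max(n_tests, len(pvals))) if pvals else []
    hits = [
        MotifHit(motif_name=h[0], sequence_id=h[1], start=h[2], stop=h[3],
                 strand=h[4], score=h[5], p_value=h[6], q_value=q,
                 matched_sequence=h[7])
        for h, q in zip(raw_hits, qvals)
    ]
    hits.sort(key=lambda h: (h.p_value, h.motif_name, h.sequence_id, h.start, h.strand))
    return hits


def bh_qvalues(p_values, m: int | None = None) -> list[float]:
    """Benjamini–Hochberg step-up q-values.

    ``m`` is the total number of tests performed, which may exceed the
    number of p-values supplied (tests below a reporting threshold are
    still tests).  q(i) = min_{j >= i} (p(j) * m / j) over p sorted
    ascending, clipped at 1, returned in input order.
    """
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        return []
    if np.any((ps <= 0) | (ps > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = ps.size
    if m < ps.size:
        raise ValueError("m must be at least the number of p-values")
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, ps.size + 1)
    qs = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.minimum(qs, 1.0)
    out = np.empty_like(qs)
    out[order] = qs
    return out.tolist()
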