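"""Sequence-level multi-motif scoring with combined p-values.

Each sequence gets, per motif, the best window p-value corrected for the
number of windows scanned (distribution of the minimum of n uniforms);
the per-motif p-values are then combined with the exact tail of a product
of independent uniforms.  Sequences are ranked by E-value = combined p
times the number of sequences scanned.  Block diagrams summarize the
non-overlapping significant sites of a sequence, with display heights
proportional to -log10(p) and truncated at the 1e-10 level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .core import Background, Motif, SequenceSet, motif_to_logodds, uniform_background, with_pseudocounts
from .scan import MotifHit, score_pvalue_table, window_integer_scores

__all__ = [
    "SequenceMatch",
    "DiagramBlock",
    "best_hit_pvalues",
    "combine_pvalues",
    "rank_sequences",
    "diagram_blocks",
    "render_diagram",
]

DIAGRAM_P_THRESHOLD = 1e-4    # report non-overlapping sites below this p
DIAGRAM_HEIGHT_CAP_P = 1e-10  # heights truncate at the p = 1e-10 level


@dataclass(frozen=True)
class DiagramBlock:
    motif_name: str
    motif_index: int            # 1-based index into the scanned motif list
    start: int                  # 1-based forward-strand start
    stop: int
    strand: str
    p_value: float
    height: float               # -log10(p), capped


@dataclass(frozen=True)
class SequenceMatch:
    sequence_id: str
    motif_pvalues: tuple[float, ...]
    combined_pvalue: float
    e_value: float
    blocks: tuple[DiagramBlock, ...] = ()
    warnings: tuple[str, ...] = ()


def best_hit_pvalues(
    motifs: list[Motif],
    residues: str,
    alphabet,
    background: Background | None = None,
    both_strands: bool = True,
    motif_pseudocount: float = 0.1,
    _tables=None,
) -> tuple[list[float], list[str]]:
    """Per-motif sequence-level p-values for one sequence.

    For each motif the minimum window p-value p_min over all positions and
    strands is corrected for multiplicity: p_seq = 1 - (1 - p_min)^n with
    n the number of windows tested (both strands pooled).  A motif wider
    than the sequence contributes p = 1 with a warning record.
    """
    if background is None:
        background = uniform_background(alphabet)
    tables = _tables if _tables is not None else _motif_tables(
        motifs, alphabet, background, both_strands, motif_pseudocount
    )
    enc = alphabet.encode(residues)
    pvals, warnings = [], []
    for motif, strand_tables in zip(motifs, tables):
        if motif.width > len(enc):
            pvals.append(1.0)
            warnings.append(
                f"motif {motif.name!r} (w={motif.width}) is wider than the "
                f"sequence ({len(enc)} letters); contributes p = 1"
            )
            continue
        p_min = 1.0
        n_windows = 0
        for _, lom, table in strand_tables:
            scores = window_integer_scores(lom, enc)
            n_windows += len(scores)
            p_min = min(p_min, float(table.pvalue(scores).min()))
        pvals.append(_min_uniform_correction(p_min, n_windows))
    return pvals, warnings


def _min_uniform_correction(p_min: float, n: int) -> float:
    """P(min of n independent uniforms <= p_min) = 1 - (1 - p_min)^n."""
    if p_min >= 1.0:
        return 1.0
    return float(min(1.0, -math.expm1(n * math.log1p(-p_min))))


def _motif_tables(motifs, alphabet, background, both_strands, motif_pseudocount):
    tables = []
    both = both_strands and alphabet.is_nucleotide
    for motif in motifs:
        padded = with_pseudocounts(motif, background, motif_pseudocount)
        per_strand = []
        for strand, m in (("+", padded),) + (
            (("-", padded.reverse_complement()),) if both else ()
        ):
            lom = motif_to_logodds(m, background)
            per_strand.append((strand, lom, score_pvalue_table(lom)))
        tables.append(per_strand)
    return tables


def combine_pvalues(p_list) -> float:
    """Exact tail probability of a product of independent uniforms.

    With x = prod(p_i) over n p-values, returns
    P(prod U_i <= x) = x * sum_{k=0}^{n-1} (-ln x)^k / k!,
    computed in log space for numerical safety.
    """
    ps = list(p_list)
    if not ps:
        raise ValueError("cannot combine an empty p-value list")
    for p in ps:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-value {p!r} outside (0, 1]")
    log_x = sum(math.log(p) for p in ps)
    if log_x == 0.0:
        return 1.0
    n = len(ps)
    t = math.log(-log_x)
    log_terms = [k * t - gammaln(k + 1) for k in range(n)]
    return float(min(1.0, math.exp(log_x + logsumexp(log_terms))))


def rank_sequences(
    motifs: list[Motif],
    seqs: SequenceSet,
    background: Background | None = None,
    both_strands: bool = True,
    with_blocks: bool = True,
    diagram_threshold: float = DIAGRAM_P_THRESHOLD,
    motif_pseudocount: float = 0.1,
) -> list[SequenceMatch]:
    """Score every sequence against all motifs; rank by E-value ascending.

    E-value = combined p-value x number of sequences scanned.  Ties are
    broken by sequence identifier, so the ranking is a pure function of
    the input content.
    """
    if not motifs or len(seqs) == 0:
        raise ValueError("need at least one motif and one sequence")
    alph = seqs.alphabet
    if background is None:
        background = uniform_background(alph)
    tables = _motif_tables(motifs, alph, background, both_strands and
                           alph.is_nucleotide, motif_pseudocount)
    n_seqs = len(seqs)
    matches = []
    for rec in seqs:
        pvals, warnings = best_hit_pvalues(
            motifs, rec.residues, alph, background,
            both_strands=both_strands, _tables=tables,
        )
        combined = combine_pvalues(pvals)
        blocks: tuple[DiagramBlock, ...] = ()
        if with_blocks:
            hits = _sequence_hits(motifs, tables, rec, alph, diagram_threshold)
            blocks = tuple(diagram_blocks(hits, p_threshold=diagram_threshold))
        matches.append(
            SequenceMatch(
                sequence_id=rec.identifier,
                motif_pvalues=tuple(pvals),
                combined_pvalue=combined,
                e_value=min(combined * n_seqs, float(n_seqs)),
                blocks=blocks,
                warnings=tuple(warnings),
            )
        )
    matches.sort(key=lambda m: (m.e_value, m.sequence_id))
    return matches


def _sequence_hits(motifs, tables, rec, alphabet, p_threshold):
    """Window hits for one sequence as (motif_index, MotifHit-like tuples)."""
    enc = alphabet.encode(rec.residues)
    hits = []
    for mi, (motif, strand_tables) in enumerate(zip(motifs, tables), start=1):
        if motif.width > len(enc):
            continue
        for strand, lom, table in strand_tables:
            scores = window_integer_scores(lom, enc)
            ps = table.pvalue(scores)
            for j in np.flatnonzero(ps < p_threshold):
                hits.append(
                    (motif.name, mi, int(j) + 1, int(j) + motif.width,
                     strand, float(ps[j]))
                )
    return hits


def diagram_blocks(hits, p_threshold: float = DIAGRAM_P_THRESHOLD) -> list[DiagramBlock]:
    """Greedy best-p-first selection of non-overlapping sites.

    ``hits`` are (motif_name, motif_index, start, stop, strand, p) tuples
    or MotifHit objects for a single sequence.  Display height is
    -log10(p) truncated at the p = 1e-10 level.
    """
    norm = []
    for h in hits:
        if isinstance(h, MotifHit):
            norm.append((h.motif_name, 0, h.start, h.stop, h.strand, h.p_value))
        else:
            norm.append(tuple(h))
    norm = [h for h in norm if h[5] < p_threshold]
    norm.sort(key=lambda h: (h[5], h[2], h[1], h[4]))
    chosen: list[tuple] = []
    covered: list[tuple[int, int]] = []
    for h in norm:
        start, stop = h[2], h[3]
        if any(start <= c_stop and stop >= c_start for c_start, c_stop in covered):
            continue
        chosen.append(h)
        covered.append((start, stop))
    cap = -math.log10(DIAGRAM_HEIGHT_CAP_P)
    chosen.sort(key=lambda h: h[2])
    return [
        DiagramBlock(
            motif_name=h[0], motif_index=h[1], start=h[2], stop=h[3],
            strand=h[4], p_value=h[5],
            height=min(-math.log10(h[5]), cap),
        )
        for h in chosen
    ]


def render_diagram(blocks, sequence_length: int) -> str:
    """Text block diagram like ``23-[+1]-50-[-2]-10``: gap lengths between
    signed motif indices along the sequence."""
    parts = []
    pos = 1
    for b in blocks:
        gap = b.start - pos
        if gap > 0:
            parts.append(str(gap))
        sign = "-" if b.strand == "-" else "+"
        parts.append(f"[{sign}{b.motif_index}]")
        pos = b.stop + 1
    tail = sequence_length - pos + 1
    if tail > 0:
        parts.append(str(tail))
    return "-".join(parts) if parts else str(sequence_length)
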