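"""Motif-motif comparison by optimal ungapped alignment.

A query motif is slid over each target at every offset (and, for
nucleotides, against the target's reverse complement); the alignment
score sums per-column similarities over the overlap, with non-overlapping
query columns contributing the metric's null value so that one-column
overlaps cannot win trivially.  Match significance comes from a
Monte-Carlo null: the best-alignment score of the query against
column-shuffled versions of the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Background, Motif, uniform_background

__all__ = [
    "MotifAlignment",
    "column_similarity",
    "best_alignment",
    "compare_to_database",
    "render_alignment",
]

DEFAULT_MIN_OVERLAP = 4
DEFAULT_N_SHUFFLES = 1000


@dataclass(frozen=True)
class MotifAlignment:
    query_name: str
    target_name: str
    offset: int          # target column index of query column 1 (may be < 0)
    orientation: str     # "+" forward, "-" reverse complement of the target
    overlap: int
    score: float
    p_value: float
    e_value: float


def column_similarity(q_col, t_col, metric: str = "pearson") -> float:
    """Similarity of two probability columns.

    ``pearson``: correlation of the two vectors (0 if either is constant);
    ``neg_euclid``: negative Euclidean distance (0 is the maximum).
    """
    q = np.asarray(q_col, dtype=float)
    t = np.asarray(t_col, dtype=float)
    if q.shape != t.shape:
        raise ValueError(f"column shapes differ: {q.shape} vs {t.shape}")
    if metric == "pearson":
        qc, tc = q - q.mean(), t - t.mean()
        denom = np.linalg.norm(qc) * np.linalg.norm(tc)
        if denom == 0:
            return 0.0
        return float(np.dot(qc, tc) / denom)
    if metric == "neg_euclid":
        return float(-np.linalg.norm(q - t))
    raise ValueError(f"unknown metric {metric!r}")


def _similarity_matrix(query: Motif, target_probs: np.ndarray,
                       metric: str) -> np.ndarray:
    """All pairwise column similarities, query columns x target columns."""
    Q = query.probabilities
    T = target_probs
    if metric == "pearson":
        qc = Q - Q.mean(axis=1, keepdims=True)
        tc = T - T.mean(axis=1, keepdims=True)
        qn = np.linalg.norm(qc, axis=1)
        tn = np.linalg.norm(tc, axis=1)
        denom = np.outer(qn, tn)
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = (qc @ tc.T) / denom
        return np.where(denom > 0, sim, 0.0)
    if metric == "neg_euclid":
        d2 = (
            (Q ** 2).sum(axis=1)[:, None]
            + (T ** 2).sum(axis=1)[None, :]
            - 2.0 * (Q @ T.T)
        )
        return -np.sqrt(np.maximum(d2, 0.0))
    raise ValueError(f"unknown metric {metric!r}")


def _null_column_value(query: Motif, metric: str,
                       background: Background) -> np.ndarray:
    """Score contributed by each unaligned query column: the metric's null
    value (0 for pearson; minus the distance to the background column for
    neg_euclid)."""
    if metric == "pearson":
        return np.zeros(query.width)
    return -np.linalg.norm(
        query.probabilities - background.frequencies[None, :], axis=1
    )


def _offset_scores(sim: np.ndarray, null_vals: np.ndarray,
                   min_overlap: int) -> list[tuple[int, int, float]]:
    """(offset, overlap, score) for every admissible offset of one
    orientation.  Offset d aligns query column i with target column i + d."""
    qw, tw = sim.shape
    out = []
    lo = min_overlap - qw          # rightmost query col must reach target
    hi = tw - min_overlap
    base = float(null_vals.sum())
    for d in range(lo, hi + 1):
        i0 = max(0, -d)
        i1 = min(qw, tw - d)
        if i1 - i0 < min_overlap:
            continue
        i = np.arange(i0, i1)
        score = base - float(null_vals[i].sum()) + float(sim[i, i + d].sum())
        out.append((d, i1 - i0, score))
    return out


def best_alignment(
    query: Motif,
    target: Motif,
    metric: str = "pearson",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    try_rc: bool | None = None,
    background: Background | None = None,
) -> tuple[int, str, float]:
    """Exhaustive search over offsets and orientations.

    Returns (offset, orientation, score) with ties broken toward larger
    overlap, then smaller absolute offset, then the forward orientation.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be at least 1")
    if query.alphabet.name != target.alphabet.name:
        raise ValueError(
            f"alphabet mismatch: {query.alphabet.name} vs {target.alphabet.name}"
        )
    if background is None:
        background = uniform_background(query.alphabet)
    if try_rc is None:
        try_rc = query.alphabet.is_nucleotide
    null_vals = _null_column_value(query, metric, background)
    candidates = []
    orientations = [("+", target.probabilities)]
    if try_rc:
        orientations.append(("-", target.reverse_complement().probabilities))
    for orient, t_probs in orientations:
        sim = _similarity_matrix(query, t_probs, metric)
        for d, ov, score in _offset_scores(sim, null_vals, min_overlap):
            candidates.append((score, ov, -abs(d), orient == "+", d, orient))
    if not candidates:
        raise ValueError(
            f"no admissible offsets: min_overlap={min_overlap} exceeds "
            f"min(query, target) width"
        )
    best = max(candidates, key=lambda c: c[:4])
    return best[4], best[5], best[0]


def compare_to_database(
    query: Motif,
    targets: list[Motif],
    metric: str = "pearson",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    seed: int = 0,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    background: Background | None = None,
    try_rc: bool | None = None,
) -> list[MotifAlignment]:
    """Align the query with every target and rank matches by p-value.

    The p-value of a target's best-alignment score is estimated against
    ``n_shuffles`` column-permuted versions of that target:
    p = (1 + #{null >= observed}) / (n_shuffles + 1).  E-value = p times
    the database size.  Deterministic given ``seed``.
    """
    if not targets:
        raise ValueError("the target database is empty")
    if background is None:
        background = uniform_background(query.alphabet)
    if try_rc is None:
        try_rc = query.alphabet.is_nucleotide
    rng = np.random.default_rng(seed)
    results = []
    for target in targets:
        offset, orient, score = best_alignment(
            query, target, metric, min_overlap, try_rc, background
        )
        i = np.arange(max(0, -offset), min(query.width, target.width - offset))
        null_scores = _null_best_scores(
            query, target, metric, min_overlap, try_rc, background,
            rng, n_shuffles,
        )
        p = float((1 + int((null_scores >= score - 1e-12).sum()))
                  / (n_shuffles + 1))
        results.append(
            MotifAlignment(
                query_name=query.name, target_name=target.name,
                offset=offset, orientation=orient, overlap=len(i),
                score=score, p_value=p, e_value=min(p * len(targets),
                                                    float(len(targets))),
            )
        )
    results.sort(key=lambda r: (r.p_value, -r.score, r.target_name))
    return results


def _null_best_scores(query, target, metric, min_overlap, try_rc,
                      background, rng, n_shuffles) -> np.ndarray:
    """Best-alignment scores of the query against column-shuffled targets.

    Shuffling the target's columns permutes the columns of the
    query-target similarity matrix, so the null scores are computed by
    re-reading one precomputed matrix under many permutations.
    """
    null_vals = _null_column_value(query, metric, background)
    sims = [_similarity_matrix(query, target.probabilities, metric)]
    if try_rc:
        sims.append(
            _similarity_matrix(query, target.reverse_complement().probabilities,
                               metric)
        )
    tw = target.width
    perms = np.stack([rng.permutation(tw) for _ in range(n_shuffles)])
    best = np.full(n_shuffles, -np.inf)
    base = float(null_vals.sum())
    qw = query.width
    for sim in sims:
        # a column shuffle of the target applied to the rc orientation is
        # itself a (reversed) column shuffle; reuse the same permutations
        shuffled = sim[:, perms]            # qw x n_shuffles x tw
        for d in range(min_overlap - qw, tw - min_overlap + 1):
            i0, i1 = max(0, -d), min(qw, tw - d)
            if i1 - i0 < min_overlap:
                continue
            i = np.arange(i0, i1)
            scores = (
                base
                - null_vals[i].sum()
                + shuffled[i, :, i + d].sum(axis=0)
            )
            np.maximum(best, scores, out=best)
    return best


def render_alignment(query: Motif, target: Motif, offset: int,
                     orientation: str) -> str:
    """Two-line consensus rendering of an alignment, query under target."""
    t = target if orientation == "+" else target.reverse_complement()
    pad_t = max(0, -offset)
    pad_q = max(0, offset)
    top = " " * pad_t + t.consensus
    bottom = " " * pad_q + query.consensus
    label = f"{target.name} ({orientation})"
    return f"{label}\n{top}\n{bottom}\n{query.name}"
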