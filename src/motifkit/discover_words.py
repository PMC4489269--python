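"""Discriminative discovery of short nucleotide motifs by word enumeration.

Exact words of length ``min_k..max_k`` present in the positive sequences
are scored against a negative (control) set with a one-sided Fisher exact
test on sequence-level presence counts; the best word is greedily
generalized one IUPAC position at a time while the p-value improves.
Accepted words are converted to probability-matrix motifs from their
matching sites and masked out before the next round.  When no negative
set is given, a per-sequence dinucleotide-preserving shuffle of the
positives serves as the control.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .core import Motif, SequenceRecord, SequenceSet

__all__ = [
    "WordCandidate",
    "shuffle_control",
    "count_sequences_with_word",
    "fisher_right_tail",
    "discover_words",
]

DEFAULT_MIN_K = 3
DEFAULT_MAX_K = 8


@dataclass(frozen=True)
class WordCandidate:
    word: str
    positives_with: int
    positives_total: int
    negatives_with: int
    negatives_total: int
    p_value: float
    e_value: float
    n_words_tested: int

    def __post_init__(self):
        if not (0 <= self.positives_with <= self.positives_total):
            raise ValueError("positive counts out of range")
        if not (0 <= self.negatives_with <= self.negatives_total):
            raise ValueError("negative counts out of range")


def shuffle_control(seqs: SequenceSet, seed: int = 0) -> SequenceSet:
    """Per-sequence dinucleotide-preserving (Eulerian) shuffle.

    Each output sequence has exactly the dinucleotide multiset of its
    source (Altschul–Erickson construction: sample a uniform random
    Eulerian path in the dinucleotide transition multigraph).
    Deterministic given ``seed``.
    """
    if not seqs.alphabet.is_nucleotide:
        raise ValueError("the shuffle control is defined for nucleotide sequences")
    rng = np.random.default_rng(seed)
    records = []
    for rec in seqs:
        records.append(
            SequenceRecord(rec.identifier, _euler_shuffle(rec.residues, rng),
                           rec.description)
        )
    return SequenceSet(seqs.alphabet, tuple(records))


def _euler_shuffle(s: str, rng: np.random.Generator) -> str:
    if len(s) < 3:
        return s
    # multigraph: vertices are letters, edges the observed dinucleotides
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    last = s[-1]
    vertices = list(edges.keys())
    # Altschul–Erickson: pick one last out-edge per vertex (except the final
    # vertex) so that the chosen edges form a tree pointing at the final
    # vertex, then randomize the order of the remaining edges.
    for _ in range(1000):
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        if _reaches_last(last_edge, vertices, last):
            break
    else:  # no admissible tree found (should not happen for a real walk)
        return s
    shuffled = {}
    for v in vertices:
        pool = list(edges[v])
        if v in last_edge:
            pool.remove(last_edge[v])
        order = rng.permutation(len(pool))
        seq = [pool[i] for i in order]
        if v in last_edge:
            seq.append(last_edge[v])
        shuffled[v] = seq
    out = [s[0]]
    ptr = {v: 0 for v in vertices}
    v = s[0]
    for _ in range(len(s) - 1):
        nxt = shuffled[v][ptr[v]]
        ptr[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


def _reaches_last(last_edge: dict[str, str], vertices: list[str], last: str) -> bool:
    for v in vertices:
        if v == last:
            continue
        seen = set()
        cur = v
        while cur != last:
            if cur in seen or cur not in last_edge:
                return False
            seen.add(cur)
            cur = last_edge[cur]
    return True


def _word_regex(word: str, alphabet) -> re.Pattern:
    parts = []
    for letter in word:
        exp = alphabet.expand(letter)
        parts.append(exp if len(exp) == 1 else f"[{exp}]")
    return re.compile("".join(parts))


def count_sequences_with_word(
    word: str, seqs: SequenceSet, both_strands: bool = True
) -> int:
    """Number of sequences containing at least one match to the IUPAC word
    (on either strand when ``both_strands``)."""
    alph = seqs.alphabet
    pattern = _word_regex(word, alph)
    rc_pattern = None
    if both_strands and alph.is_nucleotide:
        rc = alph.reverse_complement(word)
        if rc != word:
            rc_pattern = _word_regex(rc, alph)
    n = 0
    for rec in seqs:
        if pattern.search(rec.residues) or (
            rc_pattern and rc_pattern.search(rec.residues)
        ):
            n += 1
    return n


def fisher_right_tail(a: int, A: int, b: int, B: int) -> float:
    """One-sided (right tail) hypergeometric p-value.

    Probability of observing >= ``a`` positive sequences with the word,
    given ``A`` positives, ``B`` negatives and ``a + b`` sequences with
    the word in total.
    """
    if not (0 <= a <= A and 0 <= b <= B):
        raise ValueError("need 0 <= a <= A and 0 <= b <= B")
    return float(min(1.0, hypergeom.sf(a - 1, A + B, a + b, A)))


_GENERALIZATIONS = {
    # single-letter relaxations explored by the greedy IUPAC search
    "A": ["R", "W", "M", "D", "H", "V", "N"],
    "C": ["Y", "S", "M", "B", "H", "V", "N"],
    "G": ["R", "S", "K", "B", "D", "V", "N"],
    "T": ["Y", "W", "K", "B", "D", "H", "N"],
    "U": ["Y", "W", "K", "B", "D", "H", "N"],
    "R": ["D", "V", "N"], "Y": ["B", "H", "N"], "S": ["B", "V", "N"],
    "W": ["D", "H", "N"], "K": ["B", "D", "N"], "M": ["H", "V", "N"],
    "B": ["N"], "D": ["N"], "H": ["N"], "V": ["N"], "N": [],
}


def discover_words(
    positives: SequenceSet,
    negatives: SequenceSet | None = None,
    min_k: int = DEFAULT_MIN_K,
    max_k: int = DEFAULT_MAX_K,
    e_threshold: float = 0.05,
    n_motifs: int = 10,
    seed: int = 0,
    both_strands: bool = True,
) -> list[tuple[WordCandidate, Motif]]:
    """Enumerate, test, generalize, mask, repeat.

    Returns up to ``n_motifs`` (candidate, motif) pairs with
    ``e_value <= e_threshold``, in discovery order.  The E-value is the
    Fisher p-value Bonferroni-corrected by the number of words actually
    tested (exact words plus IUPAC variants).
    """
    if not positives.alphabet.is_nucleotide:
        raise ValueError("word discovery is nucleotide-only")
    if min_k > max_k:
        raise ValueError("min_k must not exceed max_k")
    if n_motifs <= 0:
        return []
    if negatives is None:
        negatives = shuffle_control(positives, seed=seed)
    alph = positives.alphabet

    pos_seqs = [rec.residues for rec in positives]
    neg_seqs = [rec.residues for rec in negatives]
    results: list[tuple[WordCandidate, Motif]] = []
    words_tested = 0
    neg_counts = _exact_word_counts(neg_seqs, alph, min_k, max_k, both_strands)

    def neg_count(word: str) -> int:
        # exact core-letter words come from the precomputed table; IUPAC
        # generalizations need a scan
        if set(word) <= set(alph.core_symbols):
            return neg_counts.get(_canonical(word, alph, both_strands), 0)
        return _count_with(word, neg_seqs, alph, both_strands)

    for _ in range(n_motifs):
        counts = _exact_word_counts(pos_seqs, alph, min_k, max_k, both_strands)
        if not counts:
            break
        A, B = len(pos_seqs), len(neg_seqs)
        words = sorted(counts)
        a_arr = np.array([counts[w] for w in words])
        b_arr = np.array([neg_counts.get(w, 0) for w in words])
        p_arr = np.minimum(1.0, hypergeom.sf(a_arr - 1, A + B, a_arr + b_arr, A))
        words_tested += len(words)
        pick = int(np.argmin(p_arr))   # first index on ties: smallest word
        best_word, best_p = words[pick], float(p_arr[pick])
        # greedy single-position IUPAC generalization
        improved = True
        while improved:
            improved = False
            for i, letter in enumerate(best_word):
                for relax in _GENERALIZATIONS[letter]:
                    cand = best_word[:i] + relax + best_word[i + 1:]
                    words_tested += 1
                    p = fisher_right_tail(
                        _count_with(cand, pos_seqs, alph, both_strands), A,
                        neg_count(cand), B,
                    )
                    if p < best_p:
                        best_word, best_p = cand, p
                        improved = True
        e_value = best_p * words_tested
        if e_value > e_threshold:
            break
        candidate = WordCandidate(
            word=best_word,
            positives_with=_count_with(best_word, pos_seqs, alph, both_strands),
            positives_total=A,
            negatives_with=neg_count(best_word),
            negatives_total=B,
            p_value=best_p,
            e_value=e_value,
            n_words_tested=words_tested,
        )
        motif, pos_seqs = _word_to_motif_and_mask(
            best_word, pos_seqs, alph, both_strands,
            name=f"word-{len(results) + 1}", evalue=e_value,
        )
        results.append((candidate, motif))
    return results


def _canonical(word: str, alph, both_strands: bool) -> str:
    """Canonical orientation: the lexicographically smaller of the word and
    its reverse complement, so a word and its complement are one test."""
    if not both_strands:
        return word
    rc = alph.reverse_complement(word)
    return word if word <= rc else rc


def _exact_word_counts(seqs, alph, min_k, max_k, both_strands):
    """Sequence-level presence counts of every exact core-letter word."""
    core = set(alph.core_symbols)
    counts: dict[str, int] = {}
    for s in seqs:
        present = set()
        for k in range(min_k, max_k + 1):
            for i in range(len(s) - k + 1):
                w = s[i : i + k]
                if set(w) <= core:
                    present.add(w)
        if both_strands:
            present |= {alph.reverse_complement(w) for w in present}
        # canonical orientation so a word and its complement are one test
        for w in present:
            if not both_strands or w <= alph.reverse_complement(w):
                counts[w] = counts.get(w, 0) + 1
    return counts


def _count_with(word, seqs, alph, both_strands):
    pattern = _word_regex(word, alph)
    rc_pattern = None
    if both_strands:
        rc = alph.reverse_complement(word)
        if rc != word:
            rc_pattern = _word_regex(rc, alph)
    n = 0
    for s in seqs:
        if pattern.search(s) or (rc_pattern and rc_pattern.search(s)):
            n += 1
    return n


def _word_to_motif_and_mask(word, seqs, alph, both_strands, name, evalue):
    """Build a count-matrix motif from all matches of ``word`` and return
    the sequences with those matches masked to the wildcard."""
    k = len(word)
    patterns = [_word_regex(word, alph)]
    rc = alph.reverse_complement(word) if both_strands else word
    if both_strands and rc != word:
        patterns.append(_word_regex(rc, alph))
    counts = np.zeros((k, alph.size))
    masked = []
    nsites = 0
    for s in seqs:
        chars = list(s)
        for pi, pattern in enumerate(patterns):
            for m in pattern.finditer(s):
                site = m.group(0)
                if pi == 1:
                    site = alph.reverse_complement(site)
                for i, letter in enumerate(site):
                    exp = alph.expand(letter)
                    for c in exp:
                        counts[i, alph.index(c)] += 1.0 / len(exp)
                nsites += 1
                chars[m.start(): m.end()] = alph.wildcard * k
        masked.append("".join(chars))
    if nsites == 0:  # degenerate: fall back to the word's own letter sets
        for i, letter in enumerate(word):
            exp = alph.expand(letter)
            for c in exp:
                counts[i, alph.index(c)] += 1.0 / len(exp)
        nsites = 1
    probs = counts / counts.sum(axis=1, keepdims=True)
    motif = Motif(name=name, alphabet=alph, probabilities=probs,
                  nsites=float(nsites), evalue=evalue)
    return motif, masked
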