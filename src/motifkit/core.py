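"""Alphabets, backgrounds, sequence containers and the motif matrix model.

Everything downstream (discovery, scanning, comparison, enrichment) is built
on the types defined here.  A motif is a fixed-width position probability
matrix; insertions and deletions are not representable.  All log quantities
are in bits (base 2), matching the usual sequence-logo convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Alphabet",
    "SequenceRecord",
    "SequenceSet",
    "Background",
    "Motif",
    "LogOddsMatrix",
    "make_alphabet",
    "estimate_background",
    "uniform_background",
    "counts_to_motif",
    "motif_to_logodds",
    "information_content",
]

_DNA_AMBIGUITY = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_RNA_AMBIGUITY = {k: v.replace("T", "U") for k, v in _DNA_AMBIGUITY.items()}
_PROTEIN_CORE = "ACDEFGHIKLMNPQRSTVWY"
_PROTEIN_AMBIGUITY = {"B": "DN", "Z": "EQ", "J": "IL", "X": _PROTEIN_CORE}
_DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_RNA_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}


@dataclass(frozen=True)
class Alphabet:
    """A biological symbol set with IUPAC ambiguity codes.

    ``core_symbols`` are the unambiguous residues (ACGT, ACGU, or the 20
    amino acids).  ``ambiguity_map`` maps each IUPAC degeneracy letter to
    the subset of core symbols it stands for; the ``wildcard`` letter (N
    or X) expands to every core symbol.  Nucleotide alphabets carry a
    complement map; protein does not.
    """

    name: str
    core_symbols: str
    complement_map: Mapping[str, str]
    ambiguity_map: Mapping[str, str]
    wildcard: str

    # derived lookup tables, built once in __post_init__
    _index: Mapping[str, int] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        ext = self.core_symbols + "".join(self.ambiguity_map)
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(ext)})

    @property
    def size(self) -> int:
        return len(self.core_symbols)

    @property
    def extended_symbols(self) -> str:
        """Core symbols followed by the ambiguity letters, in fixed order."""
        return self.core_symbols + "".join(self.ambiguity_map)

    @property
    def is_nucleotide(self) -> bool:
        return bool(self.complement_map)

    def index(self, letter: str) -> int:
        """Index of ``letter`` in the extended symbol order."""
        try:
            return self._index[letter]
        except KeyError:
            raise ValueError(
                f"letter {letter!r} is not in the {self.name} alphabet"
            ) from None

    def expand(self, letter: str) -> str:
        """Core symbols a letter stands for (a core letter maps to itself)."""
        if letter in self.ambiguity_map:
            return self.ambiguity_map[letter]
        if letter in self.complement_map or letter in self.core_symbols:
            return letter
        raise ValueError(f"letter {letter!r} is not in the {self.name} alphabet")

    def complement(self, letter: str) -> str:
        """IUPAC complement of any extended letter (nucleotide only)."""
        if not self.is_nucleotide:
            raise ValueError("protein alphabet has no complement")
        if letter in self.complement_map:
            return self.complement_map[letter]
        comp = frozenset(self.complement_map[c] for c in self.ambiguity_map[letter])
        for amb, exp in self.ambiguity_map.items():
            if frozenset(exp) == comp:
                return amb
        raise AssertionError("IUPAC complement closure violated")

    def reverse_complement(self, residues: str) -> str:
        return "".join(self.complement(c) for c in reversed(residues))

    def complement_permutation(self) -> np.ndarray:
        """Index permutation mapping core column a to its complement column."""
        return np.array(
            [self._index[self.complement_map[c]] for c in self.core_symbols]
        )

    def encode(self, residues: str) -> np.ndarray:
        """Residues as indices into ``extended_symbols`` (int16)."""
        try:
            return np.array([self._index[c] for c in residues], dtype=np.int16)
        except KeyError as exc:
            raise ValueError(
                f"letter {exc.args[0]!r} is not in the {self.name} alphabet"
            ) from None


def make_alphabet(kind: str) -> Alphabet:
    """Return the standard DNA, RNA or protein alphabet."""
    if kind == "DNA":
        return Alphabet("DNA", "ACGT", _DNA_COMPLEMENT, _DNA_AMBIGUITY, "N")
    if kind == "RNA":
        return Alphabet("RNA", "ACGU", _RNA_COMPLEMENT, _RNA_AMBIGUITY, "N")
    if kind == "protein":
        return Alphabet("protein", _PROTEIN_CORE, {}, _PROTEIN_AMBIGUITY, "X")
    raise ValueError(f"unknown alphabet kind {kind!r}; expected DNA, RNA or protein")


DNA = make_alphabet("DNA")
RNA = make_alphabet("RNA")
PROTEIN = make_alphabet("protein")


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence.  Residues are uppercase extended-alphabet letters."""

    identifier: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.identifier:
            raise ValueError("sequence identifier must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.identifier!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SequenceSet:
    """An ordered collection of sequences over one alphabet."""

    alphabet: Alphabet
    records: tuple[SequenceRecord, ...]

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        seen = set()
        for rec in self.records:
            if rec.identifier in seen:
                raise ValueError(f"duplicate sequence identifier {rec.identifier!r}")
            seen.add(rec.identifier)
            self.alphabet.encode(rec.residues)  # validates letters

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def min_length(self) -> int:
        return min(len(r) for r in self.records)


@dataclass(frozen=True)
class Background:
    """Zero-order letter model: one strictly positive frequency per core symbol."""

    alphabet: Alphabet
    frequencies: np.ndarray

    def __post_init__(self):
        freqs = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        if freqs.shape != (self.alphabet.size,):
            raise ValueError(
                f"expected {self.alphabet.size} frequencies, got {freqs.shape}"
            )
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {freqs.sum()!r}, not 1")
        if np.any(freqs <= 0):
            raise ValueError("every background frequency must be strictly positive")

    def frequency(self, letter: str) -> float:
        return float(self.frequencies[self.alphabet.index(letter)])

    def extended_frequencies(self) -> np.ndarray:
        """Frequencies for extended letters; an ambiguity letter gets the
        summed mass of its expansion (used as a normalizer, not a pmf)."""
        alph = self.alphabet
        out = np.empty(len(alph.extended_symbols))
        out[: alph.size] = self.frequencies
        for j, (amb, exp) in enumerate(alph.ambiguity_map.items()):
            out[alph.size + j] = sum(self.frequency(c) for c in exp)
        return out


def uniform_background(alphabet: Alphabet) -> Background:
    n = alphabet.size
    return Background(alphabet, np.full(n, 1.0 / n))


def estimate_background(
    seqs: SequenceSet,
    pseudocount: float = 1.0,
    use_both_strands: bool = False,
) -> Background:
    """Zero-order background from observed letter counts.

    Ambiguity letters contribute fractionally, split evenly over their
    expansion.  With ``use_both_strands`` on a nucleotide alphabet the
    counts are symmetrized with their complements, so the result is
    strand-neutral.
    """
    if len(seqs) == 0:
        raise ValueError("cannot estimate a background from an empty sequence set")
    alph = seqs.alphabet
    counts = np.zeros(alph.size)
    core_index = {c: i for i, c in enumerate(alph.core_symbols)}
    for rec in seqs:
        for letter in rec.residues:
            if letter in core_index:
                counts[core_index[letter]] += 1.0
            else:
                exp = alph.ambiguity_map[letter]
                counts[[core_index[c] for c in exp]] += 1.0 / len(exp)
    if use_both_strands and alph.is_nucleotide:
        perm = [core_index[alph.complement_map[c]] for c in alph.core_symbols]
        counts = (counts + counts[perm]) / 2.0
    total = counts.sum() + pseudocount * alph.size
    freqs = (counts + pseudocount) / total
    if np.any(freqs <= 0):
        raise ValueError(
            "zero background frequency; use a positive pseudocount when a "
            "letter is absent from the input"
        )
    return Background(alph, freqs)


@dataclass(frozen=True)
class Motif:
    """A fixed-width position probability matrix with metadata.

    ``probabilities`` has one row per motif position and one column per
    core alphabet symbol; each row sums to 1.  ``nsites`` is the effective
    number of sites the matrix was built from (it calibrates pseudocount
    arithmetic downstream); ``evalue`` carries discovery significance when
    known.
    """

    name: str
    alphabet: Alphabet
    probabilities: np.ndarray
    nsites: float = 20.0
    evalue: float | None = None
    alt_name: str = ""

    def __post_init__(self):
        probs = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", probs)
        if probs.ndim != 2 or probs.shape[1] != self.alphabet.size:
            raise ValueError(
                f"motif {self.name!r}: expected a w x {self.alphabet.size} matrix, "
                f"got shape {probs.shape}"
            )
        if probs.shape[0] < 1:
            raise ValueError(f"motif {self.name!r} must have width >= 1")
        if np.any(probs < 0):
            raise ValueError(f"motif {self.name!r} has negative probabilities")
        bad = np.flatnonzero(np.abs(probs.sum(axis=1) - 1.0) > 1e-6)
        if bad.size:
            raise ValueError(
                f"motif {self.name!r}: row {bad[0]} sums to "
                f"{probs[bad[0]].sum():.8f}, not 1"
            )
        if self.nsites <= 0:
            raise ValueError(f"motif {self.name!r}: nsites must be positive")
        if self.evalue is not None and self.evalue < 0:
            raise ValueError(f"motif {self.name!r}: evalue must be non-negative")

    @property
    def width(self) -> int:
        return self.probabilities.shape[0]

    @property
    def consensus(self) -> str:
        idx = np.argmax(self.probabilities, axis=1)
        return "".join(self.alphabet.core_symbols[i] for i in idx)

    def reverse_complement(self) -> "Motif":
        if not self.alphabet.is_nucleotide:
            raise ValueError("cannot reverse-complement a protein motif")
        perm = self.alphabet.complement_permutation()
        return replace(self, probabilities=self.probabilities[::-1, perm])

    def renamed(self, name: str) -> "Motif":
        return replace(self, name=name)


def counts_to_motif(
    counts: np.ndarray,
    background: Background,
    pseudocount_total: float = 1.0,
    name: str = "motif",
    **meta,
) -> Motif:
    """Turn a w x |alphabet| count matrix into a motif.

    Pseudocounts are background-proportional: ``alpha * background(a)`` is
    added to the count of letter ``a`` at each position, keeping log-odds
    finite and calibrated against the null model.  ``nsites`` is set to
    the mean row total.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != background.alphabet.size:
        raise ValueError(
            f"expected a w x {background.alphabet.size} count matrix, "
            f"got shape {counts.shape}"
        )
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    row_sums = counts.sum(axis=1)
    if np.any(row_sums <= 0):
        raise ValueError(f"count row {int(np.argmin(row_sums))} sums to zero")
    alpha = float(pseudocount_total)
    if alpha == 0 and np.any(counts == 0):
        raise ValueError(
            "a zero count with zero pseudocount would give a zero probability; "
            "use a positive pseudocount_total"
        )
    nsites = float(row_sums.mean())
    probs = (counts + alpha * background.frequencies) / (row_sums + alpha)[:, None]
    return Motif(name=name, alphabet=background.alphabet, probabilities=probs,
                 nsites=nsites, **meta)


@dataclass(frozen=True)
class LogOddsMatrix:
    """A motif as per-position log2(p/background) scores, plus an integer
    quantization used by the exact p-value dynamic program.

    ``integer_scores[i, a] = round((scores[i, a] - offset) / scale)`` lies in
    ``0..bins``; ``bits = integer * scale + offset`` inverts the mapping to
    within half a quantum.  Extended columns (ambiguity letters) carry the
    background-weighted average of their expansion's scores, so N-masked
    residues score neutrally.
    """

    motif: Motif
    background: Background
    scores: np.ndarray           # w x |core|, bits
    integer_scores: np.ndarray   # w x |extended|, int
    scale: float
    offset: float

    @property
    def width(self) -> int:
        return self.scores.shape[0]

    @property
    def bins(self) -> int:
        return int(self.integer_scores[:, : self.motif.alphabet.size].max())

    def bits_from_integer(self, total_integer: float) -> float:
        return total_integer * self.scale + self.width * self.offset


def motif_to_logodds(
    motif: Motif,
    background: Background,
    quantization_bins: int = 1000,
) -> LogOddsMatrix:
    """Log-odds (bits) representation of a motif with integer quantization."""
    if quantization_bins < 1:
        raise ValueError("quantization_bins must be a positive integer")
    probs = motif.probabilities
    zero = np.argwhere(probs == 0)
    if zero.size:
        i, a = zero[0]
        raise ValueError(
            f"motif {motif.name!r} has probability 0 at position {i}, letter "
            f"{motif.alphabet.core_symbols[a]!r}; log-odds undefined"
        )
    scores = np.log2(probs / background.frequencies)
    lo, hi = float(scores.min()), float(scores.max())
    scale = (hi - lo) / quantization_bins
    if scale == 0.0:          # motif identical to background: degenerate range
        scale = 1e-9
    core_int = np.rint((scores - lo) / scale).astype(np.int64)

    alph = motif.alphabet
    n_ext = len(alph.extended_symbols)
    integer_scores = np.zeros((motif.width, n_ext), dtype=np.int64)
    integer_scores[:, : alph.size] = core_int
    # ambiguity letters: background-weighted mean of the expansion's scores
    for j, (amb, exp) in enumerate(alph.ambiguity_map.items()):
        cols = [alph.index(c) for c in exp]
        wts = background.frequencies[cols]
        avg = (core_int[:, cols] * wts).sum(axis=1) / wts.sum()
        integer_scores[:, alph.size + j] = np.rint(avg).astype(np.int64)
    return LogOddsMatrix(
        motif=motif, background=background, scores=scores,
        integer_scores=integer_scores, scale=scale, offset=lo,
    )


def with_pseudocounts(
    motif: Motif, background: Background, pseudocount_total: float
) -> Motif:
    """Blend a motif with the background: effective counts ``p * nsites``
    plus ``alpha * background``.  Guarantees strictly positive rows, so
    log-odds scores are finite; with ``pseudocount_total == 0`` the motif
    is returned unchanged."""
    alpha = float(pseudocount_total)
    if alpha < 0:
        raise ValueError("pseudocount_total must be non-negative")
    if alpha == 0:
        return motif
    probs = (motif.probabilities * motif.nsites + alpha * background.frequencies)
    probs /= motif.nsites + alpha
    return replace(motif, probabilities=probs)


def information_content(
    motif: Motif, background: Background
) -> tuple[np.ndarray, float]:
    """Per-position and total information content in bits.

    IC(i) = sum_a p(i,a) log2(p(i,a)/b(a)) — the relative entropy of each
    motif column against the background, the quantity a sequence logo plots.
    """
    probs = motif.probabilities
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = probs * np.log2(probs / background.frequencies)
    terms = np.where(probs > 0, terms, 0.0)
    per_position = terms.sum(axis=1)
    # relative entropy is non-negative; clip float slop on uniform columns
    per_position = np.maximum(per_position, 0.0)
    return per_position, float(per_position.sum())
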