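import numpy as np
import pytest
from hypothesis import settings

# reproducible property tests: same example sequence on every run
settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

from motifkit import (
    Motif,
    PlantSpec,
    generate_planted_dataset,
    make_alphabet,
    uniform_background,
)


@pytest.fixture(scope="session")
def dna():
    return make_alphabet("DNA")


@pytest.fixture(scope="session")
def protein():
    return make_alphabet("protein")


@pytest.fixture(scope="session")
def uniform_dna_bg(dna):
    return uniform_background(dna)


def word_motif(word, alphabet, match=0.97, name=None):
    """Near-deterministic motif whose consensus is ``word``."""
    A = alphabet.size
    probs = np.full((len(word), A), (1.0 - match) / (A - 1))
    for i, c in enumerate(word):
        probs[i, alphabet.index(c)] = match
    return Motif(name or word.lower(), alphabet,
                 probs / probs.sum(axis=1, keepdims=True))


def random_motif(width, alphabet, rng, concentration=0.6, name="rand"):
    probs = rng.dirichlet(np.full(alphabet.size, concentration), size=width)
    probs = np.maximum(probs, 1e-9)
    probs /= probs.sum(axis=1, keepdims=True)
    return Motif(name, alphabet, probs)


@pytest.fixture
def planted_ttgaca(dna, uniform_dna_bg):
    """10 x 100 bp DNA, one exact TTGACA-consensus site per sequence."""
    motif = word_motif("TTGACA", dna, match=0.98)
    seqs, truth = generate_planted_dataset(
        10, 100, uniform_dna_bg, [PlantSpec(motif)], seed=3
    )
    return motif, seqs, truth


def column_agreement(consensus, word, alphabet=None):
    """Best column agreement of a consensus with a word, either strand."""
    fwd = sum(a == b for a, b in zip(consensus, word))
    if alphabet is not None and alphabet.is_nucleotide:
        rc = alphabet.reverse_complement(word)
        return max(fwd, sum(a == b for a, b in zip(consensus, rc)))
    return fwd
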