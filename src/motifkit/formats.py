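"""FASTA and minimal MEME-format motif I/O, plus typed-motif auto-detection.

The minimal motif exchange format is the lingua franca between the tools in
this package: a ``MEME version 4`` header, an alphabet line, optional strand
and background sections, then one ``MOTIF`` block per motif holding a
``letter-probability matrix``.  Typed motifs — aligned sites, count matrices
or probability matrices pasted as plain text — are auto-detected and
converted to the same in-memory representation.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .core import (
    Alphabet,
    Background,
    Motif,
    SequenceRecord,
    SequenceSet,
    make_alphabet,
)

__all__ = [
    "MotifFile",
    "read_fasta",
    "write_fasta",
    "infer_alphabet",
    "parse_meme_motifs",
    "write_meme_motifs",
    "parse_typed_motifs",
]

# default effective site count for a motif given only as probabilities
DEFAULT_NSITES = 20.0


@dataclass
class MotifFile:
    """A parsed minimal-format motif file: alphabet, strand note, background
    and an ordered list of motifs sharing that alphabet."""

    alphabet: Alphabet
    motifs: list[Motif] = field(default_factory=list)
    background: Background | None = None
    strands: str = "+ -"
    version: str = "4"

    def __post_init__(self):
        for m in self.motifs:
            if m.alphabet.name != self.alphabet.name:
                raise ValueError(
                    f"motif {m.name!r} alphabet {m.alphabet.name} does not match "
                    f"file alphabet {self.alphabet.name}"
                )


# --------------------------------------------------------------------------
# FASTA

def infer_alphabet(residues_iter) -> Alphabet:
    """DNA unless a non-DNA letter appears; then RNA, then protein."""
    letters = set()
    for residues in residues_iter:
        letters.update(residues)
    dna, rna = make_alphabet("DNA"), make_alphabet("RNA")
    if letters <= set(dna.extended_symbols):
        return dna
    if letters <= set(rna.extended_symbols):
        return rna
    return make_alphabet("protein")


def read_fasta(stream, alphabet: Alphabet | None = None) -> SequenceSet:
    """Parse FASTA text into a SequenceSet.

    Headers split at the first whitespace into identifier and description;
    sequence lines are concatenated and uppercased (repeat-masked lowercase
    input is common).  If no alphabet is given it is inferred from the
    letters present.  Invalid letters are rejected with their line number.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    text = stream.read()
    entries = []
    with io.StringIO(text) as handle:
        for title, seq in SimpleFastaParser(handle):
            parts = title.split(None, 1)
            if not parts:
                raise ValueError("FASTA record with an empty header")
            ident = parts[0]
            desc = parts[1] if len(parts) > 1 else ""
            entries.append((ident, desc, seq.upper()))
    if not entries:
        raise ValueError("no FASTA records found")
    if alphabet is None:
        alphabet = infer_alphabet(seq for _, _, seq in entries)
    valid = set(alphabet.extended_symbols)
    for ident, _, seq in entries:
        bad = next((c for c in seq if c not in valid), None)
        if bad is not None:
            raise ValueError(
                f"invalid {alphabet.name} letter {bad!r} in sequence "
                f"{ident!r} (line {_line_of(text, ident, bad)})"
            )
    records = tuple(SequenceRecord(i, s, d) for i, d, s in entries)
    return SequenceSet(alphabet, records)


def _line_of(text: str, ident: str, letter: str) -> int:
    """Line number (1-based) of the first occurrence of ``letter`` in the
    body of record ``ident``."""
    in_record = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">"):
            in_record = line[1:].split(None, 1)[0] == ident if line[1:].strip() else False
            continue
        if in_record and letter in line.upper():
            return lineno
    return -1


def write_fasta(seqs: SequenceSet, stream, line_width: int = 70) -> None:
    for rec in seqs:
        header = f">{rec.identifier}"
        if rec.description:
            header += f" {rec.description}"
        stream.write(header + "\n")
        for i in range(0, len(rec.residues), line_width):
            stream.write(rec.residues[i : i + line_width] + "\n")


# --------------------------------------------------------------------------
# Minimal MEME motif format

_ALPHABET_BY_LETTERS = {"ACGT": "DNA", "ACGU": "RNA"}


def _alphabet_from_letters(letters: str) -> Alphabet:
    return make_alphabet(_ALPHABET_BY_LETTERS.get(letters, "protein"))


def parse_meme_motifs(stream) -> MotifFile:
    """Parse the minimal motif exchange format.

    Recognized sections: a version header, ``ALPHABET=``, ``strands:``,
    ``Background letter frequencies`` and per-motif ``MOTIF`` /
    ``letter-probability matrix:`` blocks.  A probability row that does not
    sum to 1 within 0.01, or a row of the wrong length, is rejected naming
    the motif and row.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = stream.read().splitlines()
    version = None
    alphabet: Alphabet | None = None
    strands = "+ -"
    background = None
    motifs: list[Motif] = []

    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if line.startswith("MEME version"):
            version = line.split()[2] if len(line.split()) > 2 else "4"
            i += 1
        elif line.startswith("ALPHABET="):
            letters = line.split("=", 1)[1].strip()
            alphabet = _alphabet_from_letters(letters)
            i += 1
        elif line.startswith("strands:"):
            strands = line.split(":", 1)[1].strip()
            i += 1
        elif line.startswith("Background letter frequencies"):
            i += 1
            pairs: list[tuple[str, float]] = []
            while i < n:
                tokens = lines[i].split()
                if not tokens or not _is_background_pairs(tokens):
                    break
                pairs.extend(
                    (tokens[j], float(tokens[j + 1]))
                    for j in range(0, len(tokens), 2)
                )
                i += 1
            if alphabet is None:
                alphabet = _alphabet_from_letters("".join(l for l, _ in pairs))
            freqs = np.zeros(alphabet.size)
            for letter, f in pairs:
                freqs[alphabet.index(letter)] = f
            freqs = freqs / freqs.sum()
            background = Background(alphabet, freqs)
        elif line.startswith("MOTIF"):
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError("MOTIF line without a motif name")
            name = tokens[1]
            alt = tokens[2] if len(tokens) > 2 else ""
            i += 1
            while i < n and "letter-probability matrix" not in lines[i]:
                if lines[i].strip() and lines[i].startswith("MOTIF"):
                    raise ValueError(f"motif {name!r} has no probability matrix")
                i += 1
            if i >= n:
                raise ValueError(f"motif {name!r} has no probability matrix")
            header = lines[i]
            attrs = dict(re.findall(r"(\w+)=\s*(\S+)", header))
            if alphabet is None:
                raise ValueError("probability matrix before any ALPHABET line")
            alength = int(attrs.get("alength", alphabet.size))
            if alength != alphabet.size:
                raise ValueError(
                    f"motif {name!r}: alength= {alength} disagrees with the "
                    f"{alphabet.name} alphabet size {alphabet.size}"
                )
            width = int(attrs["w"]) if "w" in attrs else None
            nsites = float(attrs.get("nsites", DEFAULT_NSITES))
            evalue = float(attrs["E"]) if "E" in attrs else None
            i += 1
            rows = []
            while i < n:
                tokens = lines[i].split()
                if not tokens or not _is_number(tokens[0]):
                    break
                if len(tokens) != alength:
                    raise ValueError(
                        f"motif {name!r}, row {len(rows)}: expected {alength} "
                        f"probabilities, got {len(tokens)}"
                    )
                rows.append([float(t) for t in tokens])
                i += 1
            if width is not None and len(rows) != width:
                raise ValueError(
                    f"motif {name!r}: header says w= {width} but "
                    f"{len(rows)} rows were found"
                )
            matrix = np.array(rows)
            sums = matrix.sum(axis=1)
            bad = np.flatnonzero(np.abs(sums - 1.0) > 0.01)
            if bad.size:
                raise ValueError(
                    f"motif {name!r}, row {bad[0]}: probabilities sum to "
                    f"{sums[bad[0]]:.4f}, not 1"
                )
            matrix = matrix / sums[:, None]  # absorb printed rounding
            motifs.append(
                Motif(name=name, alt_name=alt, alphabet=alphabet,
                      probabilities=matrix, nsites=nsites, evalue=evalue)
            )
        else:
            i += 1

    if version is None:
        raise ValueError("not a minimal motif file: missing 'MEME version' header")
    if alphabet is None:
        alphabet = make_alphabet("DNA")
    return MotifFile(alphabet=alphabet, motifs=motifs, background=background,
                     strands=strands, version=version)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _is_background_pairs(tokens: list[str]) -> bool:
    return (
        len(tokens) % 2 == 0
        and all(len(tokens[j]) == 1 for j in range(0, len(tokens), 2))
        and all(_is_number(tokens[j]) for j in range(1, len(tokens), 2))
    )


def write_meme_motifs(motif_file: MotifFile, stream) -> None:
    """Emit the minimal motif format; probabilities with 6 decimals."""
    stream.write(f"MEME version {motif_file.version}\n\n")
    stream.write(f"ALPHABET= {motif_file.alphabet.core_symbols}\n\n")
    if motif_file.alphabet.is_nucleotide:
        stream.write(f"strands: {motif_file.strands}\n\n")
    bg = motif_file.background
    if bg is not None:
        stream.write("Background letter frequencies\n")
        stream.write(
            " ".join(
                f"{c} {bg.frequency(c):.6f}"
                for c in motif_file.alphabet.core_symbols
            )
            + "\n\n"
        )
    for m in motif_file.motifs:
        name_part = f"MOTIF {m.name}"
        if m.alt_name:
            name_part += f" {m.alt_name}"
        stream.write(name_part + "\n")
        header = (
            f"letter-probability matrix: alength= {m.alphabet.size} "
            f"w= {m.width} nsites= {_fmt_number(m.nsites)}"
        )
        if m.evalue is not None:
            header += f" E= {m.evalue:.1e}"
        stream.write(header + "\n")
        for row in m.probabilities:
            # absorb the 6-decimal rounding residue into the largest entry
            # so printed rows sum to exactly 1 and re-reading is a fixed point
            printed = np.round(row, 6)
            printed[int(np.argmax(row))] += round(1.0 - printed.sum(), 6)
            stream.write(" ".join(f"{p:.6f}" for p in printed) + "\n")
        stream.write("\n")


def _fmt_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"


# --------------------------------------------------------------------------
# Typed motifs

def parse_typed_motifs(
    text: str,
    alphabet: Alphabet,
) -> list[Motif]:
    """Convert pasted plain-text motifs into probability-matrix motifs.

    Blocks are separated by blank lines.  A block of alphabet letters
    (IUPAC codes allowed) is read as aligned sites; a numeric block is read
    as a count or probability matrix, with the orientation — rows as motif
    positions versus rows as alphabet letters — decided automatically from
    the block's shape and row/column sums.  When both readings are
    consistent (a square matrix of width |alphabet|) rows-as-positions wins.

    The resulting matrices are plain relative frequencies (zeros allowed);
    scanning and comparison regularize with pseudocounts when they need
    finite log-odds.
    """
    motifs = []
    blocks = [b for b in re.split(r"\n\s*\n", text.strip()) if b.strip()]
    for k, block in enumerate(blocks, start=1):
        lines = [ln.strip() for ln in block.splitlines() if ln.strip()]
        tokens0 = lines[0].split()
        numeric = all(_is_number(t) for t in tokens0)
        name = f"typed-{k}"
        if numeric:
            matrix = _parse_numeric_block(lines, alphabet, name)
            motifs.append(_matrix_to_motif(matrix, alphabet, name))
        else:
            motifs.append(_sites_to_motif(lines, alphabet, name))
    return motifs


def _sites_to_motif(lines, alphabet, name):
    sites = ["".join(ln.split()).upper() for ln in lines]
    width = len(sites[0])
    for s in sites:
        if len(s) != width:
            raise ValueError(
                f"{name}: sequence sites are of inconsistent lengths "
                f"({len(s)} vs {width})"
            )
    valid = set(alphabet.extended_symbols)
    counts = np.zeros((width, alphabet.size))
    for s in sites:
        for i, letter in enumerate(s):
            if letter not in valid:
                raise ValueError(
                    f"{name}: unsupported character {letter!r} for the "
                    f"{alphabet.name} alphabet"
                )
            exp = alphabet.expand(letter)
            for c in exp:
                counts[i, alphabet.index(c)] += 1.0 / len(exp)
    probs = counts / counts.sum(axis=1, keepdims=True)
    return Motif(name=name, alphabet=alphabet, probabilities=probs,
                 nsites=float(len(sites)))


def _parse_numeric_block(lines, alphabet, name) -> np.ndarray:
    """Return the matrix oriented as positions x letters."""
    rows = [[float(t) for t in ln.split()] for ln in lines]
    ncols = len(rows[0])
    if any(len(r) != ncols for r in rows):
        raise ValueError(f"{name}: numeric rows have inconsistent lengths")
    matrix = np.array(rows)
    A = alphabet.size
    as_positions = ncols == A and _consistent_sums(matrix.sum(axis=1))
    as_letters = matrix.shape[0] == A and _consistent_sums(matrix.sum(axis=0))
    if as_positions:            # tie-break: prefer rows-as-positions
        return matrix
    if as_letters:
        return matrix.T
    raise ValueError(
        f"{name}: cannot orient a {matrix.shape[0]} x {ncols} numeric block "
        f"for a {A}-letter alphabet (row/column sums inconsistent)"
    )


def _consistent_sums(sums: np.ndarray, rtol: float = 0.02) -> bool:
    """All sums equal a common total (or all ~1 for probabilities)."""
    mean = sums.mean()
    if mean <= 0:
        return False
    return bool(np.all(np.abs(sums - mean) <= rtol * mean + 1e-9))


def _matrix_to_motif(matrix, alphabet, name):
    sums = matrix.sum(axis=1)
    if np.any(sums <= 0):
        raise ValueError(f"{name}: a matrix row sums to zero")
    is_probability = np.all(matrix <= 1.0 + 1e-9) and np.all(np.abs(sums - 1.0) < 0.02)
    nsites = DEFAULT_NSITES if is_probability else float(sums.mean())
    return Motif(name=name, alphabet=alphabet,
                 probabilities=matrix / sums[:, None], nsites=nsites)
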