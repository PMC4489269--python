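"""Synthetic planted-motif data, the integrated peak pipeline, and
iterative motif refinement.

The generator draws background sequences from a zero-order letter model
and writes motif sites over them according to declarative plant
specifications (occurrence model, placement distribution, per-column
mutation rate, strand policy), returning both the sequences and a truth
table of planted sites.  The peak pipeline chains discovery, comparison
against a motif database and central enrichment into one report — the
evidence pattern for ChIP-seq peaks: a discovered motif that matches a
known motif and is centrally enriched.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .centrality import CentralityResult, central_enrichment, best_site_positions, rank_motifs_by_centrality
from .compare import MotifAlignment, compare_to_database
from .core import (
    Background,
    Motif,
    SequenceRecord,
    SequenceSet,
    uniform_background,
)
from .discover_em import SiteModel, discover_motifs
from .discover_words import WordCandidate, discover_words
from .scan import scan

__all__ = [
    "PlantSpec",
    "PlantedSite",
    "PeakReport",
    "generate_planted_dataset",
    "run_peak_pipeline",
    "iterative_refinement",
    "stage_rng",
]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible random stream for a named pipeline stage."""
    return np.random.default_rng([seed, zlib.crc32(stage.encode())])


@dataclass(frozen=True)
class PlantSpec:
    """How to plant one motif into a synthetic dataset.

    ``occurrence``: "every" (one site per sequence), a float in (0, 1]
    (per-sequence probability of one site), or "none".
    ``placement``: "uniform" over admissible starts, or "central" —
    Gaussian around the sequence midpoint with standard deviation ``sd``
    (in letters), clipped to the admissible range.
    ``mutation_rate``: per planted column, probability of replacing the
    sampled letter with a uniformly random different letter.
    ``strand``: "forward" or "both" (site orientation flipped with
    probability 1/2).
    """

    motif: Motif
    occurrence: str | float = "every"
    placement: str = "uniform"
    sd: float | None = None
    mutation_rate: float = 0.0
    strand: str = "forward"

    def __post_init__(self):
        if isinstance(self.occurrence, str):
            if self.occurrence not in ("every", "none"):
                raise ValueError(f"unknown occurrence model {self.occurrence!r}")
        elif not (0.0 < float(self.occurrence) <= 1.0):
            raise ValueError("occurrence probability must lie in (0, 1]")
        if self.placement not in ("uniform", "central"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.placement == "central" and (self.sd is None or self.sd <= 0):
            raise ValueError("central placement needs sd > 0")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.strand not in ("forward", "both"):
            raise ValueError(f"unknown strand policy {self.strand!r}")


@dataclass(frozen=True)
class PlantedSite:
    sequence_id: str
    motif_name: str
    offset: int          # 0-based forward-strand start
    strand: str
    site: str            # planted text, forward-strand orientation


def generate_planted_dataset(
    n: int,
    L: int,
    background: Background,
    plants: list[PlantSpec] = (),
    seed: int = 0,
    id_prefix: str = "seq",
) -> tuple[SequenceSet, list[PlantedSite]]:
    """i.i.d. background sequences with motif sites written over them.

    Each planted column is sampled from the motif's probability row, then
    mutated at the plant's mutation rate.  Overlapping plants within one
    sequence are re-drawn up to 100 times before the call fails.
    Deterministic given ``seed``.
    """
    alph = background.alphabet
    for spec in plants:
        if spec.motif.width > L:
            raise ValueError(
                f"motif {spec.motif.name!r} (w={spec.motif.width}) is wider "
                f"than the sequence length {L}"
            )
    rng = np.random.default_rng(seed)
    letters = np.array(list(alph.core_symbols))
    records = []
    truth: list[PlantedSite] = []
    for s in range(n):
        seq = rng.choice(letters, size=L, p=background.frequencies)
        seq_id = f"{id_prefix}{s + 1}"
        occupied: list[tuple[int, int]] = []
        for spec in plants:
            if spec.occurrence == "none":
                continue
            if spec.occurrence != "every" and rng.random() > float(spec.occurrence):
                continue
            w = spec.motif.width
            for attempt in range(100):
                if spec.placement == "uniform":
                    start = int(rng.integers(0, L - w + 1))
                else:
                    center = rng.normal((L - w) / 2.0, spec.sd)
                    start = int(np.clip(round(center), 0, L - w))
                if all(start + w <= a or start >= b for a, b in occupied):
                    break
            else:
                raise ValueError(
                    f"could not place motif {spec.motif.name!r} without "
                    f"overlap in sequence {seq_id} after 100 draws"
                )
            site = _sample_site(spec.motif, spec.mutation_rate, rng, letters)
            strand = "+"
            if spec.strand == "both" and rng.random() < 0.5:
                strand = "-"
                site = alph.reverse_complement(site)
            seq[start : start + w] = list(site)
            occupied.append((start, start + w))
            truth.append(PlantedSite(seq_id, spec.motif.name, start, strand, site))
        records.append(SequenceRecord(seq_id, "".join(seq)))
    return SequenceSet(alph, tuple(records)), truth


def _sample_site(motif: Motif, mutation_rate: float,
                 rng: np.random.Generator, letters: np.ndarray) -> str:
    A = len(letters)
    out = []
    for row in motif.probabilities:
        a = int(rng.choice(A, p=row / row.sum()))
        if mutation_rate > 0 and rng.random() < mutation_rate:
            a = (a + 1 + int(rng.integers(A - 1))) % A
        out.append(letters[a])
    return "".join(out)


# --------------------------------------------------------------------------
# Integrated peak pipeline

@dataclass
class DiscoveredMotifEvidence:
    """One discovered motif with its two independent lines of evidence."""

    motif: Motif
    source: str                          # "em" or "words"
    centrality: CentralityResult | None = None
    db_matches: list[MotifAlignment] = field(default_factory=list)

    @property
    def best_db_match(self) -> MotifAlignment | None:
        return self.db_matches[0] if self.db_matches else None


@dataclass
class PeakReport:
    discovered: list[DiscoveredMotifEvidence]
    db_centrality: list[CentralityResult]
    word_candidates: list[WordCandidate] = field(default_factory=list)

    @property
    def top(self) -> DiscoveredMotifEvidence | None:
        return self.discovered[0] if self.discovered else None

    def summary(self) -> str:
        lines = ["Peak pipeline report", "===================="]
        for i, ev in enumerate(self.discovered, start=1):
            lines.append(
                f"[{i}] {ev.motif.name} ({ev.source}) w={ev.motif.width} "
                f"E={ev.motif.evalue:.3g}"
            )
            if ev.best_db_match is not None:
                m = ev.best_db_match
                lines.append(
                    f"    best database match: {m.target_name} "
                    f"(p={m.p_value:.3g}, offset={m.offset}, {m.orientation})"
                )
            if ev.centrality is not None:
                c = ev.centrality
                lines.append(
                    f"    central enrichment: adjusted p={c.adjusted_p_value:.3g} "
                    f"({c.sites_in_window}/{c.sequences_with_site} sites in "
                    f"best window of {c.best_window_size})"
                )
        lines.append("Database motifs by central enrichment:")
        for c in self.db_centrality[:5]:
            lines.append(f"    {c.motif_name}: adjusted p={c.adjusted_p_value:.3g}")
        return "\n".join(lines)


def run_peak_pipeline(
    seqs: SequenceSet,
    motif_db: list[Motif],
    seed: int = 0,
    background: Background | None = None,
    min_width: int = 6,
    max_width: int = 10,
    n_motifs: int = 2,
    n_starts: int = 20,
    max_candidates: int = 500,
    word_e_threshold: float = 0.05,
    site_p_threshold: float = 1e-3,
) -> PeakReport:
    """Discovery + database comparison + central enrichment in one pass.

    The input must be equal-length nucleotide sequences (the ChIP-peak
    use case).  Discovery never sees positional information: sequences
    are handed to the discovery stages in a shuffled order and centrality
    is computed afterwards from hit positions only.  Deterministic given
    ``seed``.
    """
    lengths = {len(r) for r in seqs}
    if len(lengths) != 1:
        raise ValueError(
            "the peak pipeline requires equal-length sequences; got lengths "
            f"{sorted(lengths)}"
        )
    if not seqs.alphabet.is_nucleotide:
        raise ValueError("the peak pipeline targets nucleotide peak regions")
    if background is None:
        background = uniform_background(seqs.alphabet)

    # discovery sees a shuffled sequence order: a structural guarantee that
    # positional evidence stays independent of discovery
    order = stage_rng(seed, "shuffle-order").permutation(len(seqs))
    shuffled = SequenceSet(seqs.alphabet,
                           tuple(seqs.records[i] for i in order))

    em_seed = int(stage_rng(seed, "discover-em").integers(2 ** 31))
    em = discover_motifs(
        shuffled, min_width, max_width, n_motifs=n_motifs,
        model=SiteModel("ZOOPS"), background=background, seed=em_seed,
        n_starts=n_starts, max_candidates=max_candidates,
    )
    words_seed = int(stage_rng(seed, "discover-words").integers(2 ** 31))
    word_results = discover_words(
        shuffled, e_threshold=word_e_threshold, n_motifs=n_motifs,
        seed=words_seed,
    )

    discovered = [
        DiscoveredMotifEvidence(motif=m, source="em") for m in em.motifs
    ] + [
        DiscoveredMotifEvidence(motif=m, source="words")
        for _, m in word_results
    ]

    compare_seed = int(stage_rng(seed, "compare").integers(2 ** 31))
    L = lengths.pop()
    for ev in discovered:
        offsets = best_site_positions(
            ev.motif, seqs, background, p_threshold=site_p_threshold
        )
        ev.centrality = central_enrichment(
            offsets, L, ev.motif.width, motif_name=ev.motif.name
        )
        if motif_db:
            ev.db_matches = compare_to_database(
                ev.motif, motif_db, seed=compare_seed, background=background
            )

    db_centrality = rank_motifs_by_centrality(
        motif_db, seqs, background, p_threshold=site_p_threshold
    ) if motif_db else []

    discovered.sort(key=lambda ev: (ev.motif.evalue
                                    if ev.motif.evalue is not None else np.inf))
    return PeakReport(discovered=discovered, db_centrality=db_centrality,
                      word_candidates=[c for c, _ in word_results])


# --------------------------------------------------------------------------
# Iterative refinement

def iterative_refinement(
    seqs_db: SequenceSet,
    initial_motif: Motif,
    region_length: int,
    rounds: int = 2,
    background: Background | None = None,
    scan_p_threshold: float = 1e-4,
    seed: int = 0,
) -> tuple[Motif, list[int]]:
    """Refine a motif by alternating scanning and re-discovery.

    Each round scans the database with the current motif, collects the
    sequences with a hit starting within their first ``region_length``
    letters, truncates them to that region, and re-runs one-per-sequence
    EM discovery at the motif's width on the collected set.  Stops early
    (with the last motif) if a round collects fewer than two sequences.
    Returns the final motif and the per-round collected-set sizes.
    """
    if region_length < initial_motif.width:
        raise ValueError("region_length must be at least the motif width")
    if background is None:
        background = uniform_background(seqs_db.alphabet)
    motif = initial_motif
    sizes: list[int] = []
    for round_no in range(rounds):
        hits = scan(motif, seqs_db, background, p_threshold=scan_p_threshold,
                    both_strands=seqs_db.alphabet.is_nucleotide)
        keep_ids = sorted({
            h.sequence_id for h in hits if h.start <= region_length - motif.width + 1
        })
        sizes.append(len(keep_ids))
        if len(keep_ids) < 2:
            import warnings
            warnings.warn(
                f"refinement round {round_no + 1} collected only "
                f"{len(keep_ids)} sequences; stopping early"
            )
            return motif, sizes
        by_id = {r.identifier: r for r in seqs_db}
        collected = SequenceSet(
            seqs_db.alphabet,
            tuple(
                SequenceRecord(i, by_id[i].residues[:region_length],
                               by_id[i].description)
                for i in keep_ids
            ),
        )
        result = discover_motifs(
            collected, motif.width, motif.width, n_motifs=1,
            model=SiteModel("OOPS"), background=background,
            seed=seed + round_no,
        )
        motif = result.motifs[0].renamed(f"{initial_motif.name}-round{round_no + 1}")
    return motif, sizes
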