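"""Probabilistic fixed-width motif discovery by expectation-maximization.

The finite mixture model treats each sequence window as either a motif
site or background.  Three site-count models are supported:

* OOPS  — exactly one site per sequence,
* ZOOPS — zero or one site per sequence (per-sequence prior gamma),
* ANR   — any number of repetitions (per-window Bernoulli prior gamma).

Multiple motifs are found sequentially: after each motif converges, the
positions it occupies are probabilistically "erased" (down-weighted by
their site posterior) so later rounds find different signal.

EM maximizes the penalized log-likelihood ratio (data LLR plus the
Dirichlet pseudocount prior on motif columns, plus the site-prior terms),
which is guaranteed non-decreasing every iteration; that trace is exposed
for inspection.  The reported E-value is a calibrated, deliberately
conservative estimate built from the data LLR — see ``motif_significance``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    Background,
    Motif,
    SequenceSet,
    uniform_background,
)

__all__ = [
    "SiteModel",
    "Site",
    "EMResult",
    "DiscoveryResult",
    "seed_starts",
    "run_em",
    "motif_significance",
    "erase_and_repeat",
    "discover_motifs",
]

SEED_MATCH_PROBABILITY = 0.7   # soft consensus seeding; keeps matrices positive
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 200
DEFAULT_N_STARTS = 50
DEFAULT_MAX_CANDIDATES = 2000


@dataclass(frozen=True)
class SiteModel:
    """Site-count model: OOPS (one per sequence), ZOOPS (zero or one,
    prior ``gamma`` per sequence) or ANR (any number, prior ``gamma``
    per window)."""

    kind: str = "OOPS"
    gamma: float = 0.5

    def __post_init__(self):
        if self.kind not in ("OOPS", "ZOOPS", "ANR"):
            raise ValueError(f"unknown site model {self.kind!r}")
        if self.kind != "OOPS" and not (0.0 < self.gamma <= 1.0):
            raise ValueError("site prior gamma must lie in (0, 1]")


@dataclass(frozen=True)
class Site:
    sequence_id: str
    offset: int            # 0-based start of the site on the forward strand
    strand: str
    posterior: float


@dataclass
class EMResult:
    motif: Motif
    sites: list[Site]
    llr: float                       # data log-likelihood ratio, nats
    trace: list[float]               # penalized objective per iteration
    model: SiteModel
    window_posteriors: np.ndarray    # (n_windows_total * n_strands,)
    n_iterations: int = 0


@dataclass
class DiscoveryResult:
    """Motifs ordered by ascending E-value estimate."""

    motifs: list[Motif] = field(default_factory=list)
    fits: list[EMResult] = field(default_factory=list)

    def sort(self):
        order = sorted(range(len(self.motifs)),
                       key=lambda i: (self.motifs[i].evalue, i))
        self.motifs = [self.motifs[i] for i in order]
        self.fits = [self.fits[i] for i in order]


class _WindowData:
    """Precomputed window-index matrices shared across EM iterations.

    ``W[j, k]`` is the extended-letter index at window j, column k;
    ``P[j, k]`` the flat position index (for erasing weights); ``seq_slices``
    delimits each sequence's windows in the global order.
    """

    def __init__(self, seqs: SequenceSet, width: int):
        alph = seqs.alphabet
        if width > seqs.min_length():
            raise ValueError(
                f"motif width {width} exceeds the shortest sequence "
                f"({seqs.min_length()})"
            )
        encs, slices, pos_starts = [], [], []
        start = 0
        pos = 0
        for rec in seqs:
            enc = alph.encode(rec.residues)
            m = len(enc) - width + 1
            encs.append(enc)
            slices.append((start, start + m))
            pos_starts.append(pos)
            start += m
            pos += len(enc)
        self.alphabet = alph
        self.width = width
        self.seq_ids = [rec.identifier for rec in seqs]
        self.seq_slices = slices
        self.n_windows = start
        self.n_positions = pos
        W = np.empty((start, width), dtype=np.int32)
        P = np.empty((start, width), dtype=np.int64)
        for enc, (a, b), p0 in zip(encs, slices, pos_starts):
            m = b - a
            idx = np.arange(m)[:, None] + np.arange(width)[None, :]
            W[a:b] = enc[idx]
            P[a:b] = idx + p0
        self.W = W
        self.P = P
        self.seg_starts = np.array([a for a, _ in slices], dtype=np.int64)
        self.seq_index = np.empty(start, dtype=np.int64)
        for i, (a, b) in enumerate(slices):
            self.seq_index[a:b] = i

    def log_window_weights(self, weights: np.ndarray | None) -> np.ndarray:
        if weights is None:
            return np.zeros(self.n_windows)
        with np.errstate(divide="ignore"):
            lw = np.log(weights)
        return lw[self.P].sum(axis=1)

    def segment_logsumexp(self, rows: np.ndarray) -> np.ndarray:
        """logsumexp over each sequence's windows, pooled across the strand
        rows of ``rows`` (shape n_strands x n_windows); returns (n_seqs,)."""
        per_strand = _segment_lse(rows, self.seg_starts)
        return logaddexp_reduce(per_strand)


def _segment_lse(rows: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Row-wise segmented logsumexp: rows (k, n), segments given by starts."""
    m = np.maximum.reduceat(rows, starts, axis=1)
    m = np.where(np.isfinite(m), m, 0.0)       # all--inf segment -> stays -inf
    shifted = np.exp(rows - np.repeat(m, np.diff(np.append(starts, rows.shape[1])),
                                      axis=1))
    sums = np.add.reduceat(shifted, starts, axis=1)
    with np.errstate(divide="ignore"):
        return m + np.log(sums)


def logaddexp_reduce(per_strand: np.ndarray) -> np.ndarray:
    out = per_strand[0]
    for row in per_strand[1:]:
        out = np.logaddexp(out, row)
    return out


def _extended_log_ratios(motif: Motif, background: Background) -> np.ndarray:
    """log(p/b) per position for every extended letter; an ambiguity letter
    gets the log of the background-weighted average ratio of its expansion
    (neutral for N)."""
    alph = motif.alphabet
    probs = motif.probabilities
    core = np.log(probs) - np.log(background.frequencies)
    out = np.empty((motif.width, len(alph.extended_symbols)))
    out[:, : alph.size] = core
    for j, (amb, exp) in enumerate(alph.ambiguity_map.items()):
        cols = [alph.index(c) for c in exp]
        bmass = background.frequencies[cols].sum()
        out[:, alph.size + j] = np.log(probs[:, cols].sum(axis=1) / bmass)
    return out


def _window_log_ratios(data: _WindowData, motif: Motif,
                       background: Background) -> np.ndarray:
    lr = _extended_log_ratios(motif, background)
    out = lr[0][data.W[:, 0]]
    for k in range(1, data.width):
        out += lr[k][data.W[:, k]]
    return out


def seed_starts(
    seqs: SequenceSet,
    width: int,
    n_starts: int,
    background: Background | None = None,
    weights: np.ndarray | None = None,
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
    seed: int = 0,
    both_strands: bool | None = None,
) -> list[Motif]:
    """Candidate starting motifs built from observed subsequences.

    Each distinct width-``width`` subsequence becomes a soft consensus
    matrix (probability 0.7 on the observed letter, the rest spread
    evenly); the ``n_starts`` candidates with the highest one-pass OOPS
    likelihood are returned, best first.  When more than
    ``max_candidates`` distinct subsequences exist, only the most
    recurrent ones are evaluated (deterministic).
    """
    if background is None:
        background = uniform_background(seqs.alphabet)
    data = _WindowData(seqs, width)
    alph = seqs.alphabet
    if both_strands is None:
        both_strands = alph.is_nucleotide

    core_rows = data.W < alph.size
    clean = core_rows.all(axis=1)
    if weights is not None:
        lw = data.log_window_weights(weights)
        clean &= np.isfinite(lw)
    cand_idx = np.flatnonzero(clean)
    # dedupe identical subsequences, tracking multiplicity
    words: dict[bytes, int] = {}
    mult: dict[bytes, int] = {}
    for j in cand_idx:
        key = data.W[j].tobytes()
        words.setdefault(key, j)
        mult[key] = mult.get(key, 0) + 1
    cand = list(words.values())
    if len(cand) > max_candidates:
        # prefer recurrent subsequences: a word shared by many sequences is
        # a far better start than a singleton, and the choice stays
        # deterministic
        keys = sorted(words, key=lambda k: (-mult[k], words[k]))
        cand = [words[k] for k in keys[:max_candidates]]
        cand.sort()
    if not cand:
        raise ValueError("no candidate subsequences free of ambiguity letters")

    lww = data.log_window_weights(weights)
    seed_rows = data.W[cand].astype(np.int64)          # S x w core indices
    llrs = _batched_seed_llrs(data, seed_rows, background, lww, both_strands)
    order = sorted(range(len(cand)), key=lambda i: (-llrs[i], cand[i]))
    A = alph.size
    miss = (1.0 - SEED_MATCH_PROBABILITY) / (A - 1)
    starts = []
    for i in order[:n_starts]:
        seed_probs = np.full((width, A), miss)
        seed_probs[np.arange(width), seed_rows[i]] = SEED_MATCH_PROBABILITY
        starts.append(Motif(name="seed", alphabet=alph,
                            probabilities=seed_probs, nsites=len(seqs)))
    return starts


def _batched_seed_llrs(data, seed_rows, background, lww, both_strands,
                       chunk: int = 64) -> np.ndarray:
    """One-pass OOPS LLR of every candidate seed, computed jointly.

    A seed matrix takes only two values per column (match/miss), so a
    window's log-ratio splits into a seed-independent base term plus a
    membership correction gathered from an A x n_extended table.
    """
    alph = data.alphabet
    A = alph.size
    m = SEED_MATCH_PROBABILITY
    miss = (1.0 - m) / (A - 1)
    bgf = background.frequencies
    n_ext = len(alph.extended_symbols)
    val_match = np.empty(n_ext)
    val_miss = np.empty(n_ext)
    member = np.zeros((A, n_ext), dtype=bool)
    for e, letter in enumerate(alph.extended_symbols):
        if e < A:
            val_match[e] = np.log(m / bgf[e])
            val_miss[e] = np.log(miss / bgf[e])
            member[e, e] = True
        else:
            idx = [alph.index(c) for c in alph.ambiguity_map[letter]]
            bgmass = bgf[idx].sum()
            val_match[e] = np.log((m + (len(idx) - 1) * miss) / bgmass)
            val_miss[e] = np.log(len(idx) * miss / bgmass)
            member[idx, e] = True
    memberdiff = member * (val_match - val_miss)[None, :]   # A x n_ext

    base = lww.copy()
    for k in range(data.width):
        base += val_miss[data.W[:, k]]

    strands = [seed_rows]
    if both_strands:
        perm = alph.complement_permutation()
        strands.append(perm[seed_rows[:, ::-1]])
    log_m = data.segment_logsumexp(lww[None, :]) + np.log(len(strands))
    ok = np.isfinite(log_m)       # skip fully erased sequences

    # contribution of "seed column k is core letter a" to every window score
    Dm = np.empty((data.width, A, data.n_windows))
    for k in range(data.width):
        col = data.W[:, k]
        for a in range(A):
            Dm[k, a] = memberdiff[a][col]

    S = len(seed_rows)
    llrs = np.empty(S)
    R = np.empty(data.n_windows)
    for s in range(S):
        lse = None
        for rows in strands:
            np.copyto(R, base)
            for k in range(data.width):
                R += Dm[k, rows[s, k]]
            part = _segment_lse(R[None, :], data.seg_starts)[0]
            lse = part if lse is None else np.logaddexp(lse, part)
        llrs[s] = (lse[ok] - log_m[ok]).sum()
    return llrs


def _oops_llr(data, motif, background, log_weights, both_strands) -> float:
    lr = _window_log_ratios(data, motif, background)
    rows = [lr + log_weights]
    if both_strands:
        rc = _window_log_ratios(data, motif.reverse_complement(), background)
        rows.append(rc + log_weights)
    rows = np.stack(rows)
    base = np.broadcast_to(log_weights, rows.shape)
    lse = data.segment_logsumexp(rows)
    log_m = data.segment_logsumexp(base)
    ok = np.isfinite(log_m)       # fully erased sequences contribute nothing
    return float((lse[ok] - log_m[ok]).sum())


def run_em(
    seqs: SequenceSet,
    init: Motif,
    model: SiteModel = SiteModel("OOPS"),
    background: Background | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    pseudocount_total: float = 1.0,
    weights: np.ndarray | None = None,
    both_strands: bool | None = None,
) -> EMResult:
    """EM until the penalized objective's relative change drops below ``tol``.

    The E-step computes posterior site probabilities at every admissible
    window (both strands for nucleotides); the M-step re-estimates the
    motif from posterior-weighted counts with background-proportional
    pseudocounts and re-estimates the site prior for ZOOPS/ANR.
    ``weights`` are per-position erasing weights in [0, 1].
    """
    alph = seqs.alphabet
    if background is None:
        background = uniform_background(alph)
    if both_strands is None:
        both_strands = alph.is_nucleotide
    data = _WindowData(seqs, init.width)
    lww = data.log_window_weights(weights)
    n_strands = 2 if both_strands else 1
    gamma = model.gamma
    motif = init
    w, A = init.width, alph.size
    comp_perm = alph.complement_permutation() if both_strands else None
    alpha = float(pseudocount_total)

    trace: list[float] = []
    post = None
    for iteration in range(max_iter):
        # ---- E-step
        lrs = [_window_log_ratios(data, motif, background)]
        if both_strands:
            lrs.append(_window_log_ratios(data, motif.reverse_complement(),
                                          background))
        loglik, post, z_total = _estep(data, lrs, lww, model, gamma, n_strands)
        penalty = alpha * float(
            (background.frequencies * np.log(motif.probabilities)).sum()
        )
        trace.append(loglik + penalty)
        if len(trace) >= 2:
            prev, cur = trace[-2], trace[-1]
            if abs(cur - prev) <= tol * max(1.0, abs(prev)):
                break
        # ---- M-step
        n_ext = len(alph.extended_symbols)
        fwd = post[: data.n_windows]
        counts = _weighted_letter_counts(data.W, fwd, w, n_ext)
        if both_strands:
            rev = post[data.n_windows:]
            rev_counts = _weighted_letter_counts(data.W, rev, w, n_ext)
            core_rc = _fold_ambiguity(rev_counts, alph, background)
            counts_core = _fold_ambiguity(counts, alph, background)
            # complement is an involution, so the permutation is self-inverse
            counts_core += core_rc[::-1][:, comp_perm]
        else:
            counts_core = _fold_ambiguity(counts, alph, background)
        nsites = max(float(post.sum()), 1e-12)
        probs = (counts_core + alpha * background.frequencies) / (
            counts_core.sum(axis=1, keepdims=True) + alpha
        )
        motif = Motif(name=init.name, alphabet=alph, probabilities=probs,
                      nsites=max(nsites, 1e-6))
        if model.kind == "ZOOPS":
            gamma = float(np.clip(z_total / len(seqs), 1e-6, 1.0))
        elif model.kind == "ANR":
            gamma = float(np.clip(post.sum() / (data.n_windows * n_strands),
                                  1e-9, 0.999))

    llr = _data_llr(data, motif, background, lww, model, gamma, n_strands)
    sites = _extract_sites(data, post, model, n_strands)
    return EMResult(motif=motif, sites=sites, llr=llr, trace=trace,
                    model=SiteModel(model.kind, gamma if model.kind != "OOPS"
                                    else model.gamma),
                    window_posteriors=post, n_iterations=len(trace))


def _weighted_letter_counts(W, weights, width, n_ext):
    """counts[k, a] = sum of window weights whose column k shows letter a."""
    counts = np.empty((width, n_ext))
    for k in range(width):
        counts[k] = np.bincount(W[:, k].astype(np.int64), weights=weights,
                                minlength=n_ext)
    return counts


def _fold_ambiguity(counts_ext, alph, background):
    """Fold expected counts on ambiguity letters into core letters,
    split by background weight over the expansion."""
    core = counts_ext[:, : alph.size].copy()
    for j, (amb, exp) in enumerate(alph.ambiguity_map.items()):
        col = counts_ext[:, alph.size + j]
        if not col.any():
            continue
        idx = [alph.index(c) for c in exp]
        wts = background.frequencies[idx]
        wts = wts / wts.sum()
        core[:, idx] += col[:, None] * wts[None, :]
    return core


def _estep(data, lrs, lww, model, gamma, n_strands):
    """Posterior site probabilities and the data log-likelihood ratio."""
    rows = np.stack([lr + lww for lr in lrs])       # n_strands x n_windows
    if model.kind in ("OOPS", "ZOOPS"):
        base = np.broadcast_to(lww, rows.shape)
        lse = data.segment_logsumexp(rows)           # per sequence
        log_m = data.segment_logsumexp(base)         # effective window count
        ok = np.isfinite(log_m)   # fully erased sequences contribute nothing
        ok_w = ok[data.seq_index][None, :]
        if model.kind == "OOPS":
            loglik = float((lse[ok] - log_m[ok]).sum())
            with np.errstate(invalid="ignore"):
                post = np.where(ok_w, np.exp(rows - lse[data.seq_index][None, :]),
                                0.0)
            z_total = float(ok.sum())
        else:
            with np.errstate(invalid="ignore"):
                site_log = np.where(ok, math.log(gamma) + lse - log_m, -np.inf)
            seq_ll = np.logaddexp(math.log1p(-gamma), site_log)
            loglik = float(seq_ll[ok].sum())
            with np.errstate(invalid="ignore"):
                post = np.where(
                    ok_w,
                    np.exp(rows - log_m[data.seq_index][None, :]
                           + math.log(gamma) - seq_ll[data.seq_index][None, :]),
                    0.0,
                )
            z_total = float(np.exp(site_log[ok] - seq_ll[ok]).sum())
    else:  # ANR: independent windows
        u = np.exp(np.broadcast_to(lww, rows.shape))
        r = np.exp(rows - lww[None, :])
        site = gamma * u * r
        denom = site + (1.0 - gamma * u)
        loglik = float(np.log(denom).sum())
        post = site / denom
        z_total = float(post.sum())
    return loglik, post.reshape(-1), z_total


def _data_llr(data, motif, background, lww, model, gamma, n_strands):
    lrs = [_window_log_ratios(data, motif, background)]
    if n_strands == 2:
        lrs.append(_window_log_ratios(data, motif.reverse_complement(),
                                      background))
    loglik, _, _ = _estep(data, lrs, lww, model, gamma, n_strands)
    return loglik


def _extract_sites(data, post, model, n_strands) -> list[Site]:
    sites = []
    for (a, b), seq_id in zip(data.seq_slices, data.seq_ids):
        idx = np.concatenate(
            [np.arange(s * data.n_windows + a, s * data.n_windows + b)
             for s in range(n_strands)]
        )
        vals = post[idx]
        if model.kind == "ANR":
            for k in np.flatnonzero(vals > 0.5):
                j = int(idx[k])
                strand = "-" if j >= data.n_windows else "+"
                sites.append(Site(seq_id, (j % data.n_windows) - a, strand,
                                  float(vals[k])))
            continue
        k = int(np.argmax(vals))
        total = float(vals.sum())
        if model.kind == "ZOOPS" and total < 0.5:
            continue
        j = int(idx[k])
        strand = "-" if j >= data.n_windows else "+"
        sites.append(Site(seq_id, (j % data.n_windows) - a, strand,
                          float(vals[k])))
    return sites


# --------------------------------------------------------------------------
# Significance

# Calibration constants for the E-value estimate: typical converged data LLR
# per sequence on background-only inputs (OOPS, 10 x 100-letter sequences,
# uniform background), by motif width.  Values between table widths are
# linearly interpolated; outside, the nearest entry is used.
_LLR0_PER_SEQUENCE = {
    4: 0.29,
    6: 1.11,
    8: 1.84,
    11: 3.07,
    15: 4.30,
    20: 5.72,
}


def _llr0(width: int, n_sequences: int) -> float:
    ws = sorted(_LLR0_PER_SEQUENCE)
    if width <= ws[0]:
        c = _LLR0_PER_SEQUENCE[ws[0]]
    elif width >= ws[-1]:
        c = _LLR0_PER_SEQUENCE[ws[-1]]
    else:
        hi = next(w for w in ws if w >= width)
        lo = max(w for w in ws if w <= width)
        if lo == hi:
            c = _LLR0_PER_SEQUENCE[lo]
        else:
            t = (width - lo) / (hi - lo)
            c = (1 - t) * _LLR0_PER_SEQUENCE[lo] + t * _LLR0_PER_SEQUENCE[hi]
    return c * n_sequences


def motif_significance(
    loglik_ratio: float,
    width: int,
    nsites: float,
    n_tests: int,
    seqs: SequenceSet,
) -> float:
    """Conservative E-value estimate for a fitted motif.

    ``E = n_tests * exp(-(max(0, LLR - LLR0)))`` where ``LLR0`` is the
    calibrated background-only LLR level for this width and sequence count.
    Monotone decreasing in the LLR, linear in the number of starts tested;
    a motif indistinguishable from the background gets the maximal value
    ``n_tests``.
    """
    excess = max(0.0, loglik_ratio - _llr0(width, len(seqs)))
    return float(n_tests) * math.exp(-excess)


# --------------------------------------------------------------------------
# Multiple motifs

def erase_and_repeat(
    seqs: SequenceSet,
    fit: EMResult,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Down-weight positions covered by the fitted motif's sites.

    Each position under a window gets its weight multiplied by
    ``1 - posterior`` (floored at 0), so subsequent discovery rounds avoid
    re-finding the same sites.  Returns the new per-position weight array.
    """
    data = _WindowData(seqs, fit.motif.width)
    if weights is None:
        weights = np.ones(data.n_positions)
    else:
        weights = weights.copy()
    post = fit.window_posteriors
    n_strands = len(post) // data.n_windows
    w = fit.motif.width
    # a position is kept with probability prod over covering windows of
    # (1 - posterior); accumulate in log space via a length-w convolution
    with np.errstate(divide="ignore"):
        lg = np.log1p(-np.clip(post.reshape(n_strands, data.n_windows), 0.0,
                               1.0)).sum(axis=0)
    log_keep = np.zeros(data.n_positions)
    kernel = np.ones(w)
    for (a, b), p0 in zip(data.seq_slices,
                          data.P[[a for a, _ in data.seq_slices], 0]):
        seg = np.convolve(lg[a:b], kernel, mode="full")  # length m + w - 1
        log_keep[p0 : p0 + (b - a) + w - 1] += seg
    return np.clip(weights * np.exp(log_keep), 0.0, 1.0)


def discover_motifs(
    seqs: SequenceSet,
    min_width: int,
    max_width: int,
    n_motifs: int = 1,
    model: SiteModel = SiteModel("OOPS"),
    background: Background | None = None,
    seed: int = 0,
    n_starts: int = DEFAULT_N_STARTS,
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    both_strands: bool | None = None,
) -> DiscoveryResult:
    """Sequential multi-motif discovery with probabilistic erasing.

    For each requested motif, seeded EM runs at every integer width in
    the range: every start gets a short (4-iteration) EM pass, the start
    with the best E-value estimate is refined to convergence, the best
    width's fit is kept, its sites are erased, and the search repeats.
    Deterministic given ``seed``.
    """
    if n_motifs < 1:
        raise ValueError("n_motifs must be at least 1")
    if not (1 <= min_width <= max_width <= seqs.min_length()):
        raise ValueError(
            f"need 1 <= min_width <= max_width <= shortest sequence; got "
            f"[{min_width}, {max_width}] with shortest {seqs.min_length()}"
        )
    if background is None:
        background = uniform_background(seqs.alphabet)
    if both_strands is None:
        both_strands = seqs.alphabet.is_nucleotide

    result = DiscoveryResult()
    weights = None
    n_tests_per_width = n_starts
    for round_no in range(n_motifs):
        best: tuple[float, EMResult] | None = None
        for width in range(min_width, max_width + 1):
            try:
                starts = seed_starts(
                    seqs, width, n_starts, background, weights=weights,
                    max_candidates=max_candidates,
                    seed=seed + 7919 * round_no + width,
                    both_strands=both_strands,
                )
            except ValueError:
                continue
            short_fits = [
                run_em(seqs, s, model, background, max_iter=4, tol=tol,
                       weights=weights, both_strands=both_strands)
                for s in starts
            ]
            n_tests = n_tests_per_width * (max_width - min_width + 1)
            evals = [
                motif_significance(f.llr, width, f.motif.nsites, n_tests, seqs)
                for f in short_fits
            ]
            pick = int(np.argmin(evals))
            fit = run_em(seqs, short_fits[pick].motif, model, background,
                         max_iter=max_iter, tol=tol, weights=weights,
                         both_strands=both_strands)
            evalue = motif_significance(fit.llr, width, fit.motif.nsites,
                                        n_tests, seqs)
            if best is None or evalue < best[0]:
                best = (evalue, fit)
        if best is None:
            break
        evalue, fit = best
        motif = Motif(
            name=f"motif-{round_no + 1}", alphabet=fit.motif.alphabet,
            probabilities=fit.motif.probabilities, nsites=fit.motif.nsites,
            evalue=evalue,
        )
        fit.motif = motif
        result.motifs.append(motif)
        result.fits.append(fit)
        weights = erase_and_repeat(seqs, fit, weights)
    result.sort()
    return result
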