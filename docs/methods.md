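# Methods

This note documents the models, statistics and numerical choices behind
motifkit, and what its synthetic benchmarks do and do not demonstrate.

## The motif model

A motif is a fixed-width position probability matrix (PPM): `w` rows, one
probability vector over the core alphabet per row. Insertions and
deletions are not representable. Scoring uses the log-odds form
`s(i, a) = log2 p(i, a) / b(a)` against a zero-order background `b`; all
log quantities are in bits. Information content per column is the
relative entropy `IC(i) = Σ_a p(i,a) log2(p(i,a)/b(a))` — the sequence-logo
letter-height quantity.

Pseudocounts are background-proportional throughout: a total mass `α`
distributed as `α·b(a)` per letter. This keeps log-odds finite and exactly
zero for a column identical to the background. Matrices built from raw
sites (typed motifs, word-discovery output) keep their zeros; consumers
that need finite log-odds (scanning, comparison, sequence scoring) blend
in `α = 0.1` at conversion time, following the convention of
occurrence scanners. Background models must be strictly positive and are
estimated with ambiguity letters contributing fractionally over their
IUPAC expansion; lowercase input is uppercased on ingest so repeat-masked
FASTA passes through (masked letters arrive as N and score neutrally —
the background-weighted average over the expansion).

## Exact scan p-values

Log-odds scores are integerized onto `0..1000` per cell (affine map over
the score range; the quantization error of a total window score is at
most half a quantum per position). The null distribution of the total
integer score of a background window is computed exactly by position-wise
convolution of the per-letter score distributions — cost `O(w² · bins)` —
and the p-value of a window is the right tail of that distribution. With
1000 bins the difference from the unquantized p-value is negligible at
any width used here; the test suite checks exact agreement with
brute-force enumeration over all `4^w` words for widths ≤ 5 and binomial
calibration on 100k background windows.

Both strands of a nucleotide sequence are scanned; the two window scores
at one position are two separate tests, and q-values use
Benjamini–Hochberg with `m` = the number of scored windows, not the
number of reported hits — sub-threshold windows are still tests, and the
calibration property requires counting them.

## EM discovery

`discover_em` fits the standard finite-mixture site model: each length-w
window is motif or background, with OOPS (one site per sequence), ZOOPS
(zero or one; per-sequence prior γ) or ANR (independent windows;
per-window prior γ) site-count structure. The E-step computes posterior
site probabilities over all windows and both strands; the M-step
re-estimates the PPM from posterior-weighted letter counts plus
background-proportional pseudocounts (`α = 1`), and re-estimates γ for
ZOOPS/ANR.

The monotone quantity is the penalized objective — data log-likelihood
ratio plus the Dirichlet pseudocount prior term — which MAP-EM ascends by
construction; the suite asserts non-decrease to 1e-9 slack. The raw data
LLR is reported separately and feeds the significance estimate.

A note on ZOOPS γ: because the expected motif/background probability
ratio of a background window is exactly 1, the ZOOPS likelihood is nearly
flat in γ above the true site fraction, and the ML estimate often drifts
toward 1 (ZOOPS then degenerates gracefully to OOPS). γ is therefore
informative as a lower bound on the site fraction, not a point estimate.

Starting points are built from observed subsequences: probability 0.7 on
the observed letter, the remainder spread evenly (keeping matrices
strictly positive), ranked by their one-pass OOPS likelihood. When the
number of distinct subsequences exceeds `max_candidates` (default 2000),
the most *recurrent* subsequences are evaluated — a word shared by many
sequences is a far better start than a singleton, and the rule is
deterministic. Each retained start gets a 4-iteration EM pass; the most
promising start is refined to convergence (relative objective change
below 1e-6, at most 200 iterations). The width range is searched
exhaustively at every integer width.

Multiple motifs are found by probabilistic erasing: each position covered
by a discovered site keeps weight `Π (1 − posterior)` over the covering
windows, so subsequent rounds down-weight — without hard-masking — the
explained signal.

### E-values

The discovery E-value is `E = n_tests · exp(−max(0, LLR − LLR0))`, with
`n_tests` the number of starts examined across the width range and `LLR0`
a width-dependent calibration constant: the typical converged
background-only LLR (per sequence, times the number of sequences), fitted
once on background simulations at 10 × 100-letter scale and shipped as a
constant table with linear interpolation in width. This estimator is
deliberately conservative and is *not* the statistic of any published
discovery tool; it preserves the properties that matter operationally —
monotone decreasing in LLR, linear in the multiplicity of the search, and
maximal (= `n_tests`) for a motif indistinguishable from background.
Because `LLR0` grows linearly in the number of sequences while background
overfitting grows sublinearly, E-values at larger n are increasingly
conservative; rankings are unaffected.

## Word discovery

`discover_words` is the discrete, discriminative engine for short
nucleotide motifs. All exact words of length 3–8 (defaults) present in
the positive set are counted at the *sequence* level (present/absent,
both strands pooled into a canonical orientation), making Fisher's exact
test — the right tail of the hypergeometric — exact and robust to site
multiplicity. When no negative set is supplied, a per-sequence
dinucleotide-preserving shuffle (Altschul–Erickson Eulerian-path
construction) provides the control; it preserves each sequence's length
and dinucleotide multiset exactly.

The best word is generalized greedily: single-position IUPAC relaxations
are accepted while the p-value strictly improves. The E-value is
Bonferroni-style — p times the number of words actually tested (exact
words plus relaxations), recomputable from the reported counters. After a
word is accepted, its matching sites are masked to N and enumeration
repeats, so no word is reported twice. The greedy search and the
Bonferroni correction are this package's own documented choices, not a
reconstruction of any published tool's search.

## Sequence-level scoring

For ranking whole sequences (proteins, promoters) against a motif set,
each motif contributes its best window p-value corrected for multiplicity
by the minimum-of-n-uniforms law, `p_seq = 1 − (1 − p_min)^n`, with `n`
the number of windows pooled over strands — this removes length bias
between sequences. The per-motif values are combined with the exact tail
of a product of independent uniforms,
`P(Π U_i ≤ x) = x · Σ_{k<n} (−ln x)^k / k!`, evaluated in log space. The
E-value is the combined p times the number of sequences scanned. On
background data the combined p-values are approximately uniform
(Kolmogorov–Smirnov statistic < 0.02 at 10k sequences) — the residual
deviation comes from overlapping-window dependence, and from p-value
discreteness when a motif is nearly deterministic.

Block diagrams select non-overlapping sites greedily, best p first, at
threshold 1e-4; display heights are `−log10 p` truncated at the height of
`p = 1e-10`.

## Motif comparison

Comparison slides the query over each target at every offset with at
least `min_overlap = 4` aligned columns, in both orientations for
nucleotides. The score sums per-column similarities (Pearson correlation
by default; negative Euclidean distance as an alternative) over the
overlap, with unaligned *query* columns contributing the metric's null
value (0 for Pearson; minus the distance to the background column for the
Euclidean metric) so single-column overlaps cannot win. Ties break toward
larger overlap, then smaller |offset|, then the forward orientation.

Significance is a Monte-Carlo permutation null: the best-alignment score
of the query against 1000 independently column-shuffled copies of the
target, `p = (1 + #{null ≥ observed}) / 1001`. This null is assumption-
light and exactly testable (uniform by exchangeability), at the cost of a
resolution floor of ~1e-3 and weak power for self-comparison of
low-complexity motifs (a column permutation of a repetitive motif can
resemble the original). Column shuffling permutes the columns of the
precomputed query-target similarity matrix, so the 1000 null alignments
reuse one matrix and cost little.

## Central enrichment

For equal-length sequence sets (ChIP-seq peak windows), the best-scoring
site per sequence (default site threshold p ≤ 1e-3) is reduced to its
center offset from the sequence midpoint. Every centered window of
admissible start positions (odd sizes when `L − w` is even, even sizes
otherwise — the centered family is one-dimensional either way) is tested
with a binomial right tail against uniform placement
(`π = size / (L − w + 1)`), and the best window's p is Bonferroni-
corrected by the number of windows tested. Bonferroni is conservative —
under the uniform null the adjusted p exceeds 0.05 in well over 90% of
replicates — which is the right failure mode for a confirmatory screen.
Ties between equally good windows resolve to the smaller window; ties
between equally good sites to the leftmost, then the forward strand.

Because discovery never uses positional information (the pipeline hands
discovery a shuffled sequence order, and centrality consumes only hit
positions), central enrichment of a discovered motif is an independent
line of evidence that it reflects direct binding.

## Synthetic data

`generate_planted_dataset` draws i.i.d. letters from the background and
overwrites planted sites: each site column is sampled from the motif row,
then mutated with the per-column mutation rate (replaced by a uniformly
random different letter); placement is uniform or Gaussian around the
midpoint (clipped); orientation is fixed or random per the strand policy;
overlapping plants within a sequence are re-drawn up to 100 times. The
truth table records every planted site.

Benchmark conditions used by the test suite and the acceptance script:

* discovery recovery: 10 sequences × 100 bp, one ~11.6-bit 6-mer site per
  sequence, width fixed at the planted width;
* peak pipeline: 200 peaks × 500 bp, one ~15-bit 8-mer planted in 80% of
  peaks, Gaussian placement sd = L/10, per-column mutation 5%, random
  strand, a database of the planted motif plus 9 random decoys, discovery
  at the planted width with 10 starts over the 300 most recurrent
  subsequence candidates;
* calibration checks: 100k background windows (scan), 10k background
  sequences (combined p), 200 uniform-placement replicates (centrality).

What this generator does not emulate: correlated (higher-order)
background composition, repeats, variable peak widths, site clustering
and homotypic runs, sequencing artifacts. Passing these benchmarks shows
the statistics are correct and the search recovers signal under the
stated conditions; it does not bound performance on real genomes, where
background model misfit is usually the dominant error source.

## Limitations

* Zero-order background only; no position-specific priors.
* Fixed-width motifs; no gapped models.
* The discovery E-value is a calibrated surrogate (above), comparable
  within a run, not across tools.
* ZOOPS γ is weakly identified (above).
* Word discovery is nucleotide-only by design.
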