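# motifkit

Motif-based sequence analysis for DNA, RNA and protein sequences: de novo
motif discovery, motif scanning with exact p-values, sequence-level
scoring, motif–motif comparison, and central positional enrichment for
ChIP-seq-style peak sets — as a Python library with a thin command-line
interface.

Sequence motifs — short, fixed-width conserved patterns such as
transcription-factor binding sites or protein interaction signals — are
modeled throughout as position probability matrices: a motif of width *w*
is a matrix *p(i, a)* giving the probability of letter *a* at position
*i*. Scoring uses the log-odds form against a zero-order background
*b(a)*,

    s(i, a) = log2( p(i, a) / b(a) )   (bits),

and a column's information content is its relative entropy
IC(i) = Σ_a p(i,a) log2(p(i,a)/b(a)), the sequence-logo letter height.

## What's inside

| module | role |
|---|---|
| `motifkit.core` | alphabets (IUPAC), backgrounds, sequences, the motif matrix model |
| `motifkit.formats` | FASTA, the minimal motif exchange format, typed-motif auto-detection |
| `motifkit.discover_em` | probabilistic discovery: EM with OOPS / ZOOPS / ANR site models, multi-motif erasing |
| `motifkit.discover_words` | discriminative short-word discovery with Fisher exact enrichment against a dinucleotide-shuffled control |
| `motifkit.scan` | occurrence scanning: exact p-values by dynamic programming, BH q-values |
| `motifkit.seqscore` | sequence-level multi-motif scoring: combined p-values, E-values, block diagrams |
| `motifkit.compare` | motif–motif alignment over all offsets/orientations with a permutation null |
| `motifkit.centrality` | central enrichment of best sites in equal-length sequences (binomial test) |
| `motifkit.workbench` | planted-motif synthetic data, the integrated peak pipeline, iterative refinement |

Scan p-values are *exact* under the background model: window scores are
integerized and their full null distribution is computed by convolution,
so a reported p-value is the true tail probability of the score, not an
approximation. See `docs/methods.md` for every statistic's definition and
the design choices behind it.

## Worked example

Analyze 200 synthetic 500-bp "peaks" with an 8-bp motif planted near the
center of 80% of them (5% per-column mutation, random strand), against a
one-entry motif database:

```python
import motifkit as mk

dna = mk.make_alphabet("DNA")
bg = mk.uniform_background(dna)

# a known 8-bp motif, typed as aligned sites
known = mk.parse_typed_motifs(
    "TGACTCAG\nTGACTCAG\nTGAGTCAG\nTGACTCAT\nTGACTAAG", dna
)[0].renamed("known-8mer")

seqs, truth = mk.generate_planted_dataset(
    200, 500, bg,
    [mk.PlantSpec(known, occurrence=0.8, placement="central", sd=50,
                  mutation_rate=0.05, strand="both")],
    seed=42,
)
report = mk.run_peak_pipeline(seqs, [known], seed=7, min_width=8,
                              max_width=8, n_motifs=1, n_starts=10,
                              max_candidates=300)
print(report.summary())
```

Output:

```
Peak pipeline report
====================
[1] word-1 (words) w=7 E=5.84e-29
    best database match: known-8mer (p=0.002, offset=0, +)
    central enrichment: adjusted p=3.48e-30 (112/136 sites in best window of 162)
[2] motif-1 (em) w=8 E=10
    best database match: known-8mer (p=0.000999, offset=0, +)
    central enrichment: adjusted p=4.28e-33 (150/183 sites in best window of 183)
Database motifs by central enrichment:
    known-8mer: adjusted p=2.84e-34
```

Reading this: both discovery engines recover the planted pattern (the
word engine reports a 7-mer core with E ≈ 6e-29; the EM engine the full
8-mer — its E-value estimator is deliberately conservative, see the
methods note). Each discovered motif aligns to the database entry at
offset 0 (comparison p ≈ 1e-3, the resolution floor of the 1000-shuffle
permutation null), and each is strongly centrally enriched — e.g. 150 of
183 best sites inside the best centered window, Bonferroni-adjusted
binomial p ≈ 4e-33. Discovery never sees positional information, so the
central enrichment is independent evidence that the motif is real.

## Command line

The `motifkit` command wraps the library:

```
motifkit discover em peaks.fa --minw 6 --maxw 12 --nmotifs 2 --output found.meme
motifkit discover words peaks.fa --e-thresh 0.05 --tsv words.tsv
motifkit scan sites found.meme genome.fa > hits.tsv
motifkit scan sequences found.meme proteome.fa > ranked.tsv
motifkit compare found.meme database.meme > matches.tsv
motifkit enrich central database.meme peaks.fa > centrality.tsv
motifkit pipeline peaks peaks.fa database.meme --json-out report.json
motifkit fixtures generate --n 200 --length 500 --motifs known.meme --output peaks.fa
motifkit refine found.meme proteome.fa --region-length 150
```

All stochastic stages accept `--seed`; a `key = value` config file
(`--config`) can supply defaults for any flag.

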