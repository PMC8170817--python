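# Methods

## Problem and model

`insec` corrects substitution errors in the short reads relevant to one
target gene. Two assumptions drive the design: the gene reference `I_g` is
*not* error-free (the individual's true sequence `T_g` differs from it by
SNPs), and substitution errors are rare (~0.5–2% per base, Illumina-like)
and essentially random. Consequently the corrector never trusts the
reference base at a covered position — evidence comes from the column of
read bases itself — and a base disagreeing with nearly all of its column
is, with high probability, an error rather than a variant.

### Extraction

The reference is extended with up to `flank` (default 50) bases of genomic
context per side, truncated at contig ends, so reads straddling the gene
boundary by up to the flank length are still captured. The built-in mapper
is ungapped seed-and-verify: exact k-mer seeds (k = 16) probed at every
position of the read and of its reverse complement propose diagonals, each
distinct diagonal is verified by a full Hamming count, and the best
placement is kept if identity ≥ `min_identity` (default 95%). The
threshold is read as *percent identity* (≤5 mismatches per 100 bp): an
absolute Hamming budget of 95 would accept everything, while 95% identity
is exactly "noise tolerance" — room for ~1–2 sequencing errors plus SNP
mismatches without admitting unrelated sequence.

k = 16 with exhaustive probing is a deliberate choice: at most
`⌊0.05·n⌋` mismatches in a read of length n ≥ 96 leave a clean stretch of
at least 16 bases (pigeonhole over the ≤6 runs between mismatches), so a
qualifying read always has an exact seed and extraction is deterministic,
not probabilistic. Longer sampled seeds cannot guarantee this — five
evenly spread mismatches in a 100 bp read cap the longest clean run at 16.

Ties between equal-mismatch placements go to the smallest offset, then the
forward strand. Indels never enter via the built-in mapper; they arrive
only through SAM import, where insertions are stripped (those bases leave
the array) and deletions become gap cells that carry no base evidence.
Mates of a pair are extracted independently; pairing information is not
used by the corrector.

### Column dominance

For a column with `depth` non-gap bases, the dominance is the smallest
m ∈ {1,2,3} such that the m most frequent non-N types leave a remainder of
at most `minor_count` (default 3) bases, or at most a `minor_frac`
(default 2%) fraction when depth ≥ `min_depth_for_frac` (default 100);
otherwise the column is four-type and untouched. Choices fixed here:

- the minor-fraction test is **inclusive** (≤ 2%): a column split
  58% / 40% / 1.2% / 0.8% is two-type dominant, matching the intended
  behaviour of the rule at its boundary;
- frequency ties are broken in the fixed base order A<C<G<T, making
  classification and every downstream choice deterministic;
- N is never dominant and is always a correction candidate; gap cells
  count toward neither depth nor candidates;
- a column containing only N (or empty) cannot anchor a correction and is
  treated as four-type.

The smallest-m rule resolves the case where several classifications fit:
one-type dominance is preferred over two-type over three-type, which is
also the order in which corrections are prioritized.

### Row-wise conservative correction

Every minor-type cell in a dominance-1/2/3 column scores
`f + p` — its type frequency in the column plus 0.1/0.2/0.3 by column
dominance — so outliers at simpler columns rank first. Per read, the
`⌈row_error_frac · n⌉` lowest-scoring candidates (2 for a 100 bp read at
the default 2%) are corrected in one pass: to the dominant base at
one-type columns; at two/three-type columns the candidates of a column are
partitioned among the dominant types proportionally to their renormalized
frequencies (largest-remainder rounding, so 98 candidates at 40%/58%
become exactly 40 and 58), after a phasing step — if the candidate's own
read carries a dominant base at the nearest two/three-type column within
±50 bp, the dominant type that co-occurs with that base in the majority of
other reads is preferred. Residual ties are resolved by a seeded shuffle
(default seed 42), the only randomness in the corrector.

**Passes iterate to convergence.** One pass changes at most `⌈0.02·n⌉`
cells per read — the conservative budget matching the expected error count
of an Illumina read. A read can carry more errors than that: with 1%
errors per 100 bp, ~8% of reads have 3+, and a single capped pass would
leave ~10% of all errors untouched, capping gain near 90%. The driver
(`correct_array`) therefore repeats the pass (default `max_passes` 8,
typically ≤4 needed) until a pass changes nothing; each pass re-profiles
the columns, so later corrections are still confirmed against updated
evidence and the per-pass budget is never exceeded. `correct_rows` exposes
exactly one pass.

### Repeat ('out') reads

A read from a repeat of the gene elsewhere in the genome survives
extraction, but in the array it disagrees with the column profile
*consistently* — at several columns, with non-trivial frequency — rather
than randomly. The rule: if more than one of a read's ranked candidates
scores above `out_threshold`, the read is labeled `out` and removed before
consensus building. The threshold (default 0.2, exposed as
`--out-threshold`) sits just above the maximum possible score of a genuine
error in a one-type column (f < 0.1 there by construction, score < 0.2)
and below any candidate at a two/three-type column (p ≥ 0.2): repeat
alleles that form secondary haplotype structure trip it, isolated
sequencing errors never do.

### Consensus and evaluation

The consensus emits, per column, the most frequent A/C/G/T among retained
rows (ties in base order; at two/three-type columns this is the
top-frequency dominant type), falling back to the reference base at
zero-coverage columns, then trims the flanks to gene length. Planted SNP
alleles therefore reach the consensus: the reads dominate, not `I_g`.

Evaluation matches corrected to original reads by id. An injected error
restored exactly to its true base is a TP (a change to a third base counts
FN *and* FP — the error remains and a wrong base was written); reads
removed as `out` leave the corrected set and are excluded from the
tallies, reported separately. Zero-denominator metrics use fixed
sentinels (flagged in the report): precision 100 when nothing changed,
recall/gain 100 when there were no errors and no false changes, gain NA
when there were no errors but false changes exist.

## Synthetic data

The generator emulates a reduced-scale whole-genome resequencing study:
i.i.d. uniform A/C/G/T genome; gene intervals cut from it as `I_g`; an
individual genome mutated at `snp_rate` (default 0.001) from which reads
are drawn, so reference and truth genuinely differ; uniformly placed reads
on both strands at `coverage` (default 30×), read length 100, per-base
substitution probability `error_rate` (default 0.01, the middle of the
Illumina range); paired layout draws fragment lengths from
Normal(insert_mean = 300, insert_sd = 30) truncated at the read length.
Every injected error is logged (read id, position, true and observed
base), and each read's origin window is kept so truth-log completeness is
verifiable exhaustively. Independent RNG streams per stage make every
artifact reproducible byte-for-byte from the seed.

An optional decoy repeat copies a slightly diverged gene subsequence into
an intergenic locus to exercise repeat extraction and `out` labelling.

What the generator does **not** model: position-dependent quality decay
and ART-style empirical error profiles, GC/coverage bias, indel
sequencing errors (an injection hook exists only to exercise the SAM
strip/fill path), heterozygous variants, and structured repeats beyond
the single decoy. Passing tests therefore demonstrate correctness of the
method's logic under its own assumptions — uniform random errors, clean
homozygous divergence — not performance on real libraries, where error
clustering at read ends and true repeats make both extraction and
dominance classification harder.

## Reference study and problem sizes

The package's reference study (tests and `scripts/acceptance.py`) uses a
1 Mb genome with seven genes of 5, 8, 12, 18, 30, 45 and 60 kb — mirroring
the spread of gene sizes a disease-gene panel exhibits, at a scale a
laptop handles in minutes — at the default rates above, seed 42, in both
single- and paired-end layouts (300 000 reads each). Under these
conditions the across-gene average gain is ≈99.99% (single) and ≈99.98%
(paired), with per-gene consensus identical to the true gene.

## Known limitations

- The mapper is ungapped; reads whose alignment to the gene requires an
  indel are only usable via imported SAM.
- Reads overhanging the extended reference (beyond the flank) are not
  extracted; coverage at the outermost flank columns tapers accordingly.
- Very low-depth columns (≤3) are always one/two-type dominant by the
  count rule, so a lone disagreeing base at depth 2 can be "corrected"
  toward the wrong base; this matters only at region edges.
- The `out` rule needs at least two suspicious candidates, so a repeat
  read differing from the gene at a single column is indistinguishable
  from a read with one error and stays in.
- Metrics are computed over extracted reads only; errors in reads the
  extractor rejected (>5 mismatches) are outside the instance by
  definition.
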