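# Methods

## Problem and model

`orivec` classifies variable-length DNA fragments as ORI-containing or
not, using only the sequence.  The model chain is: trinucleotide
tokenization → skip-gram word vectors → convolutional classifier over
the embedded token matrix.  The biological premise is that
origin-flanking DNA differs from background in its local word
composition and short-range word order (trinucleotides are the natural
unit: codon-sized, 64 types), and that these differences are learnable
without hand-crafted features or fixed-length inputs.

## Tokenization

*Continuous* segmentation slides a width-3 window with stride 1,
yielding the L−2 overlapping trinucleotides; concatenating each token's
first base plus the last token's tail reconstructs the input exactly.
*Skip* segmentation slides with stride 3 from offsets 0, 1 and 2; each
derived sequence partitions `sequence[offset:]` into triplets with a
final mono- or dinucleotide when the length is not divisible by 3, so
no base is lost and each derived sequence preserves the original
order.  Only the first three offsets are produced: further offsets
repeat the first three up to a one-word prefix, adding near-duplicate
training text.  Vocabularies are full canonical enumerations (64 and
4+16+64 = 84 words), not corpus-observed sets, so the embedding matrix
shape is data-independent.  Index 0 is a reserved PAD whose embedding
row is pinned to zero; it is not a biological word.  Tokens containing
ambiguity characters (N etc.) are skipped at encoding time; records
with more than 10% non-ACGT characters are rejected outright.  These
two rules keep the vocabulary exactly at 64/84 while tolerating the
sporadic Ns of real assemblies.

## Word-vector pre-training

Skip-gram with negative sampling, written from scratch (the sampling
law and its table are part of the method, not a library detail):

* Unigram law: `len(w) = count(w)^¾ / Σᵢ count(i)^¾` over the corpus
  tokens.  The unit interval is cut into M = 1000 equal cells; cell n
  holds the word whose cumulative-length interval contains the cell
  midpoint (n+½)/M.  Table construction is deterministic; all sampling
  randomness lives in the draws.
* For each center w and context w̃ within a symmetric window
  (default radius 2, after the worked convention for this task),
  negatives are drawn for the center word: k = 5 per prediction (the
  small-corpus convention; the source method leaves the count open),
  re-drawn on collision with the center, so NEG never contains the
  positive word.  Context windows never cross sentence boundaries, and
  each skip-derived sequence is its own sentence.
* The objective per (w̃, w) pair is
  `log σ(v(w̃)·θ(w)) + Σ_u log(1−σ(v(w̃)·θ(u)))`, ascended by plain
  SGD with the rate decaying linearly 0.025 → 1e−4 over all updates.
  Input vectors start uniform in [−0.5/D, 0.5/D], output vectors at
  zero.  D defaults to 300.
* Epochs default to **5**.  A handful of passes suffices because the
  vocabulary is tiny (≤ 84 types) and every type is seen thousands of
  times per epoch on realistic corpora; the per-epoch NLL plateaus
  within a few epochs, and pre-training sits inside every CV fold, so
  the default keeps the protocol fast without changing the result.
* Pre-training uses the positive class only (the ORI language is what
  the vectors should encode); `pretrain_on="all"` is available.
* The inner loop is numba-compiled; negatives are pre-drawn per epoch
  with a seeded Generator, so training is deterministic bit-for-bit
  under a fixed seed.

The 2-D t-SNE projection (`project_2d`) is for inspection only:
embeddings are defined up to rotation and t-SNE adds run-to-run
variation, so coordinates differ across seeds while neighborhood
structure persists.

## Classifier

The embedding layer maps the padded index sequence to an (L_max × D)
matrix per channel; before any training this equals the one-hot matrix
product with W (a tested bit-exact equivalence).  Convolutions are
vertical only — kernel width = D, heights {2, 3, 4}, 128 filters each —
because rows are whole word vectors and horizontal convolution inside a
vector has no meaning.  ReLU, then global max-pooling per filter,
concatenated to 384 = 128×3 features, a 384-unit fully connected layer
with ReLU, and a 2-way softmax.

Training modes: `default` (one frozen channel), `embedding_training`
(one trainable channel), `two_channel` (frozen + trainable copies of W,
each filter spanning both channels, as in RGB convolution).  The PAD
row is excluded from gradient updates in all modes.

Numerical and implementation choices:

* **Masked pooling.**  Inputs are padded to L_max but max-pooling is
  restricted to windows inside the true token length (at least one
  window), so appending PAD never changes the output and padded
  positions cannot leak length information through filter biases.
  `mask_padding=False` reproduces the naive behavior.
* **Vocabulary-factorized convolution.**  Every row of the embedded
  input is one of ≤ 85 vocabulary vectors, so for each kernel row r the
  projection `W @ K[h][r]` (an 85×D×128 product) is computed once per
  step and gathered by token index; gradients flow through the same
  factorization (scatter-add by token, then two small matrix products).
  This is an exact reformulation, not an approximation, and makes
  CPU-only training practical.  Training batches are formed over
  length-sorted inputs and visited in a reshuffled order each epoch.
* **Optimizer.**  Adam, base rate 0.001 multiplied by 0.9 after each
  epoch (the decay is read as per-epoch multiplicative; a step-based
  schedule would change little at these epoch counts).  L2 with
  coefficient 1e−4 on convolutional and fully connected weights (not
  biases, not the embedding).  Batch size 64.  Default 50 epochs, no
  early stopping; the evaluation protocols pass 20 epochs, which is
  where the training loss plateaus on the synthetic sets.
* **Scores.**  A record's score is its positive-class softmax
  probability; with skip segmentation the three sibling probabilities
  are averaged (`mean_prob`, the default; `majority` voting and
  `per_derived` scoring are provided, and reports record which was
  used).  Labels threshold the score at 0.5.  ROC curves use the raw
  scores.

## Evaluation

MCC is computed in the error-rate form
`[1 − (FN/P + FP/N)] / sqrt[(1+(FP−FN)/P)(1+(FN−FP)/N)]`; its radicand
factors simplify to (TP+FP)/P and (TN+FN)/N, so it is undefined exactly
when the textbook covariance form is, and equal to it elsewhere (a
property test checks this across random matrices).  Degenerate
denominators raise; inside protocols a degenerate repetition
contributes NaN and is excluded from the MCC average.  ROC thresholds
sit at midpoints between consecutive unique scores plus sentinels;
with this sweep the trapezoid area equals the Mann–Whitney statistic
with half-credit for ties, bit-for-bit.

10-fold CV is stratified by class at the record level (skip-derived
siblings never straddle folds — a leakage guard), and the pipeline is
refit from scratch per fold, embedding pre-training included, on that
fold's training positives; pooling TP/TN/FP/FN across folds is the
default (per-fold means ± sd available).  L_max is computed over the
whole dataset so held-out records always fit.  The independent test
repeats a stratified 90/10 split 20 times with derived seeds and
averages the metrics arithmetically.

k-mer composition summaries normalize counts per record and then
average across records, so record length does not weight the mean.

## Dataset construction

FASTA input, minimum length 50 nt (strict `< 50` removal), and a
redundancy filter that drops any sequence whose identity to an already
retained (longer) sequence exceeds 80%.  The identity is a documented
stand-in for CD-HIT clustering: shared 8-mers anchor candidate ungapped
alignments, the best diagonal's matches are divided by the shorter
length, and retention is greedy longest-first.  This approximates
clustering identity well in the near-duplicate regime the threshold
targets, and a flag skips the filter for pre-clustered inputs.
Sequences are used as given (no reverse-complement augmentation);
coordinates are 0-based internally.

## Synthetic data

The generator emulates the structure of the real benchmarks — two
classes of ~300 variable-length records — with an explicit,
controllable version of the compositional cue those benchmarks carry.
Negatives are i.i.d. from a background nucleotide distribution
(uniform by default).  Positives follow a second-order Markov chain
whose next-base law is the background tilted ×factor whenever the
completed trinucleotide is in the enriched set (default: the eight
AT-rich trinucleotides, factor 3), normalized per context.  Both
classes draw lengths from the same log-uniform law on [50, 10000] by
default; evaluation and test configurations cap length at 500 so the
protocols run in minutes.  Enrichment factor 1 makes the classes
distributionally identical — the null configuration.

What this does **not** emulate: positional motifs (ARS consensus
elements), GC-skew profiles, chromatin context, or homology structure
between records.  Passing tests therefore demonstrate that the pipeline
recovers a compositional class difference of realistic size from
realistic lengths and sample counts — not that it reaches any
particular accuracy on real genomic benchmarks.

A frozen 20-record toy fixture (extreme AT vs GC composition, lengths
50–120) supports fast unit tests; it is byte-identical across calls and
platforms.

## Problem sizes used in checks

The end-to-end acceptance computation runs pooled 10-fold CV twice on
freshly generated 682-record datasets (enrichment 3 and the null),
skip segmentation, D = 300, frozen-embedding mode, 20 CNN epochs and
5 pre-training epochs per fold — about 25–30 s per fold on one CPU.
Unit tests use the toy fixture and reduced dimensions throughout.

## Known limitations

* The redundancy filter is an approximation of clustering identity;
  order-dependent in principle (greedy), deterministic in practice.
* The CNN is CPU-bound NumPy; very long sequences (L_max in the
  thousands of tokens) train slowly compared to GPU frameworks.
* Scores are softmax probabilities from a small network trained on few
  hundred records; they rank well (AUC) but are not calibrated.
* `majority` aggregation with an even sibling split (impossible with
  three siblings) would tie; three derived sequences avoid this by
  construction.
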