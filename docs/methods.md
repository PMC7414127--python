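# Methods

## Problem and model

`attnbind` predicts, from DNA sequence alone, which of T ChIP-seq
experiments (transcription-factor / cell-line pairs) would call a binding
peak over the central 200 bp of a 1,000 bp window.  It is a multi-task
binary classifier over one-hot encoded sequence with an interpretable
positional attention layer:

1. **Convolution.**  h kernels of length l scan the S x 4 one-hot input
   (column order A, G, C, T) by valid cross-correlation with no bias;
   ReLU; non-overlapping max-pooling with window w.  The result is the
   activation map `C` of shape t x h, t = floor((S - l + 1) / w).  Each
   kernel acts as a motif scanner; pooling keeps the strongest match per
   13-position window.
2. **Attention.**  A trainable key vector `p` (length h) scores each
   pooled position by a dot product, `a = softmax(C p + b)`, and every
   column of `C` is rescaled element-wise by `a`.  This adds exactly
   h + 1 trainable scalars (321 at the default h = 320).  The scalar bias
   `b` shifts all scores equally, so softmax makes it a functional no-op;
   it is kept for the parameter-count accounting and trains to nothing
   (its gradient is identically zero).
3. **BiLSTM.**  A bidirectional LSTM (per-direction width = h by default)
   reads the scaled map; per-position outputs of the two directions are
   concatenated (t x 2h).
4. **Head.**  The BiLSTM output is flattened row-major, passed through a
   ReLU layer of width 695, then a sigmoid output layer of width T.

Training minimizes mean binary cross-entropy over all sample-task pairs
(predictions clipped to [1e-7, 1 - 1e-7] before the logs) with Adam at
learning rate 0.001 and batch size 100.  Validation loss is computed each
epoch and the best-validation checkpoint is retained.

The full-scale defaults are S = 1,000, l = 26, h = 320, w = 13 (t = 75),
fc = 695, T = 690.  Everything is implemented in NumPy with hand-written
backward passes (no deep-learning framework is required); analytic
gradients are verified against central finite differences in the test
suite.  `use_attention=False` removes the attention layer, giving the
no-attention (DanQ-shaped) ablation: with a uniform attention vector the
two models coincide up to an exact 1/t scaling of the activation map.

## Dimensional note on the head layer

The head is the standard affine form `ReLU(W1' flat + b1)`.  A variant
sometimes written as `ReLU(W1'(flat + b1))` is dimensionally inconsistent
(b1 has the hidden width, flat has width 2ht) and is not implemented.

## Initialization (all choices ours; the architecture does not fix them)

- Conv kernels: He-uniform (the layer feeds a ReLU).
- Attention key `p`: small random uniform (Glorot limit for an (h, 1)
  map); bias 0.  Random initialization breaks the initial uniformity of
  the attention.
- LSTM: Glorot-uniform input weights, orthogonal recurrent blocks per
  gate, forget-gate bias 1, other biases 0, zero initial states.
- Dense layers: Glorot-uniform, zero biases.
- **Attention-aware gain.**  At initialization the attention is nearly
  uniform, so the activation map reaches the BiLSTM scaled by ~1/t.  At
  desk scale (hundreds of optimizer steps rather than hundreds of
  thousands) this stalls learning: the no-attention ablation learns all
  benchmark tasks while the attention model learns only the strongest
  motif.  The LSTM input weights therefore carry a gain of t when
  attention is active, making the attention model's initial forward
  signal match the ablation's.  This changes no architecture, only the
  starting point of optimization.
- No dropout and no weight decay by default.

## Dataset construction

Coordinates are 0-based half-open (BED convention) throughout.  The
genome is tiled into non-overlapping 200 bp bins from position 0;
trailing partial bins are discarded.  A bin is positive for a task iff
strictly more than half of it (> 100 bp) is covered by the task's peaks;
overlap is computed against the merged union of the task's peaks by
default (two abutting 60 bp peaks jointly covering 120 bp count), with a
per-peak option.  Labeled bins are extended by 400 bp on each side; bins
whose extension leaves the chromosome are dropped, not padded.  N bases
one-hot encode to all-zero rows.  Reverse complements of all records are
appended with labels copied verbatim (dataset size exactly doubles), and
the reverse complement of a record always carries its partner's split
tag.  Splits are by chromosome (default: chr7 validation, chr8+chr9
test, rest training).

## Synthetic benchmark (the stated world of the tests)

The simulator emulates the structure of the real dataset without any
download: i.i.d. background sequence at GC content 0.5; three planted
motifs of lengths 8, 10 and 12 (CREB-like TGACGTCA, GATA-like
AGATAAGATA, E-box-like GGCCACGTGGCC), one per task; per task and
sequence a plant occurs with probability 0.3, at a uniform position
inside the central 200 bp core [400, 600), on either strand with equal
probability (single instance per positive record-task pair; overlapping
plants for different tasks are allowed and recorded).  The standard
benchmark draws 5,000 / 500 / 500 train/validation/test sequences of
1,000 bp from seed 7 via deterministically spawned child seeds.

**Motif information content.**  Planted PPMs put probability 0.97 on the
consensus base at every position.  This is deliberate and load-bearing:
an ideal matched-filter scan (log-odds over both strands, restricted to
the core) was used to measure the Bayes ceiling of the benchmark before
any model training.  At consensus probability 0.85 the ceiling for the
8-mer task is AUROC ~0.79-0.95 (full-scan to core-restricted) — chance
near-matches in 1 kb of background swamp a weakly-specified 8-mer, so no
model could reach the benchmark's target of 0.90.  At 0.97 the
core-restricted ceiling is ~0.97/0.99/1.00 for the three tasks.  High
per-position certainty also mirrors the core positions of strong real TF
motifs.

What the simulator does **not** model: dinucleotide/Markov background
structure, chromatin accessibility, cooperative or overlapping binding
of the same TF, motif position preferences within the core, and label
noise.  A green benchmark test therefore establishes that the
implementation can learn and localize strongly planted signals, not that
it reproduces full-scale ChIP-seq performance.

## Evaluation

AUROC is the rank-based (Mann-Whitney) area; AUPR is average precision
(step interpolation, not trapezoidal, avoiding optimistic linear
interpolation).  A task is undefined for AUROC with single-class labels
and for AUPR with no positives; undefined tasks are excluded from macro
averages and dropped pairwise from model comparisons.  Model-vs-model
counts use strict inequality (ties are not "better"); percentages are
rounded to two decimals.

## Motif extraction and deduplication

For each kernel and each input sequence, the l-mer under the position of
maximal pre-pooling ReLU activation is collected iff that maximum is
strictly positive (leftmost on ties; one site per sequence-kernel pair,
with a top-k option).  Sites are stacked into a position probability
matrix (pseudocount 0 by default); the consensus is the per-position
argmax with ties broken toward the first base in A, C, G, T order.
Motifs with fewer than 10 sites are flagged low-support.  Harvesting
scans with the final-epoch parameters by default (predictions use the
best-validation checkpoint, but kernels keep sharpening after the
validation optimum and the sharper kernels give cleaner consensi); the
checkpoint is selectable.  The MEME
writer emits the minimal motif format (A, C, G, T column order,
`nsites=` equal to the harvest count) ready for TOMTOM; a reader
round-trips it.  Harvesting uses pre-pooling activations because the
pooled map cannot locate an l-mer at base resolution.

Deduplication clusters consensus strings by Levenshtein distance under
complete linkage; cutting the dendrogram at height <= d yields the
distinct-motif count for threshold d.  Complete linkage guarantees every
pair within a cluster is within d; at d = 0 only exact duplicates merge.
The distinct count is non-increasing in d.

## Attention interpretation

Attention vectors (one weight per pooled position, rows sum to 1) are
averaged within two groups: sequences whose maximum predicted task
probability exceeds 0.5 ("predicted any") and the rest ("predicted
none"); grouping by true labels is available as a flag.  Central
enrichment is the mean attention per pooled bin inside the core region
over the mean outside.  A pooled bin j aggregates conv windows starting
at input positions [w*j, w*j + w); bins whose start range intersects
[400, 600) are the core bins (30..46 at w = 13).  Each conv window also
extends l - 1 bases right of its start; this overhang is documented
rather than widening the core set.  An empty group is reported with
n = 0 and no profile rather than NaN means.

## Numerical choices

- Softmax subtracts the row maximum; sigmoid is evaluated in the
  numerically stable split form.
- BCE clipping epsilon 1e-7; gradients use the sigmoid-cross-entropy
  shortcut (exact wherever the clip is inactive).
- Max-pool remainder positions (conv length mod w) are dropped; pool
  backward routes gradient to the leftmost argmax.
- Training is bit-reproducible for a fixed seed: one generator drives
  initialization and batch shuffling; data generation derives child
  seeds (< 2^31) from the benchmark seed.
- float32 parameters by default; float64 supported (used by the gradient
  tests).

## Known limitations

- Desk-scale training (≤ 15 epochs, thousands of sequences) is three to
  four orders of magnitude less optimization than full-scale training;
  which of several equally planted motifs is learned first can depend on
  the initialization seed.
- The attention layer is shared across tasks, so no per-task attribution
  is possible (an architectural property, not an implementation one).
- AUPR on heavily imbalanced real data is sensitive to prevalence; the
  synthetic benchmark's ~30% positive rate is far more balanced than
  real ChIP-seq bins.
- `prepare` loads the full dataset in memory; it is intended for
  benchmark-scale genomes, not a full human genome on a laptop.
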