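# Methods

## Encodings

A target site is 27 nt: TTTN PAM at positions 1–4 (position 1 is the
5'-most base and maps to the leftmost matrix column), protospacer at
5–27. The order-k encoding slides a k-mer window with step 1 and sets a
single 1 per column in the row of the observed k-mer; rows are ordered
lexicographically over {A,C,G,T}. Row order is an arbitrary convention —
convolution is permutation-sensitive in principle, but shuffling row order
has little practical effect on classifier performance, so lexicographic is
fixed for reproducibility. A 27-nt site gives 4 × 27 (k=1), 16 × 26
(k=2, the default), 64 × 25 (k=3).

The mismatch encoding maps a guide/target pair to a 12 × 27 matrix: rows
are the 12 ordered substitutions (guide base → target base,
lexicographic), columns are positions; matched positions are all-zero
columns, so the matrix total equals the Hamming distance. PAM columns are
encoded like any other position; because scanners require the PAM to match
TTTN, only position 4 (the N) can ever be nonzero there in pipeline use.
Degenerate bases (N and other IUPAC codes) are rejected rather than
distributed fractionally — encodings are exact or refused.

Optional 40-nt context windows add 7 nt upstream of the PAM and 6 nt
downstream of the protospacer in the site's own orientation; minus-strand
windows are reverse-complemented so the PAM reads left-to-right.

## Networks

Both classifiers share one architecture family: valid (unpadded)
convolution with ReLU, non-overlapping 2 × 2 sum-pooling with floor
truncation of odd trailing rows/columns, flatten (map-major, then
row-major within each map), one fully connected ReLU layer, and a 2-unit
softmax head. The positive-class probability is "the score"; the model is
used as a binary classifier throughout (AUC/F1), which is why the head is
a normalized 2-class score rather than an unbounded regression output.

Shapes are derived, never hard-coded: on-target 16×26 → 50 maps of 12×22 →
6×11 pooled → flatten 3300 → dense 650; off-target 12×27 → 35 maps of
6×21 → 3×10 pooled (the 21st column is dropped by truncation) → flatten
1050 → dense 300. The order-1 variant uses a 4×1 kernel with 1×2 pooling
because a 5×5 kernel does not fit a 4×27 input.

Optimization is minibatch SGD with momentum: learning rate 0.005,
momentum 0.9, batch size 40 on the softmax cross-entropy. These optimizer
settings are the canonical configuration for these nets; epoch count is
exposed (library default 100; no early stopping). Weights use seeded
Glorot-scaled uniform initialization; biases and the output layer start at
zero, so an untrained network scores every input exactly 0.5 and the
symmetric start carries no class prior. All randomness (init, batch
shuffling) flows from explicit seeds, making runs bit-reproducible. The
forward and backward passes are written directly in numpy (im2col
convolution, reshape-based pooling); the backward pass is verified against
central finite differences on a float64 toy network in the test suite.

Numerical notes: arithmetic is float32; batched BLAS matmuls can differ
from single-sample evaluation in the last bit, so prediction is
order-preserving and batch-invariant up to ~1e-6, not bit-exact across
different batch partitions. Serialization stores spec + weights +
threshold in one `.npz` with a format version; round-trips reproduce
predictions bit-exactly.

## Labeling, splits and metrics

Records are ranked by indel frequency (stable descending sort; ties keep
input order). The top `floor(top_frac·n)` records are class 1, the bottom
`floor(bottom_frac·n)` class 0, the middle is excluded — with n = 1251 and
20%/20% this gives the 500-record training set (250+250) and 751 held-out
records used for rank-correlation analysis. Off-target labels are top 20%
("high-activity off-target sites") versus the remaining 80%.

External cross-validation partitions the labeled data into k seeded,
stratified, near-equal folds; each fold is scored only by a model trained
on the others, so every record is predicted exactly once out-of-fold.
Stratification is a deliberate choice over plain random folds: it
prevents degenerate single-class folds at small n without changing the
external character of the procedure. AUC is the Mann–Whitney rank
statistic with the half-tie convention (delegated to scikit-learn and
checked against an exhaustive pairwise oracle); F1 = 2TP/(2TP+FP+FN) with
positives at score ≥ threshold (default 0.5); Spearman uses average-rank
ties and refuses constant vectors.

The cutoff grid retrains the classifier under a grid of (top, bottom)
labelings — default 9 × 5 = 45 combinations over top ∈ {5…45%} and bottom
∈ {60…80%} — reporting mean CV AUC per cell; combinations whose fractions
exceed 1 or produce an empty class are reported as skipped rather than
silently dropped.

## Permutation importance and projection

Importance is measured on the flatten layer — the last layer whose neurons
still have defined receptive fields on the input. Two criteria:

- **auc** (default): each neuron's activation column is shuffled across
  samples (seeded, `n_repeats` times) while the rest stay fixed; the score
  is the mean decrease in head AUC versus baseline. Permuting one column
  shifts the dense pre-activations by an outer product, so the sweep is
  incremental and cheap. Caveat: once the classifier separates the
  evaluation set perfectly (AUC = 1), single-neuron permutations usually
  leave AUC saturated and all scores become 0 — use held-out data, an
  undertrained model, or the impurity criterion in that regime.
- **impurity**: a seeded extra-trees surrogate is fitted on the flatten
  activations and its mean decrease in node impurity per neuron is
  reported. This criterion stays informative under saturation and is the
  one used in the seed-region concentration checks.

Neither criterion is claimed canonical; both produce the same report
format. The projection step is purely structural: the receptive field of
the neuron at pooled cell (r, c) is input rows [ph·r, ph·r+kh+ph−2] ×
cols [pw·c, pw·c+kw+pw−2] (6 × 6 cells for the on-target net), and the
heatmap is the sum of indicator masks over the top `top_n` neurons
(default 50; ties broken by neuron index). It depends only on the
architecture, never on weights.

## Guide-design pipeline

Candidate discovery reports every TTTN-N23 match on both strands
(overlaps included, windows containing N skipped), with 0-based half-open
forward-strand coordinates; minus-strand sequences are stored
reverse-complemented, PAM-first. Filters remove protospacer GC < 30% or
> 70% (strict inequalities, so exactly 30%/70% survives) and polyT runs.
PolyT is defined here as ≥ 4 consecutive T within the 23-nt protospacer
(run length configurable); GC is computed over the protospacer only, since
the PAM is fixed TTTN and would only shift all values. Retention keeps
`ceil(retain_frac·n)` sites (floor of 1, so tiny inputs still yield a
candidate), ranked by predicted activity with coordinate tie-breaks.

Off-target enumeration scans all candidate PAM sites and counts
protospacer mismatches against the guide (PAM must match TTTN exactly —
the fixed-PAM scanning convention); the guide's own locus is excluded;
`max_mismatch` defaults to 4 and allows up to 7. The scan is exhaustive
and agrees exactly with a naive quadratic re-scan (tested on 50-kb
sequences). A hit scoring at or above the off-target classifier threshold
counts as high activity; a zero-mismatch hit (exact protospacer duplicate)
is counted high by definition, because its mismatch encoding is the
all-zero matrix — which carries no signal for the classifier — while an
exact match is maximally cleavable. The specificity score 1/(1+n_high)
is monotone decreasing in the number of high-activity sites. Final
ranking is lexicographic: fewest high-activity off-targets, then highest
activity, then leftmost coordinate; requesting more guides than survive
returns all survivors with a warning flag.

## Synthetic data

Real Cpf1 indel-frequency libraries are not bundled, so the generators
plant the qualitative structure such libraries exhibit, with every
parameter explicit in `GeneratorConfig`:

- **Matched targets**: random TTTN+23-nt sites; latent activity
  `logistic(β0 − β_T·nT(5–10) + β_GC·(GC−0.5))`, indel frequency
  `100·activity + N(0, σ)` clipped to [0, 100]. Defaults β0 = 0,
  β_T = 0.8, β_GC = 1.0, σ = 5 — generator choices sized so the planted
  thymine-depletion effect at the PAM-proximal seed (positions 5–10)
  dominates but does not erase the GC effect, mimicking the empirical
  finding that thymines adjacent to the PAM depress activity.
- **Mismatched pairs**: a random guide with 1–6 mismatches at protospacer
  positions; each mismatch multiplies a base activity (uniform on
  [0.4, 1.0]) by a region penalty — seed (5–10) 0.1, trunk (11–22) 0.5,
  promiscuous (23–27) 0.9 — ordered to match the observed severity
  gradient of mismatch effects along the protospacer.
- **Toy genomes**: i.i.d. uniform background with planted near-duplicate
  protospacer copies (PAM intact, exact mismatch counts, random strand,
  non-overlapping loci) plus a truth table of every planted locus.

What passing recovery tests shows: the classifiers, encodings, CV harness
and importance projection can extract a planted monotone sequence signal
of realistic shape at n = 2000. What it does not show: performance on real
libraries, whose effects are weaker, position-correlated and noisier —
the near-perfect synthetic AUCs (~0.99) should not be read as expected
real-data performance, where published Cpf1 activity models sit near
AUC 0.8. Gaussian noise + clipping is a simplification; lentiviral readout
noise and PAM-discovery design are deliberately not emulated.

## Problem sizes and defaults used in checks

The automated checks run at: CV on n = 2000 matched records (800 labeled)
with 15 epochs; off-target training on n = 2000 pairs, held-out scoring on
a fresh n = 1000 draw; importance concentration over 10 generator seeds at
n = 1000 with 10 epochs and the impurity criterion; pipeline ground truth
on a 50-kb genome. Epoch counts below the library default of 100 are used
because the planted synthetic signal saturates within a few epochs;
results are insensitive to training longer.

## Known limitations

- CPU-only, single-channel inputs, one conv stage (a deeper configurable
  stage is possible via `NetSpec`, but is not the default surface).
- No bulge (gapped) off-target search, no PAM-variant (e.g. TTTV) search,
  and no genome-scale index — scanning is desk-scale and exhaustive by
  design.
- Permutation importance with the AUC criterion is uninformative on
  perfectly separated data (see above).
- `label_by_cutoffs` floors fractional counts; with very small n and small
  fractions a class can be empty, which is an error rather than a silent
  fallback.
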