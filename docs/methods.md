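# Methods

`hictad` is a boundary-first caller of topologically associating domains
(TADs) from chromosome-level Hi-C contact matrices. This note documents the
model, the statistical components, the synthetic-data generator that the
test suite trains and evaluates on, and the design choices made where the
method leaves details open.

## Problem setting

A Hi-C experiment binned at resolution *r* (default 25 kb) yields, per
chromosome, a symmetric nonnegative matrix *M* whose entry *m<sub>ij</sub>*
counts contacts between bins *i* and *j*. TADs appear as contact-enriched
blocks on the diagonal; a TAD boundary is a bin with depleted contacts
between its upstream and downstream neighbourhoods. The caller works in
three stages: (1) classify every bin as boundary / non-boundary from its
local 10×10 contact window, (2) remove false-positive boundaries with a
one-sided Wilcoxon rank-sum test, (3) assemble the surviving boundaries
into a nested domain hierarchy by cosine-similarity merging.

## Input representation

For bin *i* the classifier sees `SubM_i = M[i-4 : i+6, i-4 : i+6]`, the
10×10 sub-matrix covering four bins upstream and five downstream. Bins
within four bins of a chromosome end get zero-padded windows rather than no
prediction, so every bin is scored. Windows are scaled entrywise by
log(1+x) followed by per-window min–max normalisation to [0, 1] (constant
windows map to zero). Raw counts span orders of magnitude and vary with
sequencing depth; per-window scaling makes the classifier respond to the
contact *pattern* rather than the local coverage. The scaling is
configurable (`none`, `log1p`, `log1p+minmax`).

Matrices may be balanced before calling. Two balancers are provided:
vanilla coverage (divide by the product of row sums, then rescale to the
input's total mass — the scale convention is ours; downstream steps are
scale-covariant) and Knight–Ruiz-style balancing, implemented as symmetric
Sinkhorn iteration to the same fixed point (every non-gap row sum equal to
the input's mean row sum, relative tolerance 1e-6, at most 3000 sweeps).
Zero-coverage rows are excluded from balancing and restored as zeros. The
pipeline defaults to KR-balanced input.

## The boundary classifier

Architecture, for one 10×10 window (one input channel):

1. 3×3 convolution, 128 filters, ReLU, "same" padding;
2. 3×3 convolution, 64 filters, ReLU, "same" padding;
3. 2×2 max pooling → 64×5×5;
4. CBAM attention: a channel gate (shared two-layer MLP, reduction 8, over
   global average- and max-pooled descriptors, sigmoid) followed by a
   spatial gate (7×7 convolution over the channel-wise mean and max maps,
   sigmoid);
5. the 5×5 grid is read as 25 tokens of 64 channels, linearly projected to
   model dimension 64 with a learned positional embedding;
6. one post-norm transformer encoder layer (4-head self-attention,
   feed-forward width 128, ReLU);
7. mean pooling over tokens, a 64-unit fully connected layer with ReLU and
   dropout 0.3, and a final linear unit with sigmoid.

A bin is a candidate boundary when its probability is strictly greater
than the decision threshold (default 0.5).

The stated operating point — seed 123, learning rate 3e-4, conv shapes
(128, 3×3) and (64, 3×3), four attention heads, threshold 0.5 — is fixed in
`ModelConfig`. Everything the method description leaves open (transformer
depth 1, model dim 64, feed-forward 128, dropout 0.3, CBAM reduction 8,
Adam, binary cross-entropy, batch 64, 30 epochs with best-validation-loss
checkpointing, pooling before CBAM) was chosen as the smallest standard
option consistent with those constraints, and every one is configurable.
A single dropout layer sits after the hidden fully connected layer;
dropout on the final one-unit output would only zero the logit at random
and was omitted.

The network is implemented directly on NumPy arrays with hand-written
backward passes (`hictad.nn`); the test suite verifies every layer's
gradient against central finite differences. Initialisation, mini-batch
shuffling and dropout all draw from generators derived from the single
config seed, so training is bit-reproducible on a fixed platform.

### Training data

Real Hi-C has no ground-truth boundary labels. Positives are bins called a
boundary by at least two of several external callers (consensus is
exact-bin by default; a ±1-bin tolerance mode exists). Each positive window
is also added rotated 90° clockwise, doubling the positive count; negatives
are then sampled uniformly without replacement from the remaining bins at
four per augmented positive (i.e. 8k negatives for k consensus bins). The
4× ratio is applied after augmentation; the ratio and an option to exclude
bins flanking a positive from the negative pool are configurable. Whole
chromosomes are assigned to train (chr1–12), validation (chr13–19) and test
(chr20–22); chrX is excluded. On synthetic data the simulator's planted
boundaries replace the consensus.

## False-positive filtering

For candidate bin *i* with half-window *w* = 5: *U* collects the contacts
among the *w* upstream bins (strict upper triangle — diagonal
self-contacts are dominated by self-ligation and excluded), *D* likewise
downstream, and *R* the *w*×*w* contacts between the two sides. A one-sided
Wilcoxon rank-sum test of *U* ∪ *D* stochastically greater than *R* is run;
candidates with p > α = 0.05 are removed. Ties are midranked; when the
smaller sample has fewer than 8 observations the permutation null is
enumerated exactly, otherwise the tie-corrected normal approximation with
continuity correction is used (via `scipy.stats.mannwhitneyu`). A pooled
sample with all values identical carries no evidence and returns p = 0.5.
Candidates with fewer than two bins on either side are kept with a missing
p-value — the classifier already vouched for them and the test is merely
unavailable. No multiple-testing correction is applied by default
(a Benjamini–Hochberg flag exists).

One property of this filter is worth stating plainly: on a smooth,
low-noise matrix, power-law distance decay alone makes "within > cross"
significant at *every* bin, so the filter removes nothing — consistent with
its role of eliminating only a few calls in flat or noisy regions. Its
discriminative behaviour (rejecting random non-boundary candidates far more
often than planted boundaries) shows, and is tested, under weak decay and
heavy noise, where only genuine boundary contrast survives.

## Hierarchy assembly

Sorted boundary bins r₁ < … < rₙ delimit n−1 leaf TADs [r_k, r_{k+1}].
Adjacent domains are merged best-first: the pair with the highest cosine
similarity strictly above the threshold *dt* (default 0.8; leftmost pair on
ties) becomes a parent whose two children tile it, profiles are recomputed,
and merging repeats until no adjacent pair qualifies. Similarity exactly
equal to *dt* does not merge. Parents may merge again, so the hierarchy can
be arbitrarily deep.

The profile compared is this implementation's definition (the similarity
vector is not specified by the method): the mean of the domain's matrix
rows, restricted to the columns spanning both domains of the pair plus a
flank of 40 bins (1 Mb at 25 kb) on each side, zero-padded where the range
leaves the chromosome so the two vectors align column-by-column.

Runs of at least *h* = 5 consecutive zero-coverage bins are annotated as
gap regions; a pair whose combined span touches a gap region is never
merged.

## Evaluation statistics

With boundary centres at bin midpoints in bp and peak membership decided by
the peak interval's midpoint (counting elements once, configurable to
overlap mode):

* **average peak** — mean over boundaries of the per-10 kb peak density in
  the ±10 kb window;
* **fold change** — mean log₂ of that near density over the density in the
  bilateral [200 kb, 500 kb] flanks (sixty 10 kb windows); a pseudocount of
  0.5 enters a ratio only when one side is zero;
* **boundary tagged ratio** — fraction of boundaries with ≥ 1 peak midpoint
  within ±20 kb;
* **MoC** — measure of concordance between two partitions; 1 when both are
  a single domain, otherwise (Σ F²ᵢⱼ/(|Pᵢ||Qⱼ|) − 1)/(√(N_P N_Q) − 1). The
  denominator convention is the one that makes MoC(P, P) = 1 — the
  alternative reading √(N_P N_Q − 1) breaks the statistic's stated range
  and was rejected;
* **TADadjR²** — this package's operationalisation of distance-stratified
  variance explained: over bin pairs up to 1.5 Mb apart, each distance
  stratum is modelled by two group means (same-TAD vs cross-TAD); adjusted
  R² = 1 − (SS_res/(N−p−1))/(SS_tot/(N−1)) with SS_tot around per-stratum
  means (distance decay itself earns no credit) and p the number of strata
  containing both groups. The source description does not print a formula;
  this definition is documented as the package's own;
* **boundary Jaccard / precision–recall–F1** — greedy nearest one-to-one
  matching within ±1 bin by default.

## Synthetic data generator

`simulate_hic` draws TAD sizes uniformly from 8–20 bins (200–500 kb at
25 kb, the commonly reported band), tiles the chromosome, and with
probability 0.3 splits a TAD into two nested sub-TADs. Expected contacts
follow `E[i,j] = base · (1+|i−j|)^(−α)` times an enrichment factor β for
every planted domain containing both bins (β² inside a nested sub-TAD).
Defaults: α = 1, base = 100, β = 3, heteroscedastic Gaussian noise with
sd = 0.1·E added on the upper triangle and mirrored, negatives clipped to
zero. Gap regions are zeroed rows/columns; planted boundaries falling in a
gap are dropped from the ground truth. `add_gaussian_noise` instead scales
noise by the global nonzero mean, matching a "noise ratio" sweep
({0, 0.05, 0.1, 0.2, 0.5} is the documented harness choice).

The default benchmark is three independent 1000-bin chromosomes (train /
validation / held-out test), labels built from the planted boundaries with
the 2× augmentation and 4× negative rules. A larger noise-free variant
with three training chromosomes (several hundred planted boundaries)
backs the parameter-recovery tests.

What the generator does *not* emulate: read-count (Poisson) sparsity,
coverage biases, A/B compartment structure, loops, translocations, and
restriction-fragment effects. Passing the recovery tests therefore shows
that the pipeline's machinery is correct and self-consistent — boundaries
planted under the model are recovered — not that real-data performance at
any particular cell line is reproduced.

## Numerical and scale choices

* All tensors are float64; convolution uses im2col with BLAS matmuls.
* Sinkhorn balancing declares non-convergence (with the residual) rather
  than returning an unconverged matrix.
* Merging ties break leftmost; identical inputs give identical trees.
* Degenerate inputs: constant windows scale to zero; all-tied rank-sum
  samples give p = 0.5; zero-norm profile vectors have cosine similarity 0.
* Test-suite problem sizes were chosen as the smallest that exercise each
  property: 1000-bin chromosomes for end-to-end recovery and noise
  robustness, 100–300 bins for unit-level properties, and 100×100 matrices
  for balancing spread.

## Known limitations

* The filter's raw α = 0.05 rule is anti-conservative on smooth matrices
  (see above); on real, noisy data it behaves as intended, but users
  wanting strict error control should pass `--bh`.
* The TADadjR² and profile-similarity definitions are this package's
  operationalisations and may differ numerically from other
  implementations of the same ideas.
* Binary `.hic`/`.cool` containers are not parsed; use text dumps.
* Training is CPU-only by design; wall-clock scales with (windows ×
  epochs) and is minutes at benchmark scale, not suitable for genome-wide
  10 kb training without patience.
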