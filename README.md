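# hictad

Hierarchical TAD calling from Hi-C contact matrices.

Topologically associating domains (TADs) are the contact-enriched blocks on
the diagonal of a Hi-C matrix: contiguous genomic regions (typically
200 kb–5 Mb) whose loci interact far more with each other than with their
surroundings. Their boundaries anchor enhancer–promoter contacts, and
boundary disruption can rewire gene regulation, so calling TADs and their
nested sub-structure accurately matters to anyone studying 3D genome
organisation. `hictad` is for researchers who have chromosome-level Hi-C
contact matrices (dense text or juicer-style sparse triplet dumps) and want
boundary calls, a nested domain hierarchy, and the standard evaluation
statistics — plus a fully seeded synthetic Hi-C simulator for testing and
benchmarking the whole pipeline without any external data.

## Method

Calling proceeds in three stages on a (KR- or VC-balanced) contact matrix
*M* with entries *m<sub>ij</sub>* over *n* bins at resolution *r*:

1. **Boundary classification.** Each bin *i* is represented by its 10×10
   window `SubM_i = M[i−4 : i+6, i−4 : i+6]` (log1p + min–max scaled). A
   NumPy-implemented neural classifier — two 3×3 convolutions (128, 64
   filters), 2×2 max pooling, CBAM channel + spatial attention gates, a
   4-head transformer encoder over the 25 pooled spatial tokens, and two
   fully connected layers ending in a sigmoid — yields P(boundary); bins
   with probability strictly above 0.5 become candidates. Training (Adam,
   lr 3·10⁻⁴, binary cross-entropy, seed 123) uses consensus boundaries of
   ≥2 external callers as positives, 90°-rotated copies as augmentation,
   and 4× uniformly sampled negatives, split by whole chromosomes.
2. **Filtering.** For candidate *i* with half-window *w* = 5, the contacts
   among upstream bins (*U*), among downstream bins (*D*) and between the
   two sides (*R*) are compared with a one-sided Wilcoxon rank-sum test of
   *U* ∪ *D* > *R*; candidates with p > .05 are removed.
3. **Assembly.** Consecutive boundaries r₁ < … < rₙ delimit leaf TADs
   [r_k, r_{k+1}]; adjacent domains whose mean contact profiles have cosine
   similarity > *dt* (default 0.8) are merged best-first into parents,
   producing a nested hierarchy; merges never span zero-coverage gap
   regions (≥ *h* = 5 bins).

Evaluation statistics include boundary peak enrichment (average peak, fold
change, boundary tagged ratio), the measure of concordance (MoC) between
partitions, a distance-stratified adjusted R² of same-TAD co-membership,
and tolerance-matched boundary Jaccard/precision/recall/F1. See
`docs/methods.md` for definitions, assumptions and design choices.

## Worked example

Simulate the default benchmark (three independent 1000-bin chromosomes at
25 kb with planted, partly nested TADs, enrichment β = 3, noise 0.1), train
the classifier, and call TADs on the held-out chromosome:

```python
from hictad import (SimConfig, make_benchmark, ModelConfig, BoundaryClassifier,
                    call_tads, boundary_prf)

split, sims = make_benchmark(SimConfig(seed=0))      # three 1000-bin chromosomes
fit = BoundaryClassifier(ModelConfig()).fit(split)   # seed 123, lr 3e-4, 30 epochs
print(fit.summary())

matrix, truth = sims["chrS2"]                        # held-out chromosome
res = call_tads(fit.net, matrix)                     # predict -> filter -> assemble
p, r, f1 = boundary_prf(res.boundaries, truth.boundaries, tol_bins=1)
print(f"{len(res.candidate_boundaries)} candidates -> {len(res.boundaries)} "
      f"boundaries -> {len(res.tads)} top-level TADs")
print(f"precision={p:.2f} recall={r:.2f} f1={f1:.2f}")
```

Output (about three minutes on one CPU):

```
Boundary classifier fit
============================================================
parameters: 119,652
epochs run: 30 (best: 29)
seed=123 lr=0.0003 batch=64 threshold=0.5
final train loss: 0.0041
best val loss:    0.0077 (P=1.000 R=0.990 F1=0.995)

89 candidates -> 89 boundaries -> 87 top-level TADs
precision=1.00 recall=0.97 f1=0.98
```

The summary reports the training trajectory and the validation operating
point at threshold 0.5. On the held-out chromosome the pipeline proposes 89
candidate boundaries, the rank-sum filter keeps all of them (the simulated
matrix is clean), and assembly merges one adjacent pair of the 88 leaf
domains into a parent, leaving 87 top-level TADs; 97% of the planted
boundaries are
recovered within ±1 bin with no false positives.

The same pipeline is available from the shell:

```sh
hictad simulate --n-bins 1000 --seed 0 --out-prefix sim
hictad train --synthetic --model-out model.npz
hictad run-all sim.matrix.txt --model model.npz --chrom chrS0 --out-prefix calls
hictad evaluate calls.boundaries.bed --peaks peaks.bed --truth sim.boundaries.bed
```

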