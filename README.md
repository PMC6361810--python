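# mcimpute

Low-rank matrix completion imputation for single-cell RNA-seq dropouts.

Single-cell RNA sequencing starts from minute amounts of RNA, so many
transcripts fail to be captured and amplified: the count matrix is riddled
with *dropouts* — zeros at positions where the gene was actually expressed.
Dropouts blur cell-type structure, distort differential-expression calls and
confound downstream analysis. `mcimpute` treats the preprocessed expression
matrix as a partially observed low-rank matrix and recovers the missing
entries by matrix completion, without assuming any distribution for gene
expression. It is aimed at computational biologists who want a
distribution-free imputation step in a Python analysis pipeline, plus the
standard evaluation battery to judge whether imputation helped.

## Model

Let X ∈ ℝ₊^{m×n} be the complete (unknown) cells × genes expression matrix
and A the binary sampling operator marking observed entries. The data are

    Y = A(X),    rank(X) small.

Gene co-regulation makes expression matrices approximately low-rank, so the
imputation problem is the classic matrix-completion problem. Two solvers are
provided, both wrapped in a majorization-minimization (MM) outer loop with
the step

    B_{k+1} = X_k + (1/a) Aᵀ(Y − A(X_k)),   a ≥ 1.

**Nuclear-norm minimization (NNM, the workhorse)** solves

    min_X ‖Y − A(X)‖²_F + λ‖X‖_*

by soft-thresholding the singular values of B at λ_eff/2 each iteration
(the exact proximal operator of the nuclear norm, ‖X‖_* = Σσᵢ(X)), then
clipping negatives — expression cannot be negative. λ is specified as a
fraction of the leading singular value of Y (default 0.005); results are
insensitive to it while it stays below ~0.01.

**Matrix factorization (MF)** fixes a target rank r, writes X = UV with
U ∈ ℝ^{m×r}, V ∈ ℝ^{r×n}, and fits min ‖Y − A(UV)‖²_F by alternating least
squares against B. It needs a rank estimate; NNM does not — which is why
NNM is the default.

Preprocessing follows the standard single-cell pipeline: genes kept when
detected with ≥3 reads in ≥3 cells, library-size normalization to the
median cell total, log₂(x+1). The inverses are stored so imputed matrices
come back on all three scales (log, normalized, counts).

## Worked example

```python
import numpy as np
from mcimpute import generate_scrnaseq, mcimpute, cts_score, clustering_ari
from mcimpute.preprocess import PreprocessConfig, preprocess

# 500 cells x 300 genes, 3 cell types, ~80% of entries zero after dropout
truth, observed = generate_scrnaseq(seed=0)
print(f"observed zeros: {(observed.values == 0).mean():.0%}")

pre = PreprocessConfig(filter=False)
out = mcimpute(observed, method="nnm", preprocess_cfg=pre)
print(f"solver iterations: {out.result.iterations}")
print(f"zeros after imputation: {(out.counts.values < 0.5).mean():.0%}")

logged_obs, _ = preprocess(observed, pre)
g = truth.labels.groups
before = cts_score(logged_obs, truth.labels, g[0], g[1]).cts
after = cts_score(out.log, truth.labels, g[0], g[1]).cts
print(f"cell-type separability: {before:.3f} -> {after:.3f}")
```

Output:

```
observed zeros: 82%
solver iterations: 500
zeros after imputation: 5%
cell-type separability: 0.073 -> 0.923
```

82% of entries are zero going in; after completion only the entries the
low-rank structure cannot support (largely the truly silent genes) stay
below the 0.5 zero-convention. The cell-type separability score — average
within-type minus cross-type median Spearman correlation of cell
transcriptomes — rises by an order of magnitude, meaning cells of the same
type look like each other again.

More narrative scripts live in `examples/`: imputing a matrix end to end,
recovery-error curves versus sampling ratio, clustering/CTS evaluation,
the dropout-vs-true-zero bin analysis, and the CV–mean diagnostic.

## Command line

A thin CLI wraps the library for shell pipelines:

```bash
mcimpute simulate --cells 500 --genes 300 --clusters 3 --out-prefix sim
mcimpute impute --input sim.observed.csv --no-filter --out-prefix imputed
mcimpute eval-ari --input imputed.log.csv --labels sim.labels.tsv --out-prefix ari
```

Every run writes a JSON report (resolved config, seeds, iterations, final
objective) from which it can be reproduced.

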