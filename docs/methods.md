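# Methods

## The model

An scRNA-seq count matrix is modelled, after preprocessing, as a partially
observed low-rank matrix. Genes act in co-regulated programs rather than in
isolation, so the cells × genes matrix X has far fewer effective degrees of
freedom than min(m, n); its singular-value energy saturates after a handful
of components (`singular_spectrum` exposes this diagnostic). Dropouts —
transcripts missed during capture/amplification — appear as false zeros in
the observed matrix Y. Writing A for the binary sampling operator
(1 = observed), the data model is Y = A(X) and imputation is the recovery
of X.

Zeros are treated as unobserved when the mask is built from the data
(`build_mask`): this is the only reading under which completion fills
dropouts. The cost is that *true* biological zeros are also declared
unobserved; the model's protection for them is indirect — a gene silent in
a whole cell group contributes a coherent block of zeros that the low-rank
fit reproduces as near-zero values — and is measured, not assumed (see
"What the tests show" below). In masking experiments the mask is supplied
by the evaluator instead.

## Solvers

Both solvers share a majorization-minimization (MM) outer loop. The
data-fit term ‖Y − A(X)‖²_F is majorized at the current iterate X_k by
adding a quadratic whose curvature `a` bounds the squared spectral norm of
A; because A is an elementwise binary mask, a = 1 suffices and is the
default. The surrogate minimization reduces to a problem in

    B_{k+1} = X_k + (1/a) Aᵀ(Y − A(X_k)),

which for a = 1 is simply "Y on observed entries, X_k elsewhere". MM
guarantees each outer iteration cannot increase the objective; the test
suite asserts the recorded traces are non-increasing to 1e-10 for both
solvers on random masked instances.

**Nuclear-norm minimization (NNM).** The Lagrangian
min ‖Y − A(X)‖²_F + λ‖X‖_* is solved by iterating the exact nuclear-norm
prox on B: soft-threshold the singular values at λ_eff/2 and reconstruct.
Negative entries are clipped to zero after each prox (expression is
non-negative); empirically this projection never breaks descent on
non-negative data, and the trace assertion would catch it if it did.

*λ parameterization.* λ is interpreted as a fraction of the leading
singular value of Y: λ_eff = λ·s₁(Y), fixed once before iterating. An
absolute λ small enough not to bias the solution makes the iteration's
progress on unobserved entries vanishingly slow (the fill-in rate scales
with the threshold), while the normalized form makes the solver's behaviour
scale-free: any λ in roughly [0.001, 0.01] recovers planted low-rank
matrices to NMSE well below 0.05, and the shipped default is λ = 0.005.
Because λ_eff is fixed, the objective is fixed too and MM descent holds
exactly.

*Initialization and stopping.* X₀ = 0 (the first MM step then proposes
B₁ = Y, the standard iterated-soft-thresholding start). Iteration stops
when the relative change of the objective falls below `tol` (default 1e-4)
or after `max_iter` (default 500) iterations. On heavily masked data the
iteration cap typically binds before the tolerance; the recovered matrix is
already stable at that point.

**Matrix factorization (MF).** With a target rank r, X = UV is fitted by
one alternating-least-squares sweep per outer iteration (U given V, then V
given U, both against B), rank-deficient systems falling back to the
least-norm solution. V is initialized from the top r right singular vectors
of Y, so the solve is deterministic. The reconstruction UV is clipped at
zero each outer iteration. The recorded objective is the data-fit term.

*Choosing r.* When the caller does not supply a rank, the pipeline uses the
smallest rank holding 99% of the squared singular-value energy of the
observed matrix. Two caveats are documented deliberately: (i) on
non-negative matrices the leading singular value concentrates most of the
energy, so the rule *underestimates* the rank of clean data; (ii) on
heavily masked data the mask spreads energy across the spectrum, so the
rule grossly *overestimates* (rank ≈ 80 for a rank-5 matrix at 50%
observed) and MF then overfits the observed entries badly. This is the
practical reason NNM — which needs no rank estimate — is the default
method, and it is why the shipped-defaults comparison shows NNM at least as
accurate as MF at every sampling ratio. When MF is given the true planted
rank on noiseless synthetic data, it fits to machine precision and can beat
NNM, whose soft-thresholding leaves a small shrinkage bias; both facts are
exercised in the tests.

*SVD determinism.* The sign ambiguity of singular vectors is fixed by
forcing the largest-magnitude element of each left singular vector
positive, so identical inputs give bitwise-identical runs on a given BLAS.

## Preprocessing

Forward: genes kept when detected with ≥ `min_reads` (3) reads in
≥ `min_cells` (3) cells; each cell divided by its total count and rescaled
by the median total; log₂(x + pseudocount) with pseudocount 1. Filtering is
skippable (`filter=False`) for analyses that must retain every gene, e.g.
the dropout-vs-true-zero bins. Inverse: the per-cell totals and their
median are recorded at forward time, so the imputed log matrix maps back
exactly to normalized and (fractional) count scales. Imputed counts are
*not* rounded: rounding would erase small imputed values near the 0.5
zero-threshold used by the zero-fraction analysis. Cell-level quality
control is out of scope; inputs are assumed to contain no empty cells (a
zero-total cell is an error, named in the message).

## Evaluation battery

* **Masked recovery** (`mask_at_random`, `recovery_metrics`): exactly
  round(ratio·m·n) entries kept; NMSE = Σ(t−e)²/Σt², RMSE and MAE over the
  held-out positions only — the matrix-completion convention, since what is
  being graded is recovery of the missing values.
* **Cell-type separability (CTS)**: for two groups, the median Spearman
  correlation over all within-group cell pairs (per group, then averaged)
  minus the median over all cross pairs. Computed on the log layer, where
  rank correlations are stable; ties get average ranks; pairs involving a
  constant cell vector are excluded with a warning. Note the median makes
  the score non-additive: duplicating one heterogeneous group into two does
  *not* give CTS = 0 (the cross pairs include perfectly correlated copies),
  it gives CTS ≤ 0.
* **Clustering ARI**: cells projected onto the top 2 principal components
  (genes mean-centered, no scaling, exact SVD), k-means with random initial
  centroids run 100 times (the variability source being characterized),
  each partition scored by the adjusted Rand index against the annotation.
* **Dropout vs true zeros** (`zero_fraction_by_bins`): genes binned by a
  matched bulk reference — bin 1 holds genes with bulk expression exactly
  0, the remaining 9 bins split (0, 500] into equal widths, genes above 500
  excluded; the per-bin statistic is the fraction of entries below 0.5
  ("an imputed value in [0, 0.5) is still a zero call") over that bin's
  genes across all cells. Empty bins report NaN, not 0.
* **CV–mean relation**: per gene, CV = sd/mean across cells; pure Poisson
  sampling noise implies CV = mean^(−1/2), a slope of −1/2 in log–log
  space. Genes with zero mean or zero variance are excluded with a count.
* **Silhouette** on a caller-supplied 2-D embedding (Euclidean); singleton
  groups score 0 with a warning rather than failing.
* **Wilcoxon rank-sum DE**: two-sided per gene; exact null enumeration for
  tie-free samples with combined n ≤ 25, normal approximation with tie
  correction otherwise; all-tied genes get p = 1. A ROC-AUC helper scores
  the p-value ranking against a caller-supplied DE/non-DE ground truth.

## Synthetic data

The generator produces the structure the model assumes, plus ground truth
for every quantity the battery measures. Each of k clusters receives its
own non-negative low-rank block (|G₁||G₂| with standard-normal factors;
per-cluster ranks sum to the planted rank r, default 6 over 3 clusters of
~167 cells each), scaled to a mean library size of 3,000 counts over 300
genes (a panel-scale depth of ~10 counts per gene) and rounded to integers
for the observed layer; the pre-rounding matrix is kept as the exact-rank
truth. Structural zeros (default 5% of entries) are planted by zeroing a
gene in a cluster's factor, so the truth stays exactly low-rank and the
silent block is exactly zero. Dropout zeroes each positive entry
independently with probability exp(−s·log₂(1+count)²) — monotone
decreasing in expression, so lowly expressed genes are hit worst. The
strength s is the decay rate: *smaller s means heavier dropout*. The
default s = 0.02 leaves ~82% of observed entries zero, the droplet-data
regime this method targets; at that load, unimputed 2-PC clustering is
measurably below perfect, which is the regime where imputation has
something to fix. Two degenerate outcomes are repaired because they
correspond to cells that upstream quality control would have removed: a
cell whose every true count rounds to zero gets one read at its strongest
transcript, and a cell losing every transcript to dropout keeps its largest
entry.

What the generator does not emulate: Poisson or overdispersed
(negative-binomial) sampling of counts, batch effects, library-size
variation beyond what the low-rank structure induces, gene-length or GC
biases, and doublets. Passing tests therefore show that the solvers recover
planted low-rank structure under expression-dependent dropout — not that
they are robust to every noise source in real data. One concrete
consequence: the "imputation restores the CV–mean relation toward the
Poisson line" effect seen on real data cannot appear here, because the
complete matrix has no sampling-noise component to restore; on this
simulation the low-rank fit smooths weak genes and *flattens* the CV–mean
cloud (shown honestly in `examples/cv_mean_relation.py`). The CV–mean
diagnostic itself is validated against simulated Poisson counts, where the
fitted slope is −0.5 to within 0.01.

## Observations and limitations

* At *intermediate* dropout loads (~60–75% zeros on this simulation),
  NNM imputation can reduce the 2-PC k-means ARI below the unimputed value
  even while CTS improves substantially: the completion reshapes the
  leading principal components, and a clustering that was already
  near-perfect on the zero pattern can lose a few cells at cluster
  boundaries. At heavy dropout (~80%+) imputation consistently improves
  both ARI and CTS here.
* Structural zeros are imputed toward zero only *relatively*: the fraction
  of near-zero calls at structural-zero positions exceeds that at dropout
  positions (measured per run), but most structurally silent entries still
  receive small positive values, because the cross-cluster low-rank fit
  bleeds expression into silent blocks.
* The NNM solution is the minimum-nuclear-norm completion, which is not
  always the minimum-rank completion: on the 2×2 instance [[1,2],[2,·]]
  the nuclear-norm-optimal fill is 1 (nuclear norm 4), not the rank-1
  value 4 (nuclear norm 5). Exact recovery needs enough observations and
  incoherence, as the sampling-ratio curves show.
* Dense in-memory SVDs bound practical problem sizes to roughly 20k × 20k;
  no randomized/partial SVD, GPU path, or joint clustering-imputation is
  provided.

## Problem sizes used in the shipped checks

Recovery and solver checks run on rank-5 non-negative 100×200 matrices
(5 seeds, sampling ratios 0.2–0.8); the biology-facing evaluation on the
generator's default 500 cells × 300 genes × 3 clusters (5 seeds, 100
k-means runs each); prox agreement on fifty 3×3…8×8 matrices; the Poisson
CV check on 120 genes × 5,000 cells. These sizes were chosen so the entire
battery reruns from scratch in a few minutes on one core while keeping
every phenomenon (exact recovery, overfitting of auto-ranked MF, dropout
regimes) visible.
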