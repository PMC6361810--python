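"""Ground-truthed synthetic expression data.

Real scRNA-seq benchmarks need downloads and annotations; this module
instead produces matrices with exactly the statistical structure the
completion model assumes — non-negative, low-rank, clustered — plus the two
kinds of zeros the method must tell apart:

* **structural zeros**: a gene silent in an entire cluster (truly zero in
  the complete matrix), planted by zeroing that gene in the cluster's
  factor so the truth stays exactly low-rank;
* **dropouts**: observed-as-zero entries whose true value is positive,
  drawn per entry with probability exp(-strength * x^2) where x is the
  log2(1 + count) value — the double-exponential decay convention that makes
  lowly expressed genes the most dropout-prone.

Everything is seeded and returns the full truth (complete matrix, dropout
and structural-zero masks, labels, planted rank), so every downstream module
can be scored against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .completion import SamplingMask
from .matrix import CellLabels, ExpressionMatrix, ValidationError

__all__ = ["SyntheticTruth", "generate_lowrank", "generate_scrnaseq"]


@dataclass
class SyntheticTruth:
    """The generator's ground truth for one simulated dataset.

    ``X_true`` is the complete matrix on the pre-rounding scale, where the
    planted rank holds exactly; ``counts_true`` is its integer-rounded
    counterpart, the complete matrix the observed layer is derived from.
    """

    X_true: ExpressionMatrix
    counts_true: ExpressionMatrix
    dropout_positions: SamplingMask  # 1 = entry zeroed by dropout
    structural_zero_positions: SamplingMask  # 1 = truly silent entry
    labels: CellLabels
    planted_rank: int


def generate_lowrank(m: int, n: int, r: int, seed: int) -> ExpressionMatrix:
    """Random non-negative matrix of rank (at most, generically exactly) r.

    Built as |G1| @ |G2| with standard-normal factors, absolute value taken
    before the product, so non-negativity and the rank bound both hold by
    construction.
    """
    if not 1 <= r <= min(m, n):
        raise ValidationError(f"rank r={r} out of range for {m}x{n}")
    rng = np.random.default_rng(seed)
    G1 = np.abs(rng.standard_normal((m, r)))
    G2 = np.abs(rng.standard_normal((r, n)))
    X = G1 @ G2
    return ExpressionMatrix(
        X,
        cell_ids=[f"cell{i}" for i in range(m)],
        gene_ids=[f"gene{j}" for j in range(n)],
        layer="counts",
    )


def generate_scrnaseq(
    m_cells: int = 500,
    n_genes: int = 300,
    k_clusters: int = 3,
    r: int = 6,
    dropout_strength: float = 0.02,
    structural_zero_frac: float = 0.05,
    seed: int = 0,
    mean_depth: float = 3000.0,
) -> tuple[SyntheticTruth, ExpressionMatrix]:
    """Simulate a clustered scRNA-seq count matrix with dropouts.

    Each cluster gets its own low-rank block of non-negative means (the
    per-cluster ranks sum to ``r``), scaled so the mean per-cell total is
    ``mean_depth`` and rounded to integer counts for the observed layer.
    ``structural_zero_frac`` of all entries are silenced gene-in-cluster
    blocks (planted in the factors, keeping the truth low-rank); dropout
    then zeroes each remaining positive entry independently with probability
    exp(-dropout_strength * log2(1 + count)^2). Smaller strengths mean
    heavier dropout (the strength is the decay rate of the detection-failure
    probability with expression); the default 0.02 leaves roughly 80% of
    entries zero at the default depth, the regime of droplet-based data.

    Returns the truth bundle and the observed counts matrix.
    """
    if k_clusters > m_cells:
        raise ValidationError(f"k={k_clusters} clusters for {m_cells} cells")
    if k_clusters < 1:
        raise ValidationError("need at least one cluster")
    if not 0 <= structural_zero_frac < 1:
        raise ValidationError(
            f"structural_zero_frac must be in [0,1), got {structural_zero_frac}"
        )
    if dropout_strength < 0:
        raise ValidationError(f"dropout_strength must be >= 0, got {dropout_strength}")
    if r < k_clusters:
        raise ValidationError(f"rank r={r} must be >= k={k_clusters} (one factor per cluster)")
    rng = np.random.default_rng(seed)

    # near-equal cluster sizes, contiguous assignment then a fixed shuffle
    sizes = np.full(k_clusters, m_cells // k_clusters)
    sizes[: m_cells % k_clusters] += 1
    cluster_of = np.repeat(np.arange(k_clusters), sizes)
    rng.shuffle(cluster_of)

    ranks = np.full(k_clusters, r // k_clusters)
    ranks[: r % k_clusters] += 1

    # structural zeros: silence whole (gene, cluster) pairs via the factors
    n_pairs_total = n_genes * k_clusters
    n_silenced = int(round(structural_zero_frac * n_pairs_total))
    silenced_flat = rng.choice(n_pairs_total, size=n_silenced, replace=False)
    silenced = np.zeros((k_clusters, n_genes), dtype=bool)
    silenced[silenced_flat // n_genes, silenced_flat % n_genes] = True

    X = np.zeros((m_cells, n_genes))
    structural = np.zeros((m_cells, n_genes), dtype=bool)
    for c in range(k_clusters):
        cells = np.flatnonzero(cluster_of == c)
        G1 = np.abs(rng.standard_normal((cells.size, ranks[c])))
        G2 = np.abs(rng.standard_normal((ranks[c], n_genes)))
        G2[:, silenced[c]] = 0.0
        X[cells] = G1 @ G2
        structural[np.ix_(cells, np.flatnonzero(silenced[c]))] = True

    # scale to the target sequencing depth and round to integer counts
    X *= mean_depth / X.sum(axis=1).mean()
    counts = np.round(X)
    # a cell whose every entry rounds to zero would be an unusable empty
    # library; give it one read at its strongest transcript
    empty = np.flatnonzero(counts.sum(axis=1) == 0)
    for i in empty:
        counts[i, np.argmax(X[i])] = 1.0

    # dropout: expression-dependent Bernoulli on positive entries
    logx = np.log2(1.0 + counts)
    p_drop = np.exp(-dropout_strength * logx**2) if dropout_strength > 0 else np.zeros_like(logx)
    dropout = (rng.random(counts.shape) < p_drop) & (counts > 0)
    if dropout_strength == 0:
        dropout[:] = False
    # a cell losing every transcript would be discarded by quality control
    # upstream of any imputation; rescue such cells' largest entry instead
    # of emitting an unusable zero-total cell
    wiped = np.flatnonzero((np.where(dropout, 0.0, counts)).sum(axis=1) == 0)
    for i in wiped:
        dropout[i, np.argmax(counts[i])] = False
    observed_counts = np.where(dropout, 0.0, counts)

    cell_ids = [f"cell{i}" for i in range(m_cells)]
    gene_ids = [f"gene{j}" for j in range(n_genes)]
    labels = CellLabels([f"cluster{c}" for c in cluster_of], list(cell_ids))

    truth = SyntheticTruth(
        X_true=ExpressionMatrix(X, cell_ids, gene_ids, layer="counts"),
        counts_true=ExpressionMatrix(counts, cell_ids, gene_ids, layer="counts"),
        dropout_positions=SamplingMask(dropout.astype(float)),
        structural_zero_positions=SamplingMask(structural.astype(float)),
        labels=labels,
        planted_rank=int(ranks.sum()),
    )
    observed = ExpressionMatrix(observed_counts, cell_ids, gene_ids, layer="counts")
    return truth, observed
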