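"""Assessment battery for imputation quality.

Covers the standard ways of grading a dropout-imputation method:

* masked-recovery error (NMSE / RMSE / MAE on artificially removed entries);
* cell-type separability (CTS): within-group minus cross-group median
  Spearman correlation of cell transcriptomes;
* clustering accuracy: adjusted Rand index of repeated k-means on the top
  principal components against annotated groups;
* dropout-vs-true-zero analysis: fraction of near-zero single-cell entries
  per bin of matched bulk expression, with the "0 to 0.5 counts as a zero"
  convention;
* the coefficient-of-variation vs mean relation (Poisson sampling noise
  predicts CV = mean^(-1/2));
* silhouette on a 2-D embedding;
* Wilcoxon rank-sum differential-expression calling with a ROC-AUC helper;
* the singular-value spectrum diagnostic behind the low-rank assumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_rand_score, roc_auc_score, silhouette_samples
from sklearn.cluster import KMeans

from .completion import SamplingMask
from .matrix import CellLabels, ExpressionMatrix, ValidationError

__all__ = [
    "RecoveryMetrics",
    "CTSResult",
    "ZeroFractionBins",
    "CVMeanRelation",
    "DEResult",
    "mask_at_random",
    "recovery_metrics",
    "cts_score",
    "clustering_ari",
    "zero_fraction_by_bins",
    "cv_mean_relation",
    "silhouette_on_embedding",
    "wilcoxon_de",
    "de_auc",
    "singular_spectrum",
]


# ---------------------------------------------------------------------------
# masked recovery


@dataclass
class RecoveryMetrics:
    """Error metrics over held-out entries only.

    nmse = sum((t-e)^2) / sum(t^2), the Frobenius-normalized convention of
    the matrix-completion literature; undefined (NaN, ``nmse_defined=False``)
    when the held-out truth is all zero.
    """

    nmse: float
    rmse: float
    mae: float
    n_heldout: int
    nmse_defined: bool = True


def mask_at_random(
    X: ExpressionMatrix | np.ndarray,
    sampling_ratio: float,
    seed: int,
) -> tuple[ExpressionMatrix | np.ndarray, SamplingMask]:
    """Sub-sample a matrix at random to mimic dropouts.

    Keeps exactly ``round(sampling_ratio * m * n)`` entries as observed; the
    rest are zeroed in the returned copy and flagged (1) in the held-out
    mask. Reproducible for a fixed seed.
    """
    if not 0 < sampling_ratio < 1:
        raise ValidationError(f"sampling_ratio must be in (0,1), got {sampling_ratio}")
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    m, n = values.shape
    n_keep = int(round(sampling_ratio * m * n))
    rng = np.random.default_rng(seed)
    order = rng.permutation(m * n)
    keep_flat = np.zeros(m * n, dtype=bool)
    keep_flat[order[:n_keep]] = True
    keep = keep_flat.reshape(m, n)
    heldout = SamplingMask((~keep).astype(float))
    observed = SamplingMask(keep.astype(float))
    observed.check_solvable()
    Yv = np.where(keep, values, 0.0)
    Y = X.with_values(Yv) if isinstance(X, ExpressionMatrix) else Yv
    return Y, heldout


def recovery_metrics(
    X_true: ExpressionMatrix | np.ndarray,
    X_est: ExpressionMatrix | np.ndarray,
    heldout: SamplingMask,
) -> RecoveryMetrics:
    """NMSE, RMSE and MAE over the held-out positions."""
    t = X_true.values if isinstance(X_true, ExpressionMatrix) else np.asarray(X_true)
    e = X_est.values if isinstance(X_est, ExpressionMatrix) else np.asarray(X_est)
    if t.shape != e.shape or t.shape != heldout.shape:
        raise ValidationError(
            f"shape mismatch: truth {t.shape}, estimate {e.shape}, mask {heldout.shape}"
        )
    sel = heldout.mask.astype(bool)
    n_heldout = int(sel.sum())
    if n_heldout == 0:
        raise ValidationError("held-out mask is empty")
    diff = t[sel] - e[sel]
    rmse = float(np.sqrt(np.mean(diff**2)))
    mae = float(np.mean(np.abs(diff)))
    denom = float(np.sum(t[sel] ** 2))
    if denom == 0:
        warnings.warn("held-out truth is all zero; NMSE undefined", stacklevel=2)
        return RecoveryMetrics(np.nan, rmse, mae, n_heldout, nmse_defined=False)
    nmse = float(np.sum(diff**2) / denom)
    return RecoveryMetrics(nmse, rmse, mae, n_heldout)


# ---------------------------------------------------------------------------
# cell-type separability


@dataclass
class CTSResult:
    """Cell-type separability between two groups.

    ``cts = mean(intra_scatter.values()) - inter_scatter``: how much more
    similar (median Spearman correlation) cells are within their own type
    than across types.
    """

    intra_scatter: dict[str, float]
    inter_scatter: float
    cts: float


def _spearman_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise Spearman correlation of rows, NaN for constant rows."""
    ranks = stats.rankdata(values, axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (centered @ centered.T) / np.outer(norms, norms)
    corr[norms == 0, :] = np.nan
    corr[:, norms == 0] = np.nan
    return corr


def _median_offdiag(corr: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    if idx_a is idx_b:
        iu = np.triu_indices(len(idx_a), k=1)
        vals = corr[np.ix_(idx_a, idx_a)][iu]
    else:
        vals = corr[np.ix_(idx_a, idx_b)].ravel()
    bad = np.isnan(vals)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} cell pairs excluded: Spearman undefined for "
            "constant expression vectors",
            stacklevel=3,
        )
        vals = vals[~bad]
    if vals.size == 0:
        raise ValidationError("no valid cell pairs left for the median")
    return float(np.median(vals))


def cts_score(
    E: ExpressionMatrix,
    labels: CellLabels,
    group_a: str,
    group_b: str,
) -> CTSResult:
    """Cell-type separability score between two annotated groups.

    For each group, the intra scatter is the median Spearman correlation over
    all within-group cell pairs; the inter scatter is the median over all
    cross pairs. CTS is the average intra scatter minus the inter scatter.
    Symmetric in the two groups.
    """
    labels = labels.aligned_to(E)
    idx_a = labels.indices_of(group_a)
    idx_b = labels.indices_of(group_b)
    for g, idx in ((group_a, idx_a), (group_b, idx_b)):
        if idx.size < 2:
            raise ValidationError(f"group {g!r} has {idx.size} cell(s); need >= 2")
    corr = _spearman_matrix(E.values)
    intra = {
        group_a: _median_offdiag(corr, idx_a, idx_a),
        group_b: _median_offdiag(corr, idx_b, idx_b),
    }
    inter = _median_offdiag(corr, idx_a, idx_b)
    cts = float(np.mean(list(intra.values())) - inter)
    return CTSResult(intra_scatter=intra, inter_scatter=inter, cts=cts)


# ---------------------------------------------------------------------------
# clustering


def pca_embed(values: np.ndarray, n_pcs: int = 2) -> np.ndarray:
    """Project cells onto the top principal components.

    Genes (columns) are mean-centered, not scaled; the projection comes from
    an exact SVD, so it is deterministic.
    """
    centered = values - values.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(centered, full_matrices=False)
    return U[:, :n_pcs] * s[:n_pcs]


def clustering_ari(
    E: ExpressionMatrix,
    labels: CellLabels,
    k: int | None = None,
    n_runs: int = 100,
    n_pcs: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """ARI of repeated k-means on the top principal components.

    k-means is run ``n_runs`` times with freshly drawn random initial
    centroids (the variability source being characterized); each run's
    partition is scored with the adjusted Rand index against the annotation.
    """
    labels = labels.aligned_to(E)
    if k is None:
        k = len(labels.groups)
    if k < 2:
        raise ValidationError(f"need k >= 2 groups, got {k}")
    if k > E.n_cells:
        raise ValidationError(f"k={k} exceeds number of cells {E.n_cells}")
    emb = pca_embed(E.values, n_pcs)
    truth = labels.as_array()
    rng = np.random.default_rng(seed)
    aris = np.empty(n_runs)
    for i in range(n_runs):
        km = KMeans(
            n_clusters=k,
            init="random",
            n_init=1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        pred = km.fit_predict(emb)
        aris[i] = adjusted_rand_score(truth, pred)
    return aris


# ---------------------------------------------------------------------------
# dropouts vs true zeros


@dataclass
class ZeroFractionBins:
    """Per-bin fraction of near-zero single-cell entries.

    Bin 0 holds genes whose bulk reference is exactly zero; the remaining
    bins split (0, max_expression] into equal widths. ``fractions`` is NaN
    for bins containing no genes.
    """

    fractions: np.ndarray
    bin_edges: np.ndarray
    genes_per_bin: np.ndarray


def zero_fraction_by_bins(
    single: ExpressionMatrix | np.ndarray,
    bulk_reference: np.ndarray,
    n_bins: int = 10,
    zero_threshold: float = 0.5,
    max_expression: float = 500.0,
) -> ZeroFractionBins:
    """Fraction of (imputed) zeros per bin of matched bulk expression.

    A value below ``zero_threshold`` counts as a zero — an imputed count in
    [0, 0.5) is still a zero call. Genes with bulk expression above
    ``max_expression`` are excluded. The fraction in each bin is taken over
    all entries of that bin's genes across all cells.
    """
    values = single.values if isinstance(single, ExpressionMatrix) else np.asarray(single)
    bulk = np.asarray(bulk_reference, dtype=float)
    if bulk.shape[0] != values.shape[1]:
        raise ValidationError(
            f"bulk reference covers {bulk.shape[0]} genes, matrix has {values.shape[1]}"
        )
    in_range = bulk <= max_expression
    edges = np.linspace(0.0, max_expression, n_bins)  # edges of bins 1..n-1
    fractions = np.full(n_bins, np.nan)
    genes_per_bin = np.zeros(n_bins, dtype=int)
    # bin 0: exactly-zero bulk genes; bins 1..n-1: equal width over (0, max]
    bin_of = np.full(bulk.shape[0], -1, dtype=int)
    zero_genes = in_range & (bulk == 0)
    bin_of[zero_genes] = 0
    pos = in_range & (bulk > 0)
    bin_of[pos] = np.clip(np.searchsorted(edges, bulk[pos], side="left"), 1, n_bins - 1)
    for b in range(n_bins):
        genes = np.flatnonzero(bin_of == b)
        genes_per_bin[b] = genes.size
        if genes.size:
            block = values[:, genes]
            fractions[b] = float(np.mean(block < zero_threshold))
    return ZeroFractionBins(fractions=fractions, bin_edges=edges, genes_per_bin=genes_per_bin)


# ---------------------------------------------------------------------------
# CV-mean relation


@dataclass
class CVMeanRelation:
    """Per-gene (log10 mean, log10 CV) cloud with fitted and reference lines.

    Under pure Poisson sampling noise CV = mean^(-1/2), i.e. a line of slope
    -1/2 in log-log space; ``slope``/``intercept`` are the least-squares fit
    to the actual cloud, ``reference_slope`` is the Poisson -0.5.
    """

    gene_ids: list[str]
    log10_mean: np.ndarray
    log10_cv: np.ndarray
    slope: float
    intercept: float
    reference_slope: float = -0.5
    n_excluded: int = 0


def cv_mean_relation(E: ExpressionMatrix | np.ndarray) -> CVMeanRelation:
    """Mean-CV relation across genes; genes with zero mean or zero CV are
    excluded (their logs are undefined)."""
    if isinstance(E, ExpressionMatrix):
        values, gene_ids = E.values, E.gene_ids
    else:
        values = np.asarray(E, dtype=float)
        gene_ids = [f"G{j}" for j in range(values.shape[1])]
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mean
    ok = (mean > 0) & (cv > 0) & np.isfinite(cv)
    n_excluded = int((~ok).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} genes excluded from CV-mean relation "
            "(zero mean or zero variance)",
            stacklevel=2,
        )
    if ok.sum() < 2:
        raise ValidationError("need >= 2 genes with defined CV")
    lm, lcv = np.log10(mean[ok]), np.log10(cv[ok])
    slope, intercept = np.polyfit(lm, lcv, 1)
    return CVMeanRelation(
        gene_ids=[g for g, o in zip(gene_ids, ok) if o],
        log10_mean=lm,
        log10_cv=lcv,
        slope=float(slope),
        intercept=float(intercept),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# embedding quality


def silhouette_on_embedding(
    embedding: np.ndarray, labels: CellLabels
) -> float:
    """Mean silhouette (Euclidean) of cells on a provided 2-D embedding.

    Cells in singleton groups get silhouette 0 (with a warning) rather than
    failing the whole computation.
    """
    emb = np.asarray(embedding, dtype=float)
    lab = labels.as_array()
    if emb.shape[0] != lab.shape[0]:
        raise ValidationError(
            f"embedding has {emb.shape[0]} points, labels {lab.shape[0]}"
        )
    uniq, counts = np.unique(lab, return_counts=True)
    if uniq.size < 2:
        raise ValidationError("silhouette needs >= 2 groups")
    if (counts == 1).any():
        warnings.warn(
            "singleton group(s) present; their cells' silhouette is 0",
            stacklevel=2,
        )
    if np.allclose(emb, emb[0]):
        return 0.0
    return float(np.mean(silhouette_samples(emb, lab)))


# ---------------------------------------------------------------------------
# differential expression


@dataclass
class DEResult:
    """Per-gene two-sided rank-sum p-values and the induced ranking."""

    gene_ids: list[str]
    p_values: np.ndarray
    ranking: np.ndarray  # gene indices sorted by ascending p


def wilcoxon_de(
    E: ExpressionMatrix,
    labels: CellLabels,
    group_a: str,
    group_b: str,
) -> DEResult:
    """Wilcoxon rank-sum (Mann-Whitney) DE test per gene between two groups.

    The exact null distribution is enumerated for small tie-free samples
    (combined n <= 25); larger or tied samples use the normal approximation
    with tie correction. A gene with all values tied gets p = 1.
    """
    labels = labels.aligned_to(E)
    idx_a = labels.indices_of(group_a)
    idx_b = labels.indices_of(group_b)
    for g, idx in ((group_a, idx_a), (group_b, idx_b)):
        if idx.size < 2:
            raise ValidationError(f"group {g!r} has {idx.size} cell(s); need >= 2")
    n_small = idx_a.size + idx_b.size <= 25
    pvals = np.empty(E.n_genes)
    n_all_tied = 0
    for j in range(E.n_genes):
        xa = E.values[idx_a, j]
        xb = E.values[idx_b, j]
        combined = np.concatenate([xa, xb])
        if np.all(combined == combined[0]):
            pvals[j] = 1.0
            n_all_tied += 1
            continue
        has_ties = np.unique(combined).size < combined.size
        method = "exact" if (n_small and not has_ties) else "asymptotic"
        pvals[j] = stats.mannwhitneyu(
            xa, xb, alternative="two-sided", method=method
        ).pvalue
    if n_all_tied:
        warnings.warn(
            f"{n_all_tied} genes with all values tied; p set to 1", stacklevel=2
        )
    ranking = np.argsort(pvals, kind="stable")
    return DEResult(gene_ids=list(E.gene_ids), p_values=pvals, ranking=ranking)


def de_auc(de: DEResult, is_de_truth: np.ndarray) -> float:
    """ROC AUC of the DE ranking against a caller-supplied ground truth.

    ``is_de_truth`` is a boolean per gene; genes are scored by -p so that
    smaller p-values rank as more confidently DE.
    """
    truth = np.asarray(is_de_truth, dtype=bool)
    if truth.shape[0] != de.p_values.shape[0]:
        raise ValidationError("ground-truth labeling length mismatch")
    return float(roc_auc_score(truth, -de.p_values))


# ---------------------------------------------------------------------------
# low-rank diagnostic


def singular_spectrum(
    E: ExpressionMatrix | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Descending singular values and cumulative squared-energy fractions.

    A sharply saturating energy curve is the empirical footprint of the
    low-rank structure the completion model assumes.
    """
    values = E.values if isinstance(E, ExpressionMatrix) else np.asarray(E, dtype=float)
    s = np.linalg.svd(values, compute_uv=False)
    power = s**2
    total = power.sum()
    energy = np.cumsum(power) / total if total > 0 else np.zeros_like(power)
    return s, energy
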