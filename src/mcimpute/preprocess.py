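"""Preprocessing pipeline: gene filtering, library-size normalization,
log transform — and the exact inverses needed to report imputed matrices on
all three scales (log, normalized, counts).

A gene counts as expressed when it reaches ``min_reads`` reads in at least
``min_cells`` cells (defaults 3 and 3). Library-size normalization divides
each cell by its total count and rescales by the median total across cells,
so every cell ends up with the same total. The log transform is
log2(x + pseudocount) with pseudocount 1.

The reverse direction is not free: library-size normalization loses the
per-cell totals. ``NormalizationRecord`` captures them at forward time so
``denormalize`` can invert exactly. Imputed counts come back fractional —
rounding would destroy small imputed values near the 0.5 zero-convention
used in the dropout analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import ExpressionMatrix, ValidationError

__all__ = [
    "PreprocessConfig",
    "NormalizationRecord",
    "filter_genes",
    "library_size_normalize",
    "log_transform",
    "inverse_log_transform",
    "denormalize",
    "preprocess",
]


@dataclass
class PreprocessConfig:
    """Knobs for the forward pipeline.

    ``filter=False`` skips gene filtering entirely — needed e.g. for
    dropout-vs-true-zero analyses where every gene must be retained.
    """

    filter: bool = True
    min_reads: int = 3
    min_cells: int = 3
    pseudocount: float = 1.0


@dataclass
class NormalizationRecord:
    """Per-cell totals and their median, captured during normalization."""

    totals: np.ndarray
    median: float


def filter_genes(
    E: ExpressionMatrix,
    min_reads: int = 3,
    min_cells: int = 3,
) -> ExpressionMatrix:
    """Keep genes detected with >= ``min_reads`` reads in >= ``min_cells`` cells.

    Cell set and gene order are unchanged. Raises if no gene survives.
    """
    if E.layer != "counts":
        raise ValidationError(f"filter_genes expects counts, got layer {E.layer!r}")
    n_cells_expressing = np.count_nonzero(E.values >= min_reads, axis=0)
    keep = n_cells_expressing >= min_cells
    if not keep.any():
        raise ValidationError(
            f"no gene has >= {min_reads} reads in >= {min_cells} cells; "
            "lower the thresholds or skip filtering"
        )
    return E.subset_genes(keep)


def library_size_normalize(
    E: ExpressionMatrix,
) -> tuple[ExpressionMatrix, NormalizationRecord]:
    """Divide each cell by its total count, then scale by the median total.

    After this every cell's total equals the median of the original totals.
    Returns the normalized matrix plus the record needed to invert.
    """
    if E.layer != "counts":
        raise ValidationError(
            f"library_size_normalize expects counts, got layer {E.layer!r}"
        )
    totals = E.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            f"cell {E.cell_ids[zero[0]]!r} has zero total count"
        )
    median = float(np.median(totals))
    out = E.values / totals[:, None] * median
    return (
        E.with_values(out, layer="normalized"),
        NormalizationRecord(totals=totals, median=median),
    )


def log_transform(E: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount); pseudocount 1 keeps zeros at zero."""
    if pseudocount <= 0:
        raise ValidationError(f"pseudocount must be > 0, got {pseudocount}")
    return E.with_values(np.log2(E.values + pseudocount), layer="log")


def inverse_log_transform(
    E: ExpressionMatrix, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """2**x - pseudocount, clipped at 0: exact inverse of ``log_transform``."""
    if E.layer != "log":
        raise ValidationError(
            f"inverse_log_transform expects log layer, got {E.layer!r}"
        )
    if pseudocount <= 0:
        raise ValidationError(f"pseudocount must be > 0, got {pseudocount}")
    vals = np.exp2(E.values) - pseudocount
    return E.with_values(np.clip(vals, 0.0, None), layer="normalized")


def denormalize(
    E: ExpressionMatrix, record: NormalizationRecord
) -> ExpressionMatrix:
    """Invert library-size normalization using the stored totals and median.

    The result is tagged ``counts`` but stays fractional after imputation.
    """
    if E.layer != "normalized":
        raise ValidationError(f"denormalize expects normalized layer, got {E.layer!r}")
    if record is None or record.totals is None:
        raise ValidationError("no stored normalization record")
    totals = np.asarray(record.totals, dtype=float)
    if totals.shape[0] != E.n_cells:
        raise ValidationError(
            f"stored totals cover {totals.shape[0]} cells, matrix has {E.n_cells}"
        )
    if record.median == 0:
        raise ValidationError("stored median total is zero")
    out = E.values * totals[:, None] / record.median
    return E.with_values(out, layer="counts")


def preprocess(
    E: ExpressionMatrix, cfg: PreprocessConfig | None = None
) -> tuple[ExpressionMatrix, NormalizationRecord]:
    """Full forward pipeline: (filter) -> normalize -> log.

    Returns the log-layer matrix ready for imputation plus the normalization
    record for the way back.
    """
    cfg = cfg or PreprocessConfig()
    if cfg.filter:
        E = filter_genes(E, cfg.min_reads, cfg.min_cells)
    normalized, record = library_size_normalize(E)
    logged = log_transform(normalized, cfg.pseudocount)
    return logged, record
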