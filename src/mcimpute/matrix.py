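"""Core in-memory containers: expression matrices and cell-group labels.

The whole package works on a single canonical orientation: rows are cells,
columns are genes. Every reader converts to this orientation at the boundary,
so downstream code never needs to ask which way a matrix is facing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

Layer = Literal["counts", "normalized", "log"]

__all__ = ["ExpressionMatrix", "CellLabels", "Layer"]


class ValidationError(ValueError):
    """Raised when a matrix or label set violates its structural contract."""


def _check_unique(ids: Sequence[str], axis: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {axis} identifier: {dup!r}")


@dataclass
class ExpressionMatrix:
    """A non-negative cells x genes expression matrix with a layer tag.

    Parameters
    ----------
    values
        Dense float array of shape ``(n_cells, n_genes)``; all entries >= 0.
        The log layer is also non-negative because log2(x + 1) >= 0 for x >= 0.
    cell_ids, gene_ids
        Unique identifiers for rows and columns respectively.
    layer
        Which stage of the preprocessing pipeline the values represent:
        raw ``counts``, library-size ``normalized``, or ``log`` (log2(x+1)).
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    layer: Layer = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(
                f"expected a 2-D matrix, got shape {self.values.shape}"
            )
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        m, n = self.values.shape
        if m == 0 or n == 0:
            raise ValidationError(f"matrix is degenerate: shape {m} x {n}")
        if len(self.cell_ids) != m:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {m} rows"
            )
        if len(self.gene_ids) != n:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n} columns"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("matrix contains non-finite values")
        if np.any(self.values < 0):
            c, g = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative entry {self.values[c, g]} at cell "
                f"{self.cell_ids[c]!r}, gene {self.gene_ids[g]!r}"
            )
        if self.layer not in ("counts", "normalized", "log"):
            raise ValidationError(f"unknown layer {self.layer!r}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, layer: Layer | None = None) -> "ExpressionMatrix":
        """Copy of this matrix with new values (same ids), optionally retagged."""
        return ExpressionMatrix(
            values=np.asarray(values, dtype=float),
            cell_ids=list(self.cell_ids),
            gene_ids=list(self.gene_ids),
            layer=layer if layer is not None else self.layer,
        )

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Column subset by boolean mask or integer index array, order preserved."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return ExpressionMatrix(
            values=self.values[:, idx],
            cell_ids=list(self.cell_ids),
            gene_ids=[self.gene_ids[i] for i in idx],
            layer=self.layer,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.n_cells} cells x {self.n_genes} genes, "
            f"layer={self.layer!r})"
        )


@dataclass
class CellLabels:
    """Group membership (e.g. annotated cell types) aligned to a matrix's cells."""

    labels: list[str]
    cell_ids: list[str] | None = None
    groups: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        if not self.labels:
            raise ValidationError("label set is empty")
        if self.cell_ids is not None:
            self.cell_ids = [str(c) for c in self.cell_ids]
            if len(self.cell_ids) != len(self.labels):
                raise ValidationError("cell_ids and labels differ in length")
            _check_unique(self.cell_ids, "cell")
        # distinct group names in first-appearance order
        self.groups = list(dict.fromkeys(self.labels))

    def __len__(self) -> int:
        return len(self.labels)

    def aligned_to(self, matrix: ExpressionMatrix) -> "CellLabels":
        """Reorder labels to the matrix's cell order; error on unknown cells."""
        if self.cell_ids is None:
            if len(self.labels) != matrix.n_cells:
                raise ValidationError(
                    f"{len(self.labels)} labels for {matrix.n_cells} cells and "
                    "no cell ids to align by"
                )
            return CellLabels(list(self.labels), list(matrix.cell_ids))
        by_id = dict(zip(self.cell_ids, self.labels))
        missing = [c for c in matrix.cell_ids if c not in by_id]
        if missing:
            raise ValidationError(f"no label for cell {missing[0]!r}")
        unknown = set(self.cell_ids) - set(matrix.cell_ids)
        if unknown:
            raise ValidationError(
                f"label refers to unknown cell {sorted(unknown)[0]!r}"
            )
        return CellLabels(
            [by_id[c] for c in matrix.cell_ids], list(matrix.cell_ids)
        )

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def indices_of(self, group: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.labels, dtype=object) == group)
        if idx.size == 0:
            raise ValidationError(f"no cells labelled {group!r}")
        return idx
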