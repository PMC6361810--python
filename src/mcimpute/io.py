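"""Readers and writers for expression matrices and cell labels.

Supported on-disk forms:

* dense delimited text (CSV/TSV) with a header row and an index column;
* Matrix Market coordinate format (``.mtx``, 1-based per the standard) with
  companion ``genes.tsv`` / ``barcodes.tsv`` lists, the 10x convention;
* labels as one- or two-column delimited text.

Whatever the on-disk orientation, the in-memory result is always
rows = cells, columns = genes.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .matrix import CellLabels, ExpressionMatrix, Layer, ValidationError

Format = Literal["csv", "tsv", "mtx"]
Orientation = Literal["cells_by_genes", "genes_by_cells"]

__all__ = ["read_counts", "read_labels", "write_matrix", "write_labels"]

_DELIMS = {"csv": ",", "tsv": "\t"}


class ParseError(ValueError):
    """A file could not be parsed in the declared format."""


def _companion_paths(mtx_path: Path) -> tuple[Path, Path]:
    d = mtx_path.parent
    return d / "genes.tsv", d / "barcodes.tsv"


def read_counts(
    path: str | os.PathLike,
    format: Format = "csv",
    orientation: Orientation = "cells_by_genes",
    layer: Layer = "counts",
    header: bool = True,
    gene_file: str | os.PathLike | None = None,
    barcode_file: str | os.PathLike | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix, normalizing orientation to rows = cells.

    Parameters
    ----------
    path
        The matrix file. For ``mtx``, companion ``genes.tsv`` and
        ``barcodes.tsv`` are looked up next to it unless given explicitly.
    format
        ``csv``, ``tsv`` (dense, header row + index column unless
        ``header=False``) or ``mtx`` (Matrix Market triplets, 1-based).
    orientation
        Which axis the *file* rows represent. The returned matrix is always
        cells x genes.
    header
        Dense formats only: set False for headerless files, in which case
        positional identifiers are synthesized.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if format in _DELIMS:
        sep = _DELIMS[format]
        try:
            if header:
                df = pd.read_csv(path, sep=sep, index_col=0)
            else:
                df = pd.read_csv(path, sep=sep, header=None)
        except Exception as exc:  # pandas raises several parser error types
            raise ParseError(f"cannot parse {path} as {format}: {exc}") from exc
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ParseError(f"{path} parsed to an empty matrix")
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-numeric entry in {path}: {exc}") from exc
        if header:
            row_ids = [str(i) for i in df.index]
            col_ids = [str(c) for c in df.columns]
        else:
            row_ids = [f"R{i}" for i in range(df.shape[0])]
            col_ids = [f"C{j}" for j in range(df.shape[1])]
    elif format == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise ParseError(f"cannot parse {path} as Matrix Market: {exc}") from exc
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        default_genes, default_barcodes = _companion_paths(path)
        gene_file = Path(gene_file) if gene_file else default_genes
        barcode_file = Path(barcode_file) if barcode_file else default_barcodes
        genes = _read_id_list(gene_file, "gene")
        barcodes = _read_id_list(barcode_file, "barcode")
        if orientation == "genes_by_cells":
            row_ids, col_ids = genes, barcodes
        else:
            row_ids, col_ids = barcodes, genes
    else:
        raise ValueError(f"unknown format {format!r}")

    if orientation == "genes_by_cells":
        values = values.T
        cell_ids, gene_ids = col_ids, row_ids
    elif orientation == "cells_by_genes":
        cell_ids, gene_ids = row_ids, col_ids
    else:
        raise ValueError(f"unknown orientation {orientation!r}")

    return ExpressionMatrix(values, cell_ids, gene_ids, layer=layer)


def _read_id_list(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(
            f"mtx input needs a companion {what} list; {path} not found"
        )
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                # 10x genes.tsv carries (id, symbol); keep the first column
                ids.append(line.split("\t")[0])
    if not ids:
        raise ParseError(f"{path} is empty")
    return ids


def read_labels(path: str | os.PathLike) -> CellLabels:
    """Read cell-group labels from one- or two-column delimited text.

    Two columns are interpreted as (cell_id, group); a single column is taken
    as groups in matrix cell order. A header line is detected and skipped when
    its first field is one of the conventional names.
    """
    path = Path(path)
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            rows.append(line.split("\t") if "\t" in line else line.split(","))
    if rows and rows[0][0].strip().lower() in {"cell", "cell_id", "barcode", "id"}:
        rows = rows[1:]
    if not rows:
        raise ParseError(f"label file {path} is empty")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ParseError(f"ragged rows in label file {path}")
    if width == 1:
        return CellLabels([r[0].strip() for r in rows])
    cell_ids = [r[0].strip() for r in rows]
    labels = [r[1].strip() for r in rows]
    if len(set(cell_ids)) != len(cell_ids):
        raise ValidationError(f"duplicate cell ids in label file {path}")
    return CellLabels(labels, cell_ids)


def write_matrix(
    E: ExpressionMatrix,
    path: str | os.PathLike,
    format: Format = "csv",
    orientation: Orientation = "cells_by_genes",
) -> None:
    """Write a matrix so that ``read_counts`` round-trips it.

    CSV/TSV preserve values to full float precision (17 significant digits);
    mtx writes a coordinate triplet file plus ``genes.tsv`` / ``barcodes.tsv``
    companions next to it.
    """
    path = Path(path)
    if format in _DELIMS:
        df = pd.DataFrame(E.values, index=E.cell_ids, columns=E.gene_ids)
        if orientation == "genes_by_cells":
            df = df.T
        df.to_csv(path, sep=_DELIMS[format], float_format="%.17g")
    elif format == "mtx":
        dense = E.values if orientation == "cells_by_genes" else E.values.T
        is_int = E.layer == "counts" and np.array_equal(E.values, np.round(E.values))
        sp = scipy.sparse.coo_matrix(dense.astype(np.int64) if is_int else dense)
        scipy.io.mmwrite(path, sp, field="integer" if is_int else "real", precision=17)
        gene_path, barcode_path = _companion_paths(path)
        _write_id_list(gene_path, E.gene_ids)
        _write_id_list(barcode_path, E.cell_ids)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_id_list(path: Path, ids: list[str]) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")


def write_labels(labels: CellLabels, path: str | os.PathLike) -> None:
    """Write labels as two-column TSV (cell_id, group)."""
    cell_ids = labels.cell_ids or [f"R{i}" for i in range(len(labels))]
    with open(path, "w") as fh:
        for c, l in zip(cell_ids, labels.labels):
            fh.write(f"{c}\t{l}\n")
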