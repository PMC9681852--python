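"""Expression-matrix container and text-format readers/writers.

The in-memory convention everywhere in this package is rows = cells,
columns = genes.  Files stored genes x cells (e.g. 10x-style Matrix Market
triplets) are handled with ``transpose=True``.

Supported formats:

``dense_csv`` / ``dense_tsv``
    Optional header row of gene identifiers, optional first column of cell
    identifiers; both are auto-detected (a leading row/column is treated as
    identifiers when it contains non-numeric tokens).
``mtx_triplet``
    Matrix Market coordinate file with two optional one-column sidecars next
    to it: ``barcodes.tsv`` (cell identifiers) and ``features.tsv`` (gene
    identifiers).  Missing sidecars yield auto-generated identifiers.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .errors import MatrixParseError, ParameterError

FORMATS = ("dense_csv", "dense_tsv", "mtx_triplet")

_BARCODE_SIDECAR = "barcodes.tsv"
_FEATURE_SIDECAR = "features.tsv"


@dataclasses.dataclass
class ExpressionMatrix:
    """A cells x genes matrix of nonnegative, finite expression values.

    Units are whatever the source provides (raw counts, TPM, or arbitrary
    normalized values); no rescaling happens on construction.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    #: z-score-integrated matrices are signed; everything else must be >= 0.
    allow_negative: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError(f"expected a 2-D matrix, got ndim={self.values.ndim}")
        q, m = self.values.shape
        if q == 0 or m == 0:
            raise ParameterError(f"empty matrix of shape {self.values.shape} is not allowed")
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.cell_ids) != q:
            raise ParameterError(f"{len(self.cell_ids)} cell ids for {q} rows")
        if len(self.gene_ids) != m:
            raise ParameterError(f"{len(self.gene_ids)} gene ids for {m} columns")
        if len(set(self.cell_ids)) != q:
            raise ParameterError("cell identifiers are not unique")
        if len(set(self.gene_ids)) != m:
            raise ParameterError("gene identifiers are not unique")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MatrixParseError(f"non-finite value at cell {i}, gene {j}")
        neg = self.values < 0 if not self.allow_negative else np.zeros_like(self.values, dtype=bool)
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise MatrixParseError(
                f"negative value {self.values[i, j]} at cell {i} ({self.cell_ids[i]}), "
                f"gene {j} ({self.gene_ids[j]})"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.cell_ids), list(self.gene_ids), self.allow_negative
        )

    def transposed(self) -> "ExpressionMatrix":
        """Swap axes, exchanging cell and gene identifiers."""
        return ExpressionMatrix(
            self.values.T.copy(), list(self.gene_ids), list(self.cell_ids), self.allow_negative
        )

    def subset(self, rows: Sequence[int] | None = None, cols: Sequence[int] | None = None) -> "ExpressionMatrix":
        rows = np.arange(self.n_cells) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_genes) if cols is None else np.asarray(cols)
        return ExpressionMatrix(
            self.values[np.ix_(rows, cols)].copy(),
            [self.cell_ids[i] for i in rows],
            [self.gene_ids[j] for j in cols],
        )


def default_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i}" for i in range(n)]


def _is_number(token: str) -> bool:
    try:
        float(token)
    except (TypeError, ValueError):
        return False
    return True


def _read_dense(path: Path, sep: str) -> ExpressionMatrix:
    try:
        raw = pd.read_csv(path, sep=sep, header=None, dtype=str, comment=None)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MatrixParseError(f"{path}: could not read file ({exc})") from exc
    if raw.empty:
        raise MatrixParseError(f"{path}: file is empty")
    first_row = raw.iloc[0].tolist()
    first_col = raw.iloc[:, 0].tolist()
    # A header / index is present when the candidate row/column contains
    # non-numeric tokens (beyond the shared corner cell).
    has_header = any(not _is_number(t) for t in first_row[1:]) or (
        len(first_row) == 1 and not _is_number(first_row[0])
    )
    has_index = any(not _is_number(t) for t in first_col[1:])
    df = pd.read_csv(
        path,
        sep=sep,
        header=0 if has_header else None,
        index_col=0 if has_index else None,
    )
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        for (i, j), v in np.ndenumerate(values):
            if not _is_number(v):
                raise MatrixParseError(f"{path}: non-numeric entry {v!r} at row {i}, column {j}")
        values = values.astype(float)
    gene_ids = [str(c) for c in df.columns] if has_header else default_ids("gene", values.shape[1])
    cell_ids = [str(r) for r in df.index] if has_index else default_ids("cell", values.shape[0])
    return _finish(path, values, cell_ids, gene_ids)


def _read_sidecar(path: Path) -> list[str] | None:
    if not path.exists():
        return None
    names = [line.split("\t")[0].strip() for line in path.read_text().splitlines() if line.strip()]
    return names or None


def _read_mtx(path: Path) -> ExpressionMatrix:
    header = path.read_text().splitlines()[0].lower() if path.exists() else ""
    if "pattern" in header or "complex" in header:
        raise MatrixParseError(f"{path}: pattern/complex Matrix Market fields are not supported")
    try:
        mat = spio.mmread(path)
    except Exception as exc:
        raise MatrixParseError(f"{path}: malformed Matrix Market file ({exc})") from exc
    values = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
    rows = _read_sidecar(path.parent / _BARCODE_SIDECAR)
    cols = _read_sidecar(path.parent / _FEATURE_SIDECAR)
    cell_ids = rows if rows is not None else default_ids("cell", values.shape[0])
    gene_ids = cols if cols is not None else default_ids("gene", values.shape[1])
    if len(cell_ids) != values.shape[0] or len(gene_ids) != values.shape[1]:
        raise MatrixParseError(
            f"{path}: sidecar lengths ({len(cell_ids)}, {len(gene_ids)}) do not match "
            f"matrix shape {values.shape}"
        )
    return _finish(path, values, cell_ids, gene_ids)


def _finish(path: Path, values: np.ndarray, cell_ids: list[str], gene_ids: list[str]) -> ExpressionMatrix:
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise MatrixParseError(f"{path}: NaN at row {i}, column {j}")
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise MatrixParseError(f"{path}: negative value {values[i, j]} at row {i}, column {j}")
    return ExpressionMatrix(values, cell_ids, gene_ids)


def read_matrix(path: str | Path, format: str = "dense_csv", transpose: bool = False) -> ExpressionMatrix:
    """Read an expression matrix, returning it in cells x genes orientation.

    Parameters
    ----------
    path
        File to read (for ``mtx_triplet``, the ``.mtx`` file; sidecars are
        looked up next to it).
    format
        One of ``dense_csv``, ``dense_tsv``, ``mtx_triplet``.
    transpose
        Set when the source is stored genes x cells; the matrix (and its
        identifier sidecars) are flipped so that rows are cells.
    """
    path = Path(path)
    if format not in FORMATS:
        raise ParameterError(f"unknown format {format!r}; expected one of {FORMATS}")
    if not path.exists():
        raise ParameterError(f"{path}: no such file")
    if format == "mtx_triplet":
        mat = _read_mtx(path)
    else:
        mat = _read_dense(path, "," if format == "dense_csv" else "\t")
    return mat.transposed() if transpose else mat


def write_matrix(matrix: ExpressionMatrix, path: str | Path, format: str = "dense_csv") -> None:
    """Write a matrix in one of the supported text formats (cells x genes on disk)."""
    path = Path(path)
    if format not in FORMATS:
        raise ParameterError(f"unknown format {format!r}; expected one of {FORMATS}")
    try:
        if format == "mtx_triplet":
            spio.mmwrite(path, sparse.coo_matrix(matrix.values))
            (path.parent / _BARCODE_SIDECAR).write_text("\n".join(matrix.cell_ids) + "\n")
            (path.parent / _FEATURE_SIDECAR).write_text("\n".join(matrix.gene_ids) + "\n")
        else:
            sep = "," if format == "dense_csv" else "\t"
            df = pd.DataFrame(matrix.values, index=matrix.cell_ids, columns=matrix.gene_ids)
            df.to_csv(path, sep=sep)
    except OSError as exc:
        raise ParameterError(f"{path}: cannot write ({exc})") from exc
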