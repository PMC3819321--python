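"""Reading, validating and writing expression matrices, gene lists and
scaling-factor vectors.

The on-disk formats are deliberately plain:

* expression matrix — delimited table, first column gene identifiers,
  header row of sample identifiers, every cell a non-negative real;
* gene list — one gene id per line, optional second column with a
  positive weight (defaults to 1);
* factor vector — two-column table ``sample<TAB>factor``.

The in-memory container for a matrix is a :class:`pandas.DataFrame` with
genes on the index (rows) and samples on the columns.  Validation lives in
:func:`validate_matrix` and is shared by every reader and estimator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._exceptions import FormatError

__all__ = [
    "validate_matrix",
    "read_matrix",
    "write_matrix",
    "read_gene_list",
    "read_factors",
    "write_factors",
]


def validate_matrix(matrix: pd.DataFrame, min_genes: int = 2, min_samples: int = 2) -> pd.DataFrame:
    """Validate a gene x sample expression matrix, returning it unchanged.

    Checks: no duplicate gene or sample identifiers, all values finite and
    non-negative, at least ``min_genes`` rows and ``min_samples`` columns.
    Missing values are not permitted; absence must be encoded as 0.
    """
    if not isinstance(matrix, pd.DataFrame):
        raise FormatError("expression matrix must be a pandas DataFrame (genes x samples)")
    if matrix.shape[0] < min_genes or matrix.shape[1] < min_samples:
        raise FormatError(
            f"matrix of shape {matrix.shape} is too small: "
            f"need at least {min_genes} genes and {min_samples} samples"
        )
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene identifiers: {dupes[:5]}")
    if matrix.columns.has_duplicates:
        dupes = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample identifiers: {dupes[:5]}")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = _first_nonnumeric(matrix)
        raise FormatError(f"non-numeric value at gene {bad[0]!r}, sample {bad[1]!r}")
    if np.isnan(values).any():
        g, k = np.argwhere(np.isnan(values))[0]
        raise FormatError(
            f"missing value at gene {matrix.index[g]!r}, sample {matrix.columns[k]!r}; "
            "encode absence as 0"
        )
    if (values < 0).any():
        g, k = np.argwhere(values < 0)[0]
        raise FormatError(
            f"negative value {values[g, k]!r} at gene {matrix.index[g]!r}, "
            f"sample {matrix.columns[k]!r}"
        )
    if not np.isfinite(values).all():
        g, k = np.argwhere(~np.isfinite(values))[0]
        raise FormatError(f"non-finite value at gene {matrix.index[g]!r}, sample {matrix.columns[k]!r}")
    return matrix


def _first_nonnumeric(matrix: pd.DataFrame) -> tuple[str, str]:
    for k, col in matrix.items():
        coerced = pd.to_numeric(col, errors="coerce")
        bad = coerced.isna() & col.notna()
        if bad.any():
            return str(col.index[bad][0]), str(k)
    return "?", "?"


def read_matrix(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a gene x sample expression matrix from a delimited text file.

    The first row must be a header of sample identifiers and the first
    column gene identifiers; every remaining cell must parse as a
    non-negative real.  Row and column order are preserved exactly.
    """
    try:
        raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty matrix file") from exc
    if raw.shape[1] == 0 or raw.shape[0] == 0:
        raise FormatError(f"{path}: matrix has no data cells")
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        g, k = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell {raw.iat[g, k]!r} at gene "
            f"{raw.index[g]!r}, sample {raw.columns[k]!r}"
        )
    matrix = numeric.astype(float)
    return validate_matrix(matrix, min_genes=1, min_samples=1)


def write_matrix(matrix: pd.DataFrame, path, delimiter: str = "\t", precision: int | None = None) -> None:
    """Write a matrix as a delimited table.

    With ``precision=None`` values are written with full ``repr`` precision
    (lossless round trip); otherwise with ``precision`` digits after the
    decimal point.
    """
    fmt = None if precision is None else f"%.{precision}f"
    matrix.to_csv(path, sep=delimiter, float_format=fmt)


def read_gene_list(path) -> pd.Series:
    """Read a gene list with optional weights into a Series gene_id -> weight.

    One gene per line; an optional second (tab- or whitespace-separated)
    column gives a positive weight, defaulting to 1.  Input order is
    preserved.
    """
    genes: list[str] = []
    weights: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            gene = parts[0]
            if gene in genes:
                raise FormatError(f"{path}:{lineno}: duplicate gene {gene!r}")
            if len(parts) == 1:
                w = 1.0
            else:
                try:
                    w = float(parts[1])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric weight {parts[1]!r}") from exc
                if not np.isfinite(w) or w <= 0:
                    raise FormatError(f"{path}:{lineno}: weight must be positive, got {parts[1]!r}")
            genes.append(gene)
            weights.append(w)
    if not genes:
        raise FormatError(f"{path}: empty gene list")
    return pd.Series(weights, index=pd.Index(genes, name="gene"), name="weight")


def read_factors(path, delimiter: str = "\t") -> pd.Series:
    """Read a two-column sample -> factor table into a Series."""
    table = pd.read_csv(path, sep=delimiter, index_col=0)
    if table.shape[1] != 1:
        raise FormatError(f"{path}: expected two columns (sample, factor), got {table.shape[1] + 1}")
    factors = table.iloc[:, 0].astype(float)
    factors.index = factors.index.astype(str)
    if (factors <= 0).any() or not np.isfinite(factors).all():
        bad = factors.index[(factors <= 0) | ~np.isfinite(factors)][0]
        raise FormatError(f"{path}: non-positive or non-finite factor for sample {bad!r}")
    factors.name = "factor"
    return factors


def write_factors(factors: pd.Series, path, delimiter: str = "\t") -> None:
    """Write a factor vector as a two-column sample/factor table."""
    out = factors.rename("factor")
    out.index.name = "sample"
    out.to_csv(path, sep=delimiter)
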