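"""Rank-based quantile normalization — the one non-factor method.

Each sample's values are sorted ascending (zeros included, ties broken by
gene-id order); the mean of the values at each rank across samples forms
the target distribution, and every gene receives the mean at its rank.
Genes tied on input value within a sample receive the average of the
rank-means they span, so equal inputs map to equal outputs.

Being non-linear, this transform does not preserve within-sample ratios
and can turn a zero into a nonzero value; it makes the value distribution
of every sample identical while preserving each sample's gene ranking and
the grand sum of the matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._exceptions import DomainError
from .io import validate_matrix
from .scalers import NormalizationResult

__all__ = ["quantile_normalize", "QuantileNormalizer"]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a genes x samples matrix.

    Returns a new matrix in which every column has the same sorted value
    vector (the rank-wise mean of the input columns) and each column's
    gene ranking is unchanged.
    """
    validate_matrix(matrix)
    values = matrix.to_numpy(dtype=float)
    n_genes, n_samples = values.shape
    # gene-id rank used as the tie-break in per-column sorting
    id_rank = np.argsort(np.argsort(matrix.index.to_numpy()))
    orders = np.empty_like(values, dtype=int)
    sorted_vals = np.empty_like(values)
    for k in range(n_samples):
        order = np.lexsort((id_rank, values[:, k]))
        orders[:, k] = order
        sorted_vals[:, k] = values[order, k]
    rank_means = sorted_vals.mean(axis=1)
    out = np.empty_like(values)
    for k in range(n_samples):
        out[orders[:, k], k] = rank_means
    result = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    # tie policy: genes sharing an input value within a column share the
    # average of the rank-means their ranks span
    for k in matrix.columns:
        col = matrix[k]
        if col.duplicated().any():
            result[k] = result[k].groupby(col).transform("mean")
    return result


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """scikit-learn style wrapper around :func:`quantile_normalize`.

    ``fit`` learns the rank-wise mean distribution of the fitted matrix;
    ``fit_transform`` performs the joint normalization described above.
    ``transform`` on new data maps each column onto the learned
    distribution (same gene count required).
    """

    method_name = "quantile"

    def fit(self, X: pd.DataFrame, y=None):
        X = validate_matrix(X)
        values = X.to_numpy(dtype=float)
        self.rank_means_ = np.sort(values, axis=0).mean(axis=1)
        self.n_genes_ = X.shape[0]
        return self

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        self.fit(X)
        return quantile_normalize(X)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "rank_means_"):
            raise DomainError("normalizer is not fitted")
        X = validate_matrix(X)
        if X.shape[0] != self.n_genes_:
            raise DomainError(
                f"matrix has {X.shape[0]} genes but the normalizer was fitted on {self.n_genes_}"
            )
        id_rank = np.argsort(np.argsort(X.index.to_numpy()))
        out = X.copy()
        for k in X.columns:
            order = np.lexsort((id_rank, X[k].to_numpy(dtype=float)))
            col = np.empty(self.n_genes_)
            col[order] = self.rank_means_
            out[k] = col
            if X[k].duplicated().any():
                out[k] = out[k].groupby(X[k]).transform("mean")
        return out

    def result(self, X: pd.DataFrame) -> NormalizationResult:
        return NormalizationResult(
            method_name=self.method_name,
            matrix=self.fit_transform(X),
            factors=None,
            metadata={"params": self.get_params()},
        )
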