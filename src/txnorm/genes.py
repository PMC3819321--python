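"""Data-driven gene selection: trimmed sets, ubiquitous genes, specific
genes and expression-capped subsets.

A *trimmed set* for a sample is obtained by discarding zero-valued genes,
ranking the remainder by expression (ascending, ties broken by gene-id
order) and keeping only the middle of the distribution.  *Ubiquitous*
genes are those in the trimmed set of (essentially) every sample — a pool
of genes expressed everywhere but never at extreme levels, which the
guide-based normalization methods build on.  *Specific* genes are the
opposite extreme: expressed in one sample above the sum of all others
combined (Jongeneel's specificity), while observed in at least half the
samples.

Two trim profiles are used throughout the package:

* ``DEFAULT_CUTS = (0.30, 0.85)`` — keep the 30th–85th percentile of each
  sample's nonzero expression distribution;
* ``WIDE_CUTS = (0.05, 0.95)`` — a more inclusive 5% trim from each end,
  used by the Stability and network-centrality methods, which benefit from
  a larger candidate pool.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from ._exceptions import DegenerateInputError, DomainError
from .io import validate_matrix

__all__ = [
    "DEFAULT_CUTS",
    "WIDE_CUTS",
    "trimmed_set",
    "ubiquitous_genes",
    "specific_genes",
    "top_expressed_subset",
]

DEFAULT_CUTS = (0.30, 0.85)
WIDE_CUTS = (0.05, 0.95)


def _check_cuts(lower_cut: float, upper_cut: float) -> None:
    if not (0.0 <= lower_cut < upper_cut <= 1.0):
        raise DomainError(f"need 0 <= lower_cut < upper_cut <= 1, got ({lower_cut}, {upper_cut})")


def trimmed_set(
    matrix: pd.DataFrame,
    sample_id: str,
    lower_cut: float = DEFAULT_CUTS[0],
    upper_cut: float = DEFAULT_CUTS[1],
) -> set[str]:
    """Return the trimmed gene set of one sample.

    The ``n`` nonzero genes of the sample are ranked ascending ``r=1..n``
    by expression (ties broken by gene-id order); genes with
    ``lower_cut*n < r <= upper_cut*n`` are kept.  The result is invariant
    under rescaling of the sample, since ranking is scale-free.
    """
    _check_cuts(lower_cut, upper_cut)
    if sample_id not in matrix.columns:
        raise DomainError(f"unknown sample {sample_id!r}")
    col = matrix[sample_id]
    nz = col[col > 0]
    n = len(nz)
    if n == 0:
        raise DegenerateInputError(f"sample {sample_id!r} has no nonzero genes")
    # ascending by (value, gene id): sort ids first, then stable value sort
    nz = nz.loc[sorted(nz.index)].sort_values(kind="stable")
    ranks = np.arange(1, n + 1)
    keep = (ranks > lower_cut * n) & (ranks <= upper_cut * n)
    return set(nz.index[keep])


def ubiquitous_genes(
    matrix: pd.DataFrame,
    lower_cut: float = DEFAULT_CUTS[0],
    upper_cut: float = DEFAULT_CUTS[1],
    min_membership: float = 1.0,
) -> set[str]:
    """Genes in the trimmed set of at least ``ceil(min_membership * N)`` samples.

    With ``min_membership=1`` this is the strict intersection of all
    per-sample trimmed sets, so every member is nonzero in every sample.
    An empty result is legal; callers may retry with ``min_membership=0.8``
    (the library never relaxes silently).
    """
    validate_matrix(matrix)
    if not (0.0 < min_membership <= 1.0):
        raise DomainError(f"min_membership must be in (0, 1], got {min_membership}")
    n_samples = matrix.shape[1]
    needed = math.ceil(min_membership * n_samples)
    counts: dict[str, int] = {}
    for sample_id in matrix.columns:
        for gene in trimmed_set(matrix, sample_id, lower_cut, upper_cut):
            counts[gene] = counts.get(gene, 0) + 1
    return {gene for gene, c in counts.items() if c >= needed}


def specific_genes(matrix: pd.DataFrame) -> set[str]:
    """Genes specific to one sample under Jongeneel's specificity measure.

    A gene qualifies when its maximal expression in one sample strictly
    exceeds the sum over all other samples combined, and it is observed
    (nonzero) in at least half the samples.
    """
    validate_matrix(matrix)
    values = matrix.to_numpy(dtype=float)
    n_samples = values.shape[1]
    top = values.max(axis=1)
    rest = values.sum(axis=1) - top
    present = (values > 0).sum(axis=1)
    mask = (top > rest) & (present >= math.ceil(n_samples / 2))
    return set(matrix.index[mask])


def top_expressed_subset(matrix: pd.DataFrame, gene_ids: set[str], n_max: int) -> set[str]:
    """The ``n_max`` genes of ``gene_ids`` with the highest geometric-mean
    expression across samples.

    Genes with any zero value are excluded before ranking (their geometric
    mean is undefined).  Ties are broken by gene-id order.  Identity when
    the set already fits within ``n_max``.
    """
    if n_max < 1:
        raise DomainError(f"n_max must be >= 1, got {n_max}")
    ids = sorted(set(gene_ids) & set(matrix.index))
    sub = matrix.loc[ids]
    sub = sub[(sub > 0).all(axis=1)]
    if len(sub) <= n_max:
        return set(sub.index)
    gm = np.exp(np.log(sub.to_numpy(dtype=float)).mean(axis=1))
    # descending geometric mean; gene-id order already ascending, and the
    # stable sort preserves it among ties
    order = np.argsort(-gm, kind="stable")
    return set(sub.index[order[:n_max]])
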