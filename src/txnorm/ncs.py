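"""Network Centrality Scaling (NCS).

The method looks for genes whose expression is mutually proportional
across samples, reasoning that such a "core" of consistently expressed
genes is the most trustworthy internal normalization guide.  It runs in
five stages:

1. select ubiquitous genes (wide 5% trimming), optionally capped at the
   most highly expressed ``pool_cap`` (default 2000) genes;
2. for every gene pair compute the per-sample expression ratios
   ``R_ijk = Y_ik / Y_jk`` and the *ratio dispersal*
   ``D_ij = log2(max_k R_ijk) - log2(min_k R_ijk)`` — zero for perfectly
   proportional pairs; pairs with ``D_ij > d_cutoff`` (default 1, i.e. the
   extreme ratios differ more than two-fold) are discarded;
3. build a weighted undirected network with edge weights
   ``sim_ij = 1/(1 + D_ij)`` (in (0.5, 1] under the default cutoff) and
   run PageRank; gene weights are ``W_g = PageRank_g * G - 1`` with
   ``G`` the node count, negative weights set to zero and dropped;
4. compute per-sample factors equalizing the ``W``-weighted geometric
   mean of the positively weighted genes, product-1 adjusted;
5. scale the full matrix by the factors.

Because dispersal is built entirely from within-sample ratios, the
network — and hence the guide-gene weights — is invariant under any
per-sample rescaling of the input.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from ._exceptions import ConvergenceError, DegenerateInputError, DomainError
from .genes import WIDE_CUTS, top_expressed_subset, ubiquitous_genes
from .io import validate_matrix
from .scalers import BaseFactorScaler, guide_factors

__all__ = [
    "pair_dispersal",
    "similarity",
    "build_similarity_network",
    "centrality_weights",
    "ncs_factors",
    "NetworkCentralityScaler",
]


def pair_dispersal(values_i, values_j) -> float:
    """Ratio dispersal ``D = log2(max ratio) - log2(min ratio)`` of two
    strictly positive per-sample expression vectors.

    Symmetric in its arguments; zero iff the genes are exactly
    proportional across samples.
    """
    vi = np.asarray(values_i, dtype=float)
    vj = np.asarray(values_j, dtype=float)
    if vi.shape != vj.shape or vi.ndim != 1 or len(vi) < 2:
        raise DomainError("dispersal needs two equal-length vectors over >= 2 samples")
    if (vi <= 0).any() or (vj <= 0).any():
        raise DomainError("dispersal is defined only for strictly positive values")
    log_ratio = np.log2(vi) - np.log2(vj)
    return float(log_ratio.max() - log_ratio.min())


def similarity(dispersal: float) -> float:
    """Pairwise similarity ``sim = 1/(1 + D)``: 1 for proportional pairs,
    0.5 at the default dispersal cutoff of 1."""
    if dispersal < 0:
        raise DomainError("dispersal must be non-negative")
    return 1.0 / (1.0 + dispersal)


def build_similarity_network(
    matrix: pd.DataFrame,
    pool,
    d_cutoff: float = 1.0,
    chunk: int = 256,
) -> nx.Graph:
    """Build the gene similarity network over a pool of ubiquitous genes.

    Nodes are all pool genes (isolated genes stay as nodes); edges connect
    pairs with dispersal ``D_ij <= d_cutoff`` and carry weight
    ``sim_ij = 1/(1 + D_ij)``.  Dispersal is computed in vectorized row
    blocks of size ``chunk`` over the log2 matrix.
    """
    if d_cutoff <= 0:
        raise DomainError(f"d_cutoff must be positive, got {d_cutoff}")
    pool = sorted(set(pool) & set(matrix.index))
    if len(pool) < 2:
        raise DomainError("similarity network needs a pool of at least 2 genes")
    sub = matrix.loc[pool]
    if sub.le(0).any(axis=None):
        bad = list(sub.index[sub.le(0).any(axis=1)])
        raise DomainError(f"pool genes with zero values: {bad[:5]}")
    log2 = np.log2(sub.to_numpy(dtype=float))
    graph = nx.Graph()
    graph.add_nodes_from(pool)
    n = len(pool)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        # log-ratio matrices for rows [start:stop) against all rows
        diff = log2[start:stop, None, :] - log2[None, :, :]
        disp = diff.max(axis=2) - diff.min(axis=2)
        for a in range(start, stop):
            row = disp[a - start]
            js = np.flatnonzero(row[a + 1:] <= d_cutoff) + a + 1
            graph.add_weighted_edges_from(
                (pool[a], pool[j], 1.0 / (1.0 + row[j])) for j in js
            )
    graph.graph["d_cutoff"] = d_cutoff
    return graph


def centrality_weights(
    network: nx.Graph,
    damping: float = 0.85,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> pd.Series:
    """PageRank-derived gene weights ``W_g = PageRank_g * G - 1``.

    PageRank is run on the weighted undirected network (each edge acting
    as two directed edges with weight-proportional transition
    probabilities) until the L1 change falls below ``tol``.  Genes with
    non-positive weight are dropped; the returned Series holds only
    ``W_g > 0``.
    """
    n_nodes = network.number_of_nodes()
    if n_nodes == 0:
        raise DomainError("cannot compute centrality of an empty network")
    try:
        # networkx declares convergence at L1 error < N * tol
        pr = nx.pagerank(
            network, alpha=damping, tol=tol / n_nodes, max_iter=max_iter, weight="weight"
        )
    except nx.PowerIterationFailedConvergence as exc:
        raise ConvergenceError(
            f"PageRank failed to reach L1 tolerance {tol} in {max_iter} iterations"
        ) from exc
    weights = pd.Series(pr, dtype=float) * n_nodes - 1.0
    weights = weights[weights > 0]
    return weights.sort_index()


def ncs_factors(matrix: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """Product-1 factors equalizing the centrality-weighted geometric mean
    of the guide genes across samples (the arbitrary common target level
    cancels in the product-1 adjustment)."""
    if weights is None or len(weights) == 0 or (pd.Series(weights) <= 0).all():
        raise DomainError("NCS needs at least one gene with positive centrality weight")
    return guide_factors(matrix, pd.Series(weights, dtype=float))


class NetworkCentralityScaler(BaseFactorScaler):
    """End-to-end Network Centrality Scaling estimator.

    Parameters mirror the five stages: trim cutoffs and pool cap for the
    ubiquitous pool, ``d_cutoff`` for pair admission, PageRank damping and
    tolerance for the centrality stage.  If the strict ubiquitous
    intersection is empty the pool is rebuilt once with 80% membership (a
    warning is issued); an empty pool after that raises.

    Fitted attributes: ``pool_`` (guide candidate pool), ``network_``
    (similarity graph), ``weights_`` (positive centrality weights),
    ``factors_``.
    """

    method_name = "ncs"

    def __init__(
        self,
        lower_cut: float = WIDE_CUTS[0],
        upper_cut: float = WIDE_CUTS[1],
        pool_cap: int = 2000,
        d_cutoff: float = 1.0,
        damping: float = 0.85,
        tol: float = 1e-9,
        max_iter: int = 1000,
    ):
        self.lower_cut = lower_cut
        self.upper_cut = upper_cut
        self.pool_cap = pool_cap
        self.d_cutoff = d_cutoff
        self.damping = damping
        self.tol = tol
        self.max_iter = max_iter

    def _compute_factors(self, X: pd.DataFrame) -> pd.Series:
        validate_matrix(X)
        pool = ubiquitous_genes(X, self.lower_cut, self.upper_cut, min_membership=1.0)
        if not pool:
            warnings.warn(
                "strict ubiquitous set is empty; relaxing membership to 80% of samples",
                stacklevel=2,
            )
            pool = ubiquitous_genes(X, self.lower_cut, self.upper_cut, min_membership=0.8)
        if not pool:
            raise DomainError(
                "ubiquitous pool empty even at 80% membership; widen the trim cutoffs"
            )
        # relaxed-membership genes may contain zeros; dispersal needs
        # strictly positive vectors
        pool = {g for g in pool if (X.loc[g] > 0).all()}
        if len(pool) < 2:
            raise DomainError("fewer than 2 strictly positive ubiquitous genes")
        pool = top_expressed_subset(X, pool, self.pool_cap)
        self.pool_ = pool
        self.network_ = build_similarity_network(X, pool, d_cutoff=self.d_cutoff)
        self.weights_ = centrality_weights(
            self.network_, damping=self.damping, tol=self.tol, max_iter=self.max_iter
        )
        if self.weights_.empty:
            # a perfectly symmetric network (e.g. all pool genes exactly
            # proportional) gives every node PageRank 1/G, so W_g = 0 for
            # all genes: every gene is equally central, and equal weights
            # are the centrality answer
            warnings.warn(
                "all centrality weights are zero (fully symmetric network); "
                "falling back to equal weights over the pool",
                stacklevel=2,
            )
            self.weights_ = pd.Series(1.0, index=sorted(self.network_.nodes))
        self.metadata_ = {
            "guide_genes": list(self.weights_.index),
            "weights": self.weights_.to_dict(),
            "pool_size": len(pool),
            "n_edges": self.network_.number_of_edges(),
        }
        return ncs_factors(X, self.weights_)
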