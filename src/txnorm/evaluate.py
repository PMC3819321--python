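"""Evaluation of normalization success.

Two mutually independent, fully data-driven metrics:

* **uniform genes** — the number of genes whose post-normalization
  coefficient of variation (CoV, sample standard deviation over mean)
  across samples falls below a strict cutoff (default 0.25).  More
  successful normalizations render more genes uniform.
* **rank decorrelation** — each gene, on its own, ranks the samples by
  its expression; for a large random sample of gene pairs the Spearman
  correlation between the two rankings is computed.  Systematic
  mis-scaling makes most gene pairs agree on sample ordering (mean
  correlation pushed away from zero), while an optimal scaling leaves a
  symmetric correlation distribution centered on zero.

Also included: pairwise comparison of the factor vectors produced by
different methods (Pearson on log2 factors) and a grid scan of trim
cutoffs scored by the resulting uniform-gene count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._exceptions import DomainError
from .genes import WIDE_CUTS, ubiquitous_genes
from .io import validate_matrix

__all__ = [
    "gene_cov",
    "count_uniform",
    "DecorrelationSummary",
    "ranking_decorrelation",
    "compare_factor_sets",
    "cutoff_grid_scan",
    "EvaluationReport",
    "evaluate_matrix",
]


def gene_cov(values) -> float:
    """Coefficient of variation of one gene's per-sample values:
    sample standard deviation (n-1 denominator) divided by the mean.
    Undefined (error) when the mean is not positive."""
    v = np.asarray(values, dtype=float)
    mean = v.mean()
    if mean <= 0:
        raise DomainError("CoV undefined: mean expression is not positive")
    return float(v.std(ddof=1) / mean)


def count_uniform(matrix: pd.DataFrame, cov_cutoff: float = 0.25):
    """Count genes with positive mean and CoV below ``cov_cutoff``.

    Returns ``(count, gene_set)``.  Invariant under global rescaling of
    the matrix (CoV is scale-free per gene).
    """
    if cov_cutoff <= 0:
        raise DomainError(f"cov_cutoff must be positive, got {cov_cutoff}")
    validate_matrix(matrix)
    values = matrix.to_numpy(dtype=float)
    mask = _uniform_mask(values, cov_cutoff)
    return int(mask.sum()), set(matrix.index[mask])


def _uniform_mask(values: np.ndarray, cov_cutoff: float) -> np.ndarray:
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.inf)
    return (mean > 0) & (cov < cov_cutoff)


@dataclass
class DecorrelationSummary:
    """Distribution of sample-ranking Spearman correlations over sampled
    gene pairs."""

    mean: float
    median: float
    correlations: np.ndarray = field(repr=False)
    n_pairs: int = 0
    n_genes: int = 0
    n_excluded_constant: int = 0
    seed: int | None = None


def ranking_decorrelation(
    matrix: pd.DataFrame,
    pool=None,
    n_pairs: int = 100_000,
    seed: int = 0,
) -> DecorrelationSummary:
    """Spearman correlation of per-gene sample rankings over random gene
    pairs.

    ``pool`` defaults to the wide-trim (5%) ubiquitous genes.  Genes with
    fewer than two distinct values induce no ranking and are excluded up
    front (counted in ``n_excluded_constant``).  Unordered pairs are drawn
    without replacement under ``seed``; if ``n_pairs`` covers all pairs the
    full enumeration is used and the result is seed-independent.  Ties in
    a gene's values receive average ranks.
    """
    validate_matrix(matrix)
    if pool is None:
        pool = ubiquitous_genes(matrix, *WIDE_CUTS)
    pool = sorted(set(pool) & set(matrix.index))
    if len(pool) < 2:
        raise DomainError("decorrelation needs a pool of at least 2 genes")
    values = matrix.loc[pool].to_numpy(dtype=float)
    distinct = (values != values[:, :1]).any(axis=1)
    n_excluded = int((~distinct).sum())
    usable = [g for g, d in zip(pool, distinct) if d]
    values = values[distinct]
    if len(usable) < 2:
        raise DomainError("fewer than 2 genes with non-constant profiles")
    # Spearman with average ranks == Pearson on the rank vectors
    ranks = rankdata(values, axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    unit = centered / norms[:, None]

    p = len(usable)
    total_pairs = p * (p - 1) // 2
    if n_pairs >= total_pairs:
        ii, jj = np.triu_indices(p, k=1)
        n_used = total_pairs
    else:
        rng = np.random.default_rng(seed)
        seen: set[tuple[int, int]] = set()
        while len(seen) < n_pairs:
            draw = rng.integers(0, p, size=(2 * (n_pairs - len(seen)) + 16, 2))
            for a, b in draw:
                if a == b:
                    continue
                pair = (a, b) if a < b else (b, a)
                seen.add(pair)
                if len(seen) == n_pairs:
                    break
        pairs = np.array(sorted(seen))
        ii, jj = pairs[:, 0], pairs[:, 1]
        n_used = n_pairs
    corr = np.einsum("ij,ij->i", unit[ii], unit[jj])
    return DecorrelationSummary(
        mean=float(corr.mean()),
        median=float(np.median(corr)),
        correlations=corr,
        n_pairs=int(n_used),
        n_genes=p,
        n_excluded_constant=n_excluded,
        seed=seed,
    )


def compare_factor_sets(factor_sets) -> pd.DataFrame:
    """Pearson correlation matrix of log2 factor vectors across methods.

    ``factor_sets`` is a mapping method name -> factor Series (or a list of
    named Series) over identical samples.  The result is symmetric with a
    unit diagonal; multiplying any factor set by a constant leaves its row
    unchanged (correlation in log space is shift-invariant).
    """
    if isinstance(factor_sets, dict):
        named = list(factor_sets.items())
    else:
        named = [(getattr(f, "name", None) or f"set{i}", f) for i, f in enumerate(factor_sets)]
    if len(named) < 2:
        raise DomainError("need at least two factor sets to compare")
    samples = list(named[0][1].index)
    for name, f in named:
        if sorted(f.index) != sorted(samples):
            raise DomainError(f"factor set {name!r} covers different samples")
        if (pd.Series(f) <= 0).any():
            raise DomainError(f"factor set {name!r} has non-positive factors")
    logf = np.vstack([np.log2(pd.Series(f).reindex(samples).to_numpy(dtype=float)) for _, f in named])
    corr = np.corrcoef(logf)
    names = [name for name, _ in named]
    return pd.DataFrame(corr, index=names, columns=names)


def cutoff_grid_scan(
    matrix: pd.DataFrame,
    resolution: float = 0.05,
    cov_cutoff: float = 0.25,
):
    """Scan trim-cutoff combinations, scoring each by the uniform-gene
    count after Total-Ubiquitous scaling with that pool.

    Lower cutoffs run over multiples of ``resolution`` from 0; upper
    cutoffs over multiples up to ``1 - resolution`` (the top of each
    sample's distribution is always trimmed); only ``lower < upper`` is
    evaluated.  An empty ubiquitous pool scores 0.  Returns
    ``(grid, best)`` where ``grid`` is a DataFrame indexed by lower cutoff
    with upper cutoffs as columns (NaN for invalid combinations) and
    ``best`` is the argmax ``(lower, upper)`` (ties: smallest lower, then
    smallest upper).
    """
    from .scalers import TotalUbiquitousScaler  # local import to avoid cycle

    if not (0.0 < resolution < 0.5):
        raise DomainError(f"resolution must be in (0, 0.5), got {resolution}")
    validate_matrix(matrix)
    steps = int(round(1.0 / resolution))
    lowers = [round(i * resolution, 10) for i in range(steps)]
    uppers = [round(i * resolution, 10) for i in range(1, steps)]
    grid = pd.DataFrame(np.nan, index=lowers, columns=uppers)
    best, best_count = None, -1
    for lower, upper in itertools.product(lowers, uppers):
        if lower >= upper:
            continue
        pool = ubiquitous_genes(matrix, lower, upper, min_membership=1.0)
        if not pool:
            count = 0
        else:
            scaler = TotalUbiquitousScaler(pool=pool)
            scaled = scaler.fit(matrix).transform(matrix)
            count, _ = count_uniform(scaled, cov_cutoff)
        grid.loc[lower, upper] = count
        if count > best_count:
            best, best_count = (lower, upper), count
    return grid, best


@dataclass
class EvaluationReport:
    """Summary of both success metrics for one normalized matrix."""

    method_name: str
    uniform_count: int
    specific_count: int
    cov_cutoff: float
    mean_pair_correlation: float
    median_pair_correlation: float
    n_pairs_sampled: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method_name,
            "uniform_count": self.uniform_count,
            "specific_count": self.specific_count,
            "cov_cutoff": self.cov_cutoff,
            "mean_pair_correlation": self.mean_pair_correlation,
            "median_pair_correlation": self.median_pair_correlation,
            "n_pairs_sampled": self.n_pairs_sampled,
            "seed": self.seed,
        }


def evaluate_matrix(
    matrix: pd.DataFrame,
    method_name: str = "unknown",
    cov_cutoff: float = 0.25,
    pool=None,
    n_pairs: int = 100_000,
    seed: int = 0,
) -> EvaluationReport:
    """Run both success metrics plus the specific-gene count on a
    normalized matrix and package them as an :class:`EvaluationReport`."""
    from .genes import specific_genes

    uniform, _ = count_uniform(matrix, cov_cutoff)
    specific = specific_genes(matrix)
    deco = ranking_decorrelation(matrix, pool=pool, n_pairs=n_pairs, seed=seed)
    return EvaluationReport(
        method_name=method_name,
        uniform_count=uniform,
        specific_count=len(specific),
        cov_cutoff=cov_cutoff,
        mean_pair_correlation=deco.mean,
        median_pair_correlation=deco.median,
        n_pairs_sampled=deco.n_pairs,
        seed=seed,
    )
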