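"""Single-factor scaling methods.

Every method here reduces to choosing one positive multiplier ``f_k`` per
sample and scaling all of the sample's values by it, which preserves
within-sample expression ratios exactly.  The methods differ only in how
the factors are derived:

===================  =====================================================
``CPMScaler``        each sample to a fixed total of one million
``TotalCountScaler`` each sample to the average total per sample
``PercentileScaler`` the value at a quantile (e.g. upper quartile/decile)
                     to the average of that value across samples
``GuideGeneScaler``  equalize the (weighted) geometric mean of a guide
                     gene set across samples; the single-housekeeping-gene
                     method is the one-gene case
``GeNormScaler``     guide genes picked from housekeeping candidates by
                     iterative gene-stability (geNorm) selection
``StabilityScaler``  guide genes = the n most stable ubiquitous genes
``RandomUbiquitousScaler``  n randomly drawn ubiquitous guide genes
``AllUbiquitousScaler``     every ubiquitous gene as guide
``TotalUbiquitousScaler``   equalize the summed expression of ubiquitous
                            genes across samples
``RandomScaler``     mock normalization: factors 2**r, r ~ U[-0.5, 0.5)
``TMMScaler``        trimmed mean of M-values against a reference sample
===================  =====================================================

Guide-based factors (and TMM) are *relative*: they are canonicalized so
their product equals 1 (:func:`adjust_factors`), which preserves the
global scale of the data set while fixing the ratios between samples.

All estimators follow the scikit-learn protocol: ``fit(X)`` computes
``factors_`` (a :class:`pandas.Series` indexed by sample), ``transform(X)``
multiplies each column by its factor.  ``X`` is a genes x samples
DataFrame throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gmean
from sklearn.base import BaseEstimator, TransformerMixin

from ._exceptions import DegenerateInputError, DomainError
from .genes import DEFAULT_CUTS, WIDE_CUTS, ubiquitous_genes
from .io import validate_matrix

__all__ = [
    "HOUSEKEEPING_GENES",
    "NormalizationResult",
    "adjust_factors",
    "guide_factors",
    "genorm_select",
    "stability_select",
    "BaseFactorScaler",
    "CPMScaler",
    "TotalCountScaler",
    "PercentileScaler",
    "GuideGeneScaler",
    "GeNormScaler",
    "StabilityScaler",
    "RandomUbiquitousScaler",
    "AllUbiquitousScaler",
    "TotalUbiquitousScaler",
    "RandomScaler",
    "TMMScaler",
]

#: The nine housekeeping genes of the geNorm study that are expressed in
#: all samples of typical human tissue panels (YWHAZ, the tenth geNorm
#: gene, is commonly absent and is not part of the preset).
HOUSEKEEPING_GENES = ("ACTB", "B2M", "GAPDH", "HMBS", "HPRT1", "RPL13A", "SDHA", "TBP", "UBC")


@dataclass
class NormalizationResult:
    """Outcome of one normalization: the scaled matrix, the factors that
    produced it (None for the non-factor quantile method), and metadata
    describing parameters, guide genes and seeds."""

    method_name: str
    matrix: pd.DataFrame
    factors: pd.Series | None = None
    metadata: dict = field(default_factory=dict)


def adjust_factors(factors: pd.Series) -> pd.Series:
    """Canonicalize a positive factor vector so its product equals 1.

    Divides by the geometric mean, preserving every between-sample ratio
    exactly.  Idempotent and invariant under global rescaling of the input.
    """
    f = pd.Series(factors, dtype=float)
    if (f <= 0).any() or not np.isfinite(f).all():
        raise DomainError("all scaling factors must be positive and finite")
    return f / gmean(f)


def _check_positive_guides(matrix: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """Validate guide weights against a matrix; return the positive-weight
    guide rows (genes x samples)."""
    w = pd.Series(weights, dtype=float)
    if (w < 0).any() or not np.isfinite(w).all():
        raise DomainError("guide weights must be finite and non-negative")
    w = w[w > 0]
    if w.empty:
        raise DomainError("at least one guide gene must have positive weight")
    missing = [g for g in w.index if g not in matrix.index]
    if missing:
        raise DomainError(f"guide genes absent from matrix: {missing[:5]}")
    guides = matrix.loc[w.index]
    zero = guides.le(0).any(axis=1)
    if zero.any():
        bad = list(guides.index[zero])
        raise DomainError(
            f"guide gene(s) with zero expression in some sample: {bad[:5]}; "
            "exclude them before scaling"
        )
    return w


def guide_factors(matrix: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """Product-1 factors equalizing the weighted geometric mean of guide
    genes across samples.

    With guide log-expression ``ln Y_gk`` and weights ``W_g``, the per-sample
    guide level is ``g_k = exp(sum_g W_g ln Y_gk / sum_g W_g)``; factors are
    proportional to ``1/g_k`` and canonicalized to product 1, after which
    ``g_k * f_k`` is identical across samples.
    """
    w = _check_positive_guides(matrix, weights)
    log_guides = np.log(matrix.loc[w.index].to_numpy(dtype=float))
    g_k = np.exp(w.to_numpy() @ log_guides / w.sum())
    return adjust_factors(pd.Series(1.0 / g_k, index=matrix.columns))


class BaseFactorScaler(BaseEstimator, TransformerMixin):
    """Base class for all single-factor scaling estimators.

    Subclasses implement ``_compute_factors(X) -> pd.Series``; ``fit``
    validates the matrix and stores ``factors_``, ``transform`` applies
    them column-wise.
    """

    method_name: str = "base"

    def _compute_factors(self, X: pd.DataFrame) -> pd.Series:  # pragma: no cover
        raise NotImplementedError

    def fit(self, X: pd.DataFrame, y=None):
        X = validate_matrix(X)
        self.factors_ = self._compute_factors(X).astype(float)
        self.sample_ids_ = list(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "factors_"):
            raise DomainError("scaler is not fitted; call fit or fit_transform first")
        X = validate_matrix(X)
        if list(X.columns) != self.sample_ids_:
            raise DomainError("matrix samples do not match the fitted samples")
        return X.mul(self.factors_, axis=1)

    def result(self, X: pd.DataFrame) -> NormalizationResult:
        """Fit on ``X`` and package matrix, factors and parameters."""
        self.fit(X)
        meta = {"params": self.get_params()}
        meta.update(getattr(self, "metadata_", {}))
        return NormalizationResult(
            method_name=self.method_name,
            matrix=self.transform(X),
            factors=self.factors_.copy(),
            metadata=meta,
        )


class CPMScaler(BaseFactorScaler):
    """Scale each sample to a fixed total (counts per million).

    Factors are ``target / column_total``; samples are scaled independently
    of each other — the only method here with that property.
    """

    method_name = "cpm"

    def __init__(self, target: float = 1e6):
        self.target = target

    def _compute_factors(self, X: pd.DataFrame) -> pd.Series:
        totals = X.sum(axis=0)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0][0]
            raise DegenerateInputError(f"sample {bad!r} has zero total expression")
        return self.target / totals


class TotalCountScaler(BaseFactorScaler):
    """Scale each sample to the average total per sample; the grand total
    of the matrix is preserved."""

    method_name = "total"

    def _compute_factors(self, X: pd.DataFrame) -> pd.Series:
        totals = X.sum(axis=0)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0][0]
            raise DegenerateInputError(f"sample {bad!r} has zero total expression")
        return totals.mean() / totals


def _nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Nearest-rank quantile: the value at 1-based rank ceil(q*n) of the
    ascending sorted vector."""
    v = np.sort(values)
    rank = max(1, int(np.ceil(q * len(v))))
    return float(v[rank - 1])


class PercentileScaler(BaseFactorScaler):
    """Scale the expression value at quantile ``q`` of each sample to the
    average of that value across samples.

    ``q=0.75`` is the Upper Quartile method, ``q=0.90`` the Upper Decile.
    With ``nonzero_only`` the quantile is taken over nonzero genes only,
    which is far more robust on sparse count matrices.
    """

    method_name = "percentile"

    def __init__(self, q: float = 0.75, nonzero_only: bool = False):
        self.q = q
        self.nonzero_only = nonzero_only

    def _compute_factors(self, X: pd.DataFrame) -> pd.Series:
        if not (0.0 < self.q < 1.0):
            raise DomainError(f"q must be in (0, 1), got {self.q}")
        v = {}
        for k, col in X.items():
            vals = col.to_numpy(dtype=float)
            if self.nonzero_only:
                vals = vals[vals > 0]
                if vals.size == 0:
                    raise DegenerateInputError(f"sample {k!r} has no nonzero genes")
            v[k] = _nearest_rank_quantile(vals, self.q)
        v = pd.Series(v)
        if (v <= 0).any():
            bad = v.index[v <= 0][0]
            raise DegenerateInputError(
                f"quantile q={self.q} of sample {bad!r} is zero; "
                "use nonzero_only=True or a higher q"
            )
        return v.mean() / v


class GuideGeneScaler(BaseFactorScaler):
    """Equalize the weighted geometric mean of a guide gene set.

    ``guide_weights`` maps gene id -> non-negative weight; an iterable of
    ids gets unit weights.  A single gene reproduces the classic
    housekeeping-gene normalization.  Factors are product-1 adjusted and
    invariant under rescaling of the weight vector.
    """

    method_name = "guide-genes"

    def __init__(self, guide_weights=None):
        self.guide_weights = guide_weights

    def _weights(self) -> pd.Series:
        gw = self.guide_weights
        if gw is None:
            raise DomainError("guide_weights must be provided")
        if isinstance(gw, pd.Series):
            return gw.astype(float)
        if isinstance(gw, dict):
            return pd.Series(gw, dtype=float)
        return pd.Series(1.0, index=pd.Index(list(gw)))

    def _compute_factors(self, X: pd.DataFrame) -> pd.Series:
        w = self._weights()
        self.metadata_ = {"guide_genes": list(w.index[w > 0]), "weights": w[w > 0].to_dict()}
        return guide_factors(X, w)


def genorm_select(matrix: pd.DataFrame, candidates, k: int):
    """geNorm control-gene selection by iterative stability exclusion.

    For each candidate ``j`` the stability measure ``M_j`` is the mean over
    the other candidates ``h`` of the standard deviation (across samples,
    n-1 denominator) of ``log2(Y_j / Y_h)``; exactly proportional genes
    contribute zero.  The candidate with the largest ``M`` is removed and
    the measure recomputed, until ``k`` genes remain.

    Returns ``(selected, ranking)`` where ``ranking`` is a DataFrame with
    the removal order (survivors last) and each gene's ``M`` at the stage
    it was evaluated last.
    """
    cand = list(pd.Series(1.0, index=pd.Index(candidates)).index) if not isinstance(candidates, pd.Series) else list(candidates.index)
    cand = sorted(dict.fromkeys(cand))
    if len(cand) < 3 or not (3 <= k <= len(cand)):
        raise DomainError(f"need 3 <= k <= number of candidates ({len(cand)}), got k={k}")
    missing = [g for g in cand if g not in matrix.index]
    if missing:
        raise DomainError(f"candidate genes absent from matrix: {missing[:5]}")
    sub = matrix.loc[cand]
    if sub.le(0).any(axis=None):
        bad = list(sub.index[sub.le(0).any(axis=1)])
        raise DomainError(f"candidates with zero values: {bad[:5]}")
    log2 = np.log2(sub.to_numpy(dtype=float))
    remaining = list(range(len(cand)))
    removal: list[tuple[str, float]] = []

    def m_values(idx: list[int]) -> np.ndarray:
        L = log2[idx]
        m = np.empty(len(idx))
        for a in range(len(idx)):
            diffs = L[a][None, :] - np.delete(L, a, axis=0)
            m[a] = diffs.std(axis=1, ddof=1).mean()
        return m

    while len(remaining) > k:
        m = m_values(remaining)
        worst = int(np.argmax(m))  # ties: first (gene-id order) removed
        removal.append((cand[remaining[worst]], float(m[worst])))
        del remaining[worst]
    final_m = m_values(remaining)
    for a, i in enumerate(remaining):
        removal.append((cand[i], float(final_m[a])))
    ranking = pd.DataFrame(removal, columns=["gene", "M"]).set_index("gene")
    selected = {cand[i] for i in remaining}
    return selected, ranking


class GeNormScaler(BaseFactorScaler):
    """geNorm: guide genes chosen among housekeeping candidates by the
    gene-stability measure, then combined by geometric mean.

    ``candidates`` defaults to the nine-gene housekeeping preset restricted
    to genes present and nonzero in the matrix; ``k`` control genes are
    retained (between 3 and 9 in typical use).
    """

    method_name = "genorm"

    def __init__(self, k: int = 3, candidates=None):
        self.k = k
        self.candidates = candidates

    def _compute_factors(self, X: pd.DataFrame) -> pd.Series:
        cand = self.candidates
        if cand is None:
            cand = [g for g in HOUSEKEEPING_GENES if g in X.index and (X.loc[g] > 0).all()]
        selected, ranking = genorm_select(X, cand, self.k)
        self.ranking_ = ranking
        self.selected_ = selected
        self.metadata_ = {"guide_genes": sorted(selected)}
        return guide_factors(X, pd.Series(1.0, index=sorted(selected)))


def stability_select(matrix: pd.DataFrame, pool, n: int = 100, seed: int = 0) -> pd.Series:
    """Pick the ``n`` most stable genes of a (ubiquitous) pool.

    A single-pass variant of the geNorm stability measure that scales to
    pools of thousands of genes: each gene's ``M`` is the mean standard
    deviation of its pairwise log2 ratios against a fixed, seeded random
    subsample of the pool (size ``min(100, pool)``), instead of full
    iterative re-ranking, which would be quadratic in the pool size.
    Returns unit weights for the selected genes (lowest ``M`` first wins;
    ties broken by gene-id order).
    """
    pool = sorted(set(pool) & set(matrix.index))
    if len(pool) < 2:
        raise DomainError("stability selection needs a pool of at least 2 genes")
    if n < 2:
        raise DomainError(f"n must be >= 2, got {n}")
    if len(pool) <= n:
        warnings.warn(
            f"pool ({len(pool)} genes) not larger than n={n}; returning the whole pool",
            stacklevel=2,
        )
        return pd.Series(1.0, index=pd.Index(pool))
    sub = matrix.loc[pool]
    if sub.le(0).any(axis=None):
        raise DomainError("stability pool contains zero values; use a strict ubiquitous pool")
    log2 = np.log2(sub.to_numpy(dtype=float))
    rng = np.random.default_rng(seed)
    ref_idx = rng.choice(len(pool), size=min(100, len(pool)), replace=False)

    n_samples = log2.shape[1]
    centered = log2 - log2.mean(axis=1, keepdims=True)
    var = (centered**2).sum(axis=1) / (n_samples - 1)
    cov = centered @ centered[ref_idx].T / (n_samples - 1)
    # var(L_j - L_h) = var_j + var_h - 2 cov_jh
    pairvar = var[:, None] + var[ref_idx][None, :] - 2 * cov
    sd = np.sqrt(np.clip(pairvar, 0.0, None))
    # exclude the self-pair where gene j is in the reference subsample
    self_mask = np.arange(len(pool))[:, None] == ref_idx[None, :]
    counts = (~self_mask).sum(axis=1)
    m = np.where(self_mask, 0.0, sd).sum(axis=1) / counts
    order = np.argsort(m, kind="stable")  # pool is id-sorted, so ties go by gene id
    chosen = [pool[i] for i in order[:n]]
    return pd.Series(1.0, index=pd.Index(sorted(chosen)))


class _PoolScalerMixin:
    """Shared ubiquitous-pool construction for pool-based scalers."""

    def _pool(self, X: pd.DataFrame) -> set[str]:
        pool = self.pool
        if pool is None:
            pool = ubiquitous_genes(X, self.lower_cut, self.upper_cut, self.min_membership)
        if not pool:
            raise DegenerateInputError(
                "ubiquitous gene pool is empty; consider wider cutoffs or "
                "min_membership=0.8"
            )
        return set(pool)


class StabilityScaler(BaseFactorScaler, _PoolScalerMixin):
    """Equalize the geometric mean of the ``n`` most stable ubiquitous
    genes (wide 5% trimming by default)."""

    method_name = "stability"

    def __init__(
        self,
        n: int = 100,
        seed: int = 0,
        lower_cut: float = WIDE_CUTS[0],
        upper_cut: float = WIDE_CUTS[1],
        min_membership: float = 1.0,
        pool=None,
    ):
        self.n = n
        self.seed = seed
        self.lower_cut = lower_cut
        self.upper_cut = upper_cut
        self.min_membership = min_membership
        self.pool = pool

    def _compute_factors(self, X: pd.DataFrame) -> pd.Series:
        weights = stability_select(X, self._pool(X), n=self.n, seed=self.seed)
        self.selected_ = set(weights.index)
        self.metadata_ = {"guide_genes": sorted(weights.index), "seed": self.seed}
        return guide_factors(X, weights)


class RandomUbiquitousScaler(BaseFactorScaler, _PoolScalerMixin):
    """Negative control: geometric-mean scaling on ``n`` randomly drawn
    ubiquitous genes (default trim 30/85)."""

    method_name = "random-ubiquitous"

    def __init__(
        self,
        n: int = 100,
        seed: int = 0,
        lower_cut: float = DEFAULT_CUTS[0],
        upper_cut: float = DEFAULT_CUTS[1],
        min_membership: float = 1.0,
        pool=None,
    ):
        self.n = n
        self.seed = seed
        self.lower_cut = lower_cut
        self.upper_cut = upper_cut
        self.min_membership = min_membership
        self.pool = pool

    def _compute_factors(self, X: pd.DataFrame) -> pd.Series:
        pool = sorted(self._pool(X))
        if self.n > len(pool):
            raise DomainError(f"cannot draw n={self.n} genes from a pool of {len(pool)}")
        rng = np.random.default_rng(self.seed)
        chosen = sorted(rng.choice(pool, size=self.n, replace=False))
        self.selected_ = set(chosen)
        self.metadata_ = {"guide_genes": chosen, "seed": self.seed}
        return guide_factors(X, pd.Series(1.0, index=pd.Index(chosen)))


class AllUbiquitousScaler(BaseFactorScaler, _PoolScalerMixin):
    """Geometric-mean scaling on the entire ubiquitous gene pool."""

    method_name = "all-ubiquitous"

    def __init__(
        self,
        lower_cut: float = DEFAULT_CUTS[0],
        upper_cut: float = DEFAULT_CUTS[1],
        min_membership: float = 1.0,
        pool=None,
    ):
        self.lower_cut = lower_cut
        self.upper_cut = upper_cut
        self.min_membership = min_membership
        self.pool = pool

    def _compute_factors(self, X: pd.DataFrame) -> pd.Series:
        pool = sorted(self._pool(X))
        self.metadata_ = {"guide_genes": pool}
        return guide_factors(X, pd.Series(1.0, index=pd.Index(pool)))


class TotalUbiquitousScaler(BaseFactorScaler, _PoolScalerMixin):
    """Equalize the summed expression of ubiquitous genes across samples.

    With pool totals ``T_k``, factors are ``mean(T)/T_k``; after scaling all
    pool totals coincide.  Factors depend only on pool genes (locality).
    """

    method_name = "total-ubiquitous"

    def __init__(
        self,
        lower_cut: float = DEFAULT_CUTS[0],
        upper_cut: float = DEFAULT_CUTS[1],
        min_membership: float = 1.0,
        pool=None,
    ):
        self.lower_cut = lower_cut
        self.upper_cut = upper_cut
        self.min_membership = min_membership
        self.pool = pool

    def _compute_factors(self, X: pd.DataFrame) -> pd.Series:
        pool = sorted(self._pool(X))
        totals = X.loc[pool].sum(axis=0)
        if (totals <= 0).any():
            raise DomainError("a sample has zero total over the ubiquitous pool")
        self.pool_ = set(pool)
        self.metadata_ = {"pool_size": len(pool)}
        return totals.mean() / totals


class RandomScaler(BaseFactorScaler):
    """Mock normalization: each factor drawn as ``2**r`` with
    ``r ~ U[-0.5, 0.5)``, so factors lie in [0.707, 1.414).  A negative
    control, not a normalization."""

    method_name = "random"

    def __init__(self, seed: int = 0):
        self.seed = seed

    def _compute_factors(self, X: pd.DataFrame) -> pd.Series:
        rng = np.random.default_rng(self.seed)
        r = rng.uniform(-0.5, 0.5, size=X.shape[1])
        self.metadata_ = {"seed": self.seed}
        return pd.Series(np.exp2(r), index=X.columns)


def _trim_both_ends(stat: np.ndarray, frac: float) -> np.ndarray:
    """Boolean mask keeping values after removing floor(frac*n) smallest and
    largest entries of ``stat`` (ties resolved by index order)."""
    n = len(stat)
    cut = int(np.floor(frac * n))
    order = np.argsort(stat, kind="stable")
    keep = np.ones(n, dtype=bool)
    if cut > 0:
        keep[order[:cut]] = False
        keep[order[n - cut:]] = False
    return keep


class TMMScaler(BaseFactorScaler):
    """Trimmed mean of M-values against a reference sample.

    Each sample ``k`` is compared with the reference ``r`` through per-gene
    fractions ``F_gk = Y_gk / total_k`` over genes nonzero in both samples.
    Genes in the top/bottom ``trim_A`` (default 5%) of the average log
    fraction ``A_g = log F_gk + log F_gr`` are trimmed, then the top/bottom
    ``trim_M`` (default 30%) of the log ratio ``M_g = log F_gk - log F_gr``.
    The log scaling constant is the weighted mean of the surviving ``M_g``
    with delta-method inverse-variance weights
    ``w_g = (N_k - Y_gk)/(N_k Y_gk) + (N_r - Y_gr)/(N_r Y_gr)`` inverted.
    Final factors are ``1 / (total_k * TMM_k)``, product-1 adjusted;
    real-valued coverage is accepted as pseudo-counts.
    """

    method_name = "tmm"

    def __init__(self, reference_sample: str | None = None, trim_M: float = 0.30, trim_A: float = 0.05):
        self.reference_sample = reference_sample
        self.trim_M = trim_M
        self.trim_A = trim_A

    def _compute_factors(self, X: pd.DataFrame) -> pd.Series:
        ref = self.reference_sample if self.reference_sample is not None else X.columns[0]
        if ref not in X.columns:
            raise DomainError(f"reference sample {ref!r} not in matrix")
        totals = X.sum(axis=0)
        if (totals <= 0).any():
            raise DegenerateInputError("a sample has zero total expression")
        y_r = X[ref].to_numpy(dtype=float)
        n_r = float(totals[ref])
        log_tmm = {}
        for k in X.columns:
            if k == ref:
                log_tmm[k] = 0.0
                continue
            y_k = X[k].to_numpy(dtype=float)
            n_k = float(totals[k])
            both = (y_k > 0) & (y_r > 0)
            f_k, f_r = y_k[both] / n_k, y_r[both] / n_r
            a = np.log(f_k) + np.log(f_r)
            m = np.log(f_k) - np.log(f_r)
            keep = _trim_both_ends(a, self.trim_A)
            keep_idx = np.flatnonzero(keep)
            keep_m = _trim_both_ends(m[keep_idx], self.trim_M)
            idx = keep_idx[keep_m]
            if len(idx) < 3:
                raise DegenerateInputError(
                    f"fewer than 3 genes survive TMM trimming for sample {k!r}"
                )
            yk, yr = y_k[both][idx], y_r[both][idx]
            var = (n_k - yk) / (n_k * yk) + (n_r - yr) / (n_r * yr)
            w = 1.0 / var
            log_tmm[k] = float((w * m[idx]).sum() / w.sum())
        tmm = pd.Series(log_tmm).reindex(X.columns)
        self.tmm_ = np.exp(tmm)
        self.metadata_ = {"reference_sample": ref}
        return adjust_factors(1.0 / (totals * np.exp(tmm)))
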