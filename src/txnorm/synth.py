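"""Synthetic expression matrices with known ground truth.

The generator emulates the data model the scaling methods assume: a large
*core* of genes expressed in a mutually consistent pattern across all
samples, distorted by per-sample scaling factors (sequencing depth /
library composition), plus sample-*specific* genes (one dominant sample,
low elsewhere) and independent *noise* genes with dropout zeros.

Core gene ``g`` in sample ``k`` takes the value
``B_g * phi_k * 2**eps`` with a log-normal base level ``B_g``
(``log2 B ~ N(base_log2_mean, base_log2_sd)``), planted factor ``phi_k``
and multiplicative noise ``eps ~ N(0, noise_sigma)`` on the log2 scale.
At ``noise_sigma=0`` scaling the matrix by ``1/phi`` renders every core
gene exactly constant, so the planted core is recoverable by construction.

Specific genes receive a high value in their home sample exceeding the
sum of their values elsewhere (Jongeneel specificity) while remaining
nonzero in all samples; concentrating their home samples via
``specific_samples`` skews per-sample totals and is what breaks
total-count normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import DomainError
from .io import validate_matrix

__all__ = ["SynthConfig", "GroundTruth", "generate", "distort"]


@dataclass
class SynthConfig:
    """Study conditions for one synthetic matrix.

    ``true_factors`` (length ``n_samples``) default to ``2**r`` with
    ``r ~ U[-0.5, 0.5)`` — the same range as the mock normalization, so
    planted distortions and mock factors are commensurate.
    ``n_specific_genes`` is the total number of specific genes; they are
    assigned round-robin to ``specific_samples`` (default: all samples).
    ``noise_sigma`` is the log2-scale standard deviation of the
    multiplicative noise; ``dropout`` the zero fraction among noise genes.
    """

    n_samples: int = 16
    n_core_genes: int = 2000
    n_specific_genes: int = 200
    n_noise_genes: int = 500
    true_factors: np.ndarray | None = None
    base_log2_mean: float = 4.0
    base_log2_sd: float = 2.0
    noise_sigma: float = 0.05
    dropout: float = 0.3
    specific_samples: list[int] | None = None
    seed: int = 0

    def validate(self) -> "SynthConfig":
        if self.n_samples < 2:
            raise DomainError("need at least 2 samples")
        for name in ("n_core_genes", "n_specific_genes", "n_noise_genes"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.noise_sigma < 0 or not (0.0 <= self.dropout < 1.0):
            raise DomainError("noise_sigma must be >= 0 and dropout in [0, 1)")
        if self.true_factors is not None:
            f = np.asarray(self.true_factors, dtype=float)
            if f.shape != (self.n_samples,) or (f <= 0).any():
                raise DomainError("true_factors must be n_samples positive values")
        return self


@dataclass
class GroundTruth:
    """Planted structure of a generated matrix: the true factors, the
    disjoint gene classes, and the core base profile."""

    true_factors: pd.Series
    core_genes: list[str]
    specific_genes: dict[str, list[str]]
    noise_genes: list[str]
    base_profile: pd.Series = field(repr=False, default=None)


def generate(config: SynthConfig | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate an expression matrix plus its ground truth.

    Deterministic under ``config.seed``.  Gene classes are disjoint and
    labelled (``CORE...``, ``SPEC...``, ``NOISE...``); samples are
    ``S01..``.
    """
    config = (config or SynthConfig()).validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i + 1:02d}" for i in range(n)]
    if config.true_factors is None:
        phi = np.exp2(rng.uniform(-0.5, 0.5, size=n))
    else:
        phi = np.asarray(config.true_factors, dtype=float)

    blocks: list[np.ndarray] = []
    gene_ids: list[str] = []

    # core: shared base profile x factors x multiplicative noise
    base = np.exp2(rng.normal(config.base_log2_mean, config.base_log2_sd, size=config.n_core_genes))
    if config.n_core_genes:
        eps = rng.normal(0.0, config.noise_sigma, size=(config.n_core_genes, n)) if config.noise_sigma > 0 else 0.0
        core = base[:, None] * phi[None, :] * np.exp2(eps)
        blocks.append(core)
        gene_ids += [f"CORE{i + 1:05d}" for i in range(config.n_core_genes)]

    # specific: high in the home sample, low (but nonzero) elsewhere so the
    # home value strictly exceeds the sum of the rest
    specific: dict[str, list[str]] = {s: [] for s in samples}
    if config.n_specific_genes:
        homes = config.specific_samples if config.specific_samples is not None else list(range(n))
        spec = np.empty((config.n_specific_genes, n))
        for i in range(config.n_specific_genes):
            home = homes[i % len(homes)]
            high = np.exp2(rng.normal(config.base_log2_mean + 6.0, 1.0))
            low = high / (8.0 * (n - 1))  # sum of others = high/8 << high
            row = np.full(n, low)
            row[home] = high
            if config.noise_sigma > 0:
                row = row * np.exp2(rng.normal(0.0, config.noise_sigma, size=n))
            spec[i] = row * phi
            gid = f"SPEC{i + 1:05d}"
            gene_ids.append(gid)
            specific[samples[home]].append(gid)
        blocks.append(spec)

    # noise: independent per-cell levels with dropout zeros
    if config.n_noise_genes:
        noise = np.exp2(rng.normal(config.base_log2_mean, config.base_log2_sd, size=(config.n_noise_genes, n)))
        if config.dropout > 0:
            noise[rng.random((config.n_noise_genes, n)) < config.dropout] = 0.0
        noise = noise * phi[None, :]
        blocks.append(noise)
        gene_ids += [f"NOISE{i + 1:05d}" for i in range(config.n_noise_genes)]

    if not blocks:
        raise DomainError("configuration generates no genes")
    matrix = pd.DataFrame(np.vstack(blocks), index=gene_ids, columns=samples)
    validate_matrix(matrix, min_genes=1, min_samples=2)
    truth = GroundTruth(
        true_factors=pd.Series(phi, index=samples, name="factor"),
        core_genes=[g for g in gene_ids if g.startswith("CORE")],
        specific_genes=specific,
        noise_genes=[g for g in gene_ids if g.startswith("NOISE")],
        base_profile=pd.Series(base, index=[f"CORE{i + 1:05d}" for i in range(config.n_core_genes)]),
    )
    return matrix, truth


def distort(matrix: pd.DataFrame, factors) -> pd.DataFrame:
    """Multiply each sample by a factor — the exact inverse of normalizing
    by the reciprocal factors.  Rankings within samples, and hence trimmed
    and ubiquitous sets, are unchanged."""
    f = pd.Series(factors, dtype=float) if not isinstance(factors, pd.Series) else factors.astype(float)
    if not isinstance(factors, pd.Series):
        if len(f) != matrix.shape[1]:
            raise DomainError("factor vector length does not match sample count")
        f.index = matrix.columns
    if (f <= 0).any():
        raise DomainError("distortion factors must be positive")
    return matrix.mul(f.reindex(matrix.columns), axis=1)
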