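"""Gamma-Poisson scRNA-seq count simulator (Splat-style) with group
differential expression and logistic dropout.

The generative chain per gene g and cell c:

1. base gene means  μ_g ~ Gamma(mean_shape, rate=mean_rate);
2. per-group DE: a ``de_prob`` fraction of genes receives a
   multiplicative log-normal(0, de_facscale) fold-change in each group;
3. cell library sizes  L_c ~ LogNormal(lib_loc, lib_scale); the group's
   gene means are renormalized to proportions and scaled to L_c;
4. biological noise: λ_gc ~ Gamma(1/B², scale = mean·B²) with a
   mean-trended coefficient of variation B = bcv + 1/sqrt(mean+1),
   then counts ~ Poisson(λ_gc) — a negative-binomial marginal;
5. dropout: each count is zeroed with probability
   logistic(dropout_shape · (log mean − dropout_mid)), so with a
   negative shape weakly expressed genes drop out most.

The default parameterization produces the study conditions used
throughout: two groups of 100 cells, 22,002 genes, a hard noisy
two-group problem. Everything is deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .io_matrix import CountMatrix

__all__ = ["SimParams", "simulate_counts", "plant_outliers"]


@dataclass
class SimParams:
    n_groups: int = 2
    cells_per_group: int = 100
    n_genes: int = 22002
    de_prob: float = 0.1
    de_facscale: float = 0.215
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    lib_loc: float = 11.0
    lib_scale: float = 0.3
    bcv: float = 0.2
    dropout_mid: float = 0.0
    dropout_shape: float = -1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.cells_per_group < 1 or self.n_genes < 1:
            raise ValueError("n_groups, cells_per_group and n_genes must be >= 1")
        if not 0 <= self.de_prob <= 1:
            raise ValueError("de_prob must be in [0, 1]")
        for name in ("de_facscale", "mean_shape", "mean_rate", "lib_scale", "bcv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def simulate_counts(p: SimParams) -> CountMatrix:
    """Draw one labelled count matrix from the generative model above."""
    rng = np.random.default_rng(p.seed)
    G = p.n_genes
    n = p.n_groups * p.cells_per_group

    base = rng.gamma(p.mean_shape, 1.0 / p.mean_rate, size=G)
    group_means = np.empty((G, p.n_groups))
    for g in range(p.n_groups):
        de_mask = rng.random(G) < p.de_prob
        factors = np.exp(rng.normal(0.0, p.de_facscale, size=G))
        group_means[:, g] = base * np.where(de_mask, factors, 1.0)

    lib = rng.lognormal(p.lib_loc, p.lib_scale, size=n)
    groups = np.repeat(np.arange(p.n_groups), p.cells_per_group)
    props = group_means / group_means.sum(axis=0, keepdims=True)
    mean_gc = props[:, groups] * lib[None, :]

    bcv_gc = p.bcv + 1.0 / np.sqrt(mean_gc + 1.0)
    shape = 1.0 / bcv_gc**2
    lam = rng.gamma(shape, np.maximum(mean_gc, 1e-300) / shape)
    counts = rng.poisson(lam)

    p_drop = expit(p.dropout_shape * (np.log(np.maximum(mean_gc, 1e-12)) - p.dropout_mid))
    counts[rng.random(counts.shape) < p_drop] = 0

    gene_ids = [f"Gene{i + 1}" for i in range(G)]
    cell_ids = [f"Cell{i + 1}" for i in range(n)]
    labels = [f"Group{g + 1}" for g in groups]
    return CountMatrix(counts.astype(np.int64), gene_ids, cell_ids, labels)


def plant_outliers(
    c: CountMatrix, n_outliers: int, intensity: float, seed: int
) -> tuple[CountMatrix, np.ndarray]:
    """Corrupt ``n_outliers`` random cells into outliers.

    Each chosen cell's count vector is replaced by a gene-permuted,
    intensity-scaled copy of itself, destroying its expression profile
    while keeping its library-size order of magnitude. Labels are kept;
    the corrupted cell indices are returned alongside the matrix.
    """
    if n_outliers < 0 or n_outliers >= c.n_cells:
        raise ValueError("n_outliers must be in [0, n_cells)")
    if n_outliers == 0:
        return c, np.array([], dtype=int)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(c.n_cells, size=n_outliers, replace=False))
    counts = c.counts.copy()
    for i in idx:
        perm = rng.permutation(c.n_genes)
        counts[:, i] = np.rint(counts[perm, i] * intensity).astype(np.int64)
    out = CountMatrix(counts, list(c.gene_ids), list(c.cell_ids), c.labels)
    return out, idx
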