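"""Preprocessing of raw counts into the model input matrix X.

Four steps, applied in order: (1) drop genes with zero total count,
(2) drop genes expressed in fewer than ``min_cells_expressed`` cells,
(3) keep the top ``n_hvg`` highly variable genes by binned normalized
dispersion, (4) log1p-transform and standardize each gene to zero mean
and unit (population) variance.

Standardization produces negative values, which a nonnegative
factorization cannot consume; ``nonneg_mode`` controls the resolution:
``"shift"`` (default) subtracts each gene row's minimum so the row's
smallest entry is 0 while its variance is preserved, ``"clip"`` zeroes
negatives, ``"none"`` leaves the standardized values untouched.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_matrix import CountMatrix

__all__ = [
    "PreprocessConfig",
    "ProcessedMatrix",
    "filter_genes",
    "select_hvg",
    "log_scale",
    "preprocess_pipeline",
]

logger = logging.getLogger(__name__)

_NONNEG_MODES = ("shift", "clip", "none")


@dataclass
class PreprocessConfig:
    min_cells_expressed: int = 3
    n_hvg: int = 1000
    scale_per_gene: bool = True
    nonneg_mode: str = "shift"
    n_bins: int = 20  # mean bins for dispersion normalization

    def __post_init__(self) -> None:
        if self.min_cells_expressed < 0:
            raise ValueError("min_cells_expressed must be >= 0")
        if self.n_hvg < 1:
            raise ValueError("n_hvg must be >= 1")
        if self.nonneg_mode not in _NONNEG_MODES:
            raise ValueError(f"nonneg_mode must be one of {_NONNEG_MODES}")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


@dataclass
class ProcessedMatrix:
    """Model input X (m genes × n cells) with aligned identifiers."""

    X: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.gene_ids) != self.X.shape[0]:
            raise ValueError("gene_ids do not match X rows")
        if len(self.cell_ids) != self.X.shape[1]:
            raise ValueError("cell_ids do not match X columns")
        if self.labels is not None and len(self.labels) != self.X.shape[1]:
            raise ValueError("labels do not match X columns")

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]


def _subset_genes(c: CountMatrix, keep: np.ndarray) -> CountMatrix:
    return CountMatrix(
        c.counts[keep],
        [c.gene_ids[i] for i in np.flatnonzero(keep)]
        if keep.dtype == bool
        else [c.gene_ids[i] for i in keep],
        c.cell_ids,
        c.labels,
    )


def filter_genes(c: CountMatrix, cfg: PreprocessConfig) -> CountMatrix:
    """Steps 1–2: remove silent genes, then rarely-expressed genes."""
    totals = c.counts.sum(axis=1)
    n_expressed = (c.counts > 0).sum(axis=1)
    keep = (totals > 0) & (n_expressed >= cfg.min_cells_expressed)
    n_zero = int((totals == 0).sum())
    n_rare = int(((totals > 0) & ~keep).sum())
    logger.info(
        "filter_genes: removed %d silent and %d rarely-expressed genes "
        "(min_cells_expressed=%d), %d retained",
        n_zero, n_rare, cfg.min_cells_expressed, int(keep.sum()),
    )
    if not keep.any():
        raise ValueError("all genes removed by filtering")
    return _subset_genes(c, keep)


def _normalized_dispersion(counts: np.ndarray, n_bins: int) -> np.ndarray:
    """Binned normalized dispersion of log1p library-size-normalized counts.

    dispersion = variance/mean per gene; genes are binned by mean into
    ``n_bins`` equal-width bins and the dispersion is z-scored within each
    bin. Zero-variance genes score -inf so a constant gene never outranks
    a varying one.
    """
    totals = counts.sum(axis=0).astype(float)
    target = np.median(totals[totals > 0]) if (totals > 0).any() else 1.0
    scale = np.divide(target, totals, out=np.ones_like(totals), where=totals > 0)
    y = np.log1p(counts * scale)
    mean = y.mean(axis=1)
    var = y.var(axis=1)
    disp = np.divide(var, mean, out=np.zeros_like(var), where=mean > 0)

    if np.ptp(mean) == 0:
        bins = np.zeros(len(mean), dtype=int)
    else:
        bins = pd.cut(mean, bins=n_bins, labels=False)
    z = np.empty_like(disp)
    for b in np.unique(bins):
        sel = bins == b
        mu, sd = disp[sel].mean(), disp[sel].std()
        z[sel] = (disp[sel] - mu) / sd if sd > 0 else 0.0
    z[var == 0] = -np.inf
    return z, disp


def select_hvg(c: CountMatrix, n_hvg: int, n_bins: int = 20) -> CountMatrix:
    """Step 3: keep the ``n_hvg`` most variable genes, preserving order."""
    if n_hvg >= c.n_genes:
        if n_hvg > c.n_genes:
            warnings.warn(
                f"requested {n_hvg} HVGs but only {c.n_genes} genes remain; "
                "keeping all",
                stacklevel=2,
            )
        return c
    z, disp = _normalized_dispersion(c.counts, n_bins)
    # z-score ranks first; raw dispersion breaks ties (degenerate bins)
    order = np.lexsort((-disp, -z))
    keep = np.sort(order[:n_hvg])
    logger.info("select_hvg: kept %d of %d genes", n_hvg, c.n_genes)
    return _subset_genes(c, keep)


def log_scale(c: CountMatrix, cfg: PreprocessConfig) -> ProcessedMatrix:
    """Step 4: log1p then per-gene standardization (population variance).

    Zero-variance genes become all-zero rows rather than NaN. The
    configured ``nonneg_mode`` is applied afterwards.
    """
    if c.n_genes == 0 or c.n_cells == 0:
        raise ValueError("cannot log-scale an empty matrix")
    X = np.log1p(c.counts.astype(float))
    if cfg.scale_per_gene:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)  # ddof=0
        # constant rows leave an O(eps) residual sd; zero them, don't divide
        nonconst = sd > 1e-10 * np.maximum(1.0, np.abs(mu))
        X = np.divide(X - mu, sd, out=np.zeros_like(X), where=nonconst)
    if cfg.nonneg_mode == "shift":
        X = X - X.min(axis=1, keepdims=True)
    elif cfg.nonneg_mode == "clip":
        X = np.maximum(X, 0.0)
    return ProcessedMatrix(X, list(c.gene_ids), list(c.cell_ids), c.labels)


def preprocess_pipeline(c: CountMatrix, cfg: PreprocessConfig | None = None) -> ProcessedMatrix:
    """filter_genes → select_hvg → log_scale (deterministic)."""
    cfg = cfg or PreprocessConfig()
    if c.n_genes == 0 or c.n_cells == 0:
        raise ValueError("empty count matrix")
    filtered = filter_genes(c, cfg)
    hvg = select_hvg(filtered, cfg.n_hvg, cfg.n_bins)
    return log_scale(hvg, cfg)
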