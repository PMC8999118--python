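"""Nonnegative matrix factorization core: objectives, per-cell losses and
multiplicative updates, unweighted and cell-weighted.

The factorization approximates X ≈ U Vᵀ with X the m × n preprocessed
expression matrix (genes × cells), U ≥ 0 the m × r gene loading matrix and
V ≥ 0 the n × r cell embedding whose rows are clustered downstream. Two
data-fit norms are supported:

* ``frobenius`` — Σ_i w_i ‖x_i − U v_i‖²: the classical squared loss.
* ``l21`` — Σ_i w_i ‖x_i − U v_i‖₂: column-wise (per-cell) unsquared
  residual norms, which damp the influence of outlying cells.

Weights w ∈ [0,1]ⁿ act on cells, i.e. W = diag(w) multiplies the residual
on its cell axis. Updates are multiplicative (Lee–Seung style): U first,
then V against the freshly updated U, which keeps the matching objective
non-increasing; denominators carry an additive 1e-10 guard. The l21
V-step uses the trace-form rule V ← V ∘ (W Xᵀ U) / (W V Vᵀ Xᵀ U), which
also drives V toward column orthogonality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EPS",
    "Factorization",
    "init_factors",
    "objective",
    "cell_losses",
    "update_unweighted",
    "update_weighted",
    "normalize_v_columns",
]

EPS = 1e-10

_NORMS = ("frobenius", "l21")


@dataclass
class Factorization:
    """Nonnegative factors U (m×r) and V (n×r); rows of V embed cells."""

    U: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.U.ndim != 2 or self.V.ndim != 2:
            raise ValueError("U and V must be 2-D")
        if self.U.shape[1] != self.V.shape[1]:
            raise ValueError(
                f"rank mismatch: U has {self.U.shape[1]} components, "
                f"V has {self.V.shape[1]}"
            )
        for name, M in (("U", self.U), ("V", self.V)):
            if not np.isfinite(M).all():
                raise ValueError(f"{name} contains NaN/Inf")
            if (M < 0).any():
                raise ValueError(f"{name} contains negative entries")

    @property
    def r(self) -> int:
        return self.U.shape[1]

    def reconstruction(self) -> np.ndarray:
        return self.U @ self.V.T


def _check_norm(norm: str) -> None:
    if norm not in _NORMS:
        raise ValueError(f"norm must be one of {_NORMS}, got {norm!r}")


def _as_weights(w, n: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weight vector must have length {n}, got shape {w.shape}")
    if (w < 0).any() or (w > 1).any():
        raise ValueError("weights must lie in [0, 1]")
    return w


def init_factors(X: np.ndarray, r: int, seed: int) -> Factorization:
    """Strictly positive uniform(0,1) factors scaled by sqrt(mean(X)/r)."""
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    if not 1 <= r <= min(m, n):
        raise ValueError(f"rank r={r} out of range [1, {min(m, n)}]")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(X.mean(), EPS) / r)
    U = rng.uniform(EPS, 1.0, size=(m, r)) * scale
    V = rng.uniform(EPS, 1.0, size=(n, r)) * scale
    return Factorization(U, V)


def _column_sq_residuals(X: np.ndarray, F: Factorization) -> np.ndarray:
    R = X - F.reconstruction()
    return np.einsum("ij,ij->j", R, R)


def cell_losses(X: np.ndarray, F: Factorization, norm: str = "frobenius") -> np.ndarray:
    """Per-cell residual l_i = ‖x_i − U v_i‖²  (frobenius) or ‖·‖₂ (l21)."""
    _check_norm(norm)
    sq = _column_sq_residuals(np.asarray(X, dtype=float), F)
    return sq if norm == "frobenius" else np.sqrt(sq)


def objective(
    X: np.ndarray,
    F: Factorization,
    w: np.ndarray | None = None,
    norm: str = "frobenius",
) -> float:
    """Weighted data-fit term Σ_i w_i · l_i (self-paced penalty excluded)."""
    X = np.asarray(X, dtype=float)
    if X.shape != (F.U.shape[0], F.V.shape[0]):
        raise ValueError(
            f"X is {X.shape}, factorization reconstructs "
            f"{(F.U.shape[0], F.V.shape[0])}"
        )
    n = X.shape[1]
    w = np.ones(n) if w is None else _as_weights(w, n)
    return float(w @ cell_losses(X, F, norm))


def update_unweighted(X: np.ndarray, F: Factorization) -> Factorization:
    """One multiplicative step of plain Frobenius NMF.

    U ← U ∘ (X V)/(U VᵀV), then V ← V ∘ (Xᵀ U)/(V UᵀU) with the updated U.
    """
    X = np.asarray(X, dtype=float)
    U = F.U * (X @ F.V) / (F.U @ (F.V.T @ F.V) + EPS)
    V = F.V * (X.T @ U) / (F.V @ (U.T @ U) + EPS)
    return Factorization(U, V)


def update_weighted(
    X: np.ndarray, F: Factorization, w: np.ndarray, norm: str = "frobenius"
) -> Factorization:
    """One multiplicative step of cell-weighted NMF with W = diag(w).

    Both norms share the U-step U ← U ∘ (X W V)/(U VᵀW V). The V-step is
    V ← V ∘ (W Xᵀ U)/(W V UᵀU) for the Frobenius model (cell weights
    cancel row-wise, so with unit weights the step is bit-identical to
    :func:`update_unweighted`) and V ← V ∘ (W Xᵀ U)/(W V Vᵀ Xᵀ U) for the
    l21/trace model.
    """
    _check_norm(norm)
    X = np.asarray(X, dtype=float)
    if X.shape != (F.U.shape[0], F.V.shape[0]):
        raise ValueError("X does not conform with the factorization")
    w = _as_weights(w, X.shape[1])
    wc = w[:, None]

    WV = wc * F.V
    U = F.U * (X @ WV) / (F.U @ (F.V.T @ WV) + EPS)

    XtU = X.T @ U
    if norm == "frobenius":
        V = F.V * (wc * XtU) / (wc * (F.V @ (U.T @ U)) + EPS)
    else:
        V = F.V * (wc * XtU) / (wc * (F.V @ (F.V.T @ XtU)) + EPS)
    return Factorization(U, V)


def normalize_v_columns(F: Factorization) -> Factorization:
    """Rescale V's columns to unit Euclidean norm, folding the inverse
    scale into U so that U Vᵀ is unchanged. Zero columns are left as is."""
    norms = np.linalg.norm(F.V, axis=0)
    scale = np.where(norms > EPS, norms, 1.0)
    return Factorization(F.U * scale, F.V / scale)
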