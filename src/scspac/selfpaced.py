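"""Self-paced controller: weighting schemes, pace scheduling and the outer
fit loop (scSPaC for the Frobenius norm, sscSPaC for the l2,1 norm).

Cells are admitted to the factorization from easy to hard. "Easy" means a
small current reconstruction loss l_i; the pace parameter λ is set from
the empirical loss distribution so that a target fraction of cells is
selected, starting at 60% and growing by 10 percentage points per outer
iteration until every cell participates. Two weighting schemes map losses
to weights w ∈ [0,1]:

* ``hard``    — w_i = 1 if l_i < λ else 0 (binary selection);
* ``mixture`` — w_i = 1 for l_i ≤ ζλ/(ζ+λ), 0 for l_i ≥ λ, and
  ζ/l_i − ζ/λ in between: a soft transition zone governed by ζ, held at
  ζ = 0.5·λ by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .nmf_core import (
    EPS,
    Factorization,
    cell_losses,
    init_factors,
    objective,
    update_weighted,
)
from .preprocess import ProcessedMatrix

__all__ = [
    "SPLState",
    "SPaCConfig",
    "OuterRecord",
    "FitResult",
    "hard_weights",
    "mixture_weights",
    "spl_regularizer",
    "schedule_lambda",
    "fit",
]

_SCHEMES = ("hard", "mixture")


@dataclass
class SPLState:
    """Snapshot of the self-paced controller."""

    w: np.ndarray
    losses: np.ndarray
    lam: float
    zeta: float
    selected_fraction: float


@dataclass
class SPaCConfig:
    """Configuration of a scSPaC/sscSPaC fit.

    ``norm`` picks the model (frobenius → scSPaC, l21 → sscSPaC);
    ``weighting`` picks the selection scheme (mixture is the default,
    hard is kept for ablation). ``init_fraction``/``fraction_step``
    define the admission schedule; ``inner_iters`` is the factor-update
    budget per outer iteration; ``warm_start_iters`` unweighted steps
    provide the initial losses. All randomness flows from ``seed``.
    """

    norm: str = "frobenius"
    weighting: str = "mixture"
    r: int = 2
    init_fraction: float = 0.6
    fraction_step: float = 0.1
    inner_iters: int = 50
    tol: float = 1e-5
    seed: int = 0
    warm_start_iters: int = 10
    zeta_ratio: float = 0.5
    max_extra_outer: int = 20

    def __post_init__(self) -> None:
        if self.norm not in ("frobenius", "l21"):
            raise ValueError("norm must be 'frobenius' or 'l21'")
        if self.weighting not in _SCHEMES:
            raise ValueError(f"weighting must be one of {_SCHEMES}")
        if not 0 < self.init_fraction <= 1:
            raise ValueError("init_fraction must be in (0, 1]")
        if not 0 < self.fraction_step <= 1:
            raise ValueError("fraction_step must be in (0, 1]")
        if self.r < 1:
            raise ValueError("r must be >= 1")
        if self.inner_iters < 1:
            raise ValueError("inner_iters must be >= 1")


@dataclass
class OuterRecord:
    """One outer iteration: pace, selection size and objective value."""

    outer: int
    fraction: float
    lam: float
    zeta: float
    n_selected: int
    objective: float  # data fit + self-paced penalty
    data_fit: float


@dataclass
class FitResult:
    factors: Factorization
    state: SPLState
    history: list[OuterRecord]
    converged: bool

    def __iter__(self):
        # allow `factors, state, history = fit(...)`
        return iter((self.factors, self.state, self.history))


def hard_weights(losses: np.ndarray, lam: float) -> np.ndarray:
    """Binary selection: w_i = 1 iff l_i < λ."""
    if lam <= 0:
        raise ValueError("lam must be > 0")
    return (np.asarray(losses, dtype=float) < lam).astype(float)


def mixture_weights(losses: np.ndarray, lam: float, zeta: float) -> np.ndarray:
    """Soft selection with a transition zone between ζλ/(ζ+λ) and λ.

    Continuous in l_i: w = 1 below the lower breakpoint, 0 at or above λ,
    ζ/l − ζ/λ in between. A zero loss falls in the first branch, so no
    division by zero can occur.
    """
    if lam <= 0 or zeta <= 0:
        raise ValueError("lam and zeta must be > 0")
    l = np.asarray(losses, dtype=float)
    low = zeta * lam / (zeta + lam)
    mid = zeta / np.maximum(l, low) - zeta / lam
    w = np.where(l <= low, 1.0, np.where(l >= lam, 0.0, mid))
    return np.clip(w, 0.0, 1.0)


def spl_regularizer(w: np.ndarray, lam: float, zeta: float, scheme: str) -> float:
    """Self-paced penalty f(λ, w): −λ·Σw (hard) or −Σ ζ·ln(w + ζ/λ) (mixture)."""
    w = np.asarray(w, dtype=float)
    if scheme == "hard":
        return float(-lam * w.sum())
    if scheme == "mixture":
        return float(-(zeta * np.log(w + zeta / lam)).sum())
    raise ValueError(f"scheme must be one of {_SCHEMES}")


def _weights(losses: np.ndarray, lam: float, zeta: float, scheme: str) -> np.ndarray:
    if scheme == "hard":
        return hard_weights(losses, lam)
    return mixture_weights(losses, lam, zeta)


def schedule_lambda(losses: np.ndarray, target_fraction: float) -> float:
    """Set λ just above the k-th smallest loss, k = ceil(fraction·n).

    Exactly the k easiest cells then satisfy l_i < λ (ties at the k-th
    value are all included). ``target_fraction=1`` yields λ above the
    maximum loss, selecting every cell.
    """
    losses = np.asarray(losses, dtype=float)
    if losses.size == 0:
        raise ValueError("empty loss vector")
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    n = losses.size
    k = min(max(int(math.ceil(target_fraction * n)), 1), n)
    kth = float(np.partition(losses, k - 1)[k - 1])
    # the 1e-12 floor keeps λ positive (and selecting) when the k-th loss is 0
    return kth * (1.0 + 1e-6) + 1e-12


def _reinflate(V: np.ndarray, w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Give collapsed-but-selected cells a fresh positive embedding row.

    A deselected cell's V row is driven to exact zero by the weighted
    multiplicative update, from which a multiplicative rule cannot
    escape; when the schedule re-admits the cell its row is reseeded
    with a small positive value so the updates can regrow it.
    """
    dead = (w > 0) & (V.max(axis=1) <= EPS)
    if not dead.any():
        return V
    pos = V[V > EPS]
    scale = float(pos.mean()) if pos.size else 1.0
    V = V.copy()
    V[dead] = rng.uniform(0.1, 1.0, size=(int(dead.sum()), V.shape[1])) * scale * 1e-2
    return V


def fit(X: np.ndarray | ProcessedMatrix, cfg: SPaCConfig) -> FitResult:
    """Run the full self-paced factorization.

    Outer loop: a short unweighted warm start supplies initial losses;
    λ is set from them at ``init_fraction``; then each outer iteration
    runs ``inner_iters`` weighted multiplicative updates at fixed w
    (Step 1), recomputes losses, raises the target fraction by
    ``fraction_step``, re-derives λ (and ζ = zeta_ratio·λ) from the fresh
    losses and recomputes w (Step 2). Iteration stops once every cell is
    selected and the relative change of the penalized objective falls
    below ``tol``; if that never happens within the schedule length plus
    ``max_extra_outer`` iterations the best-so-far result is returned
    with ``converged=False`` and a warning.
    """
    if isinstance(X, ProcessedMatrix):
        X = X.X
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError(
            "X must be nonnegative; preprocess with nonneg_mode='shift' or 'clip'"
        )
    n = X.shape[1]

    F = init_factors(X, cfg.r, cfg.seed)
    ones = np.ones(n)
    for _ in range(cfg.warm_start_iters):
        F = update_weighted(X, F, ones, cfg.norm)
    losses = cell_losses(X, F, cfg.norm)

    fraction = cfg.init_fraction
    lam = schedule_lambda(losses, fraction)
    zeta = cfg.zeta_ratio * lam
    w = _weights(losses, lam, zeta, cfg.weighting)

    n_sched = int(math.ceil((1.0 - cfg.init_fraction) / cfg.fraction_step)) + 1
    max_outer = n_sched + cfg.max_extra_outer
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x51AC]))

    history: list[OuterRecord] = []
    prev_full_obj: float | None = None
    converged = False

    for outer in range(max_outer):
        F = Factorization(F.U, _reinflate(F.V, w, rng))
        for _ in range(cfg.inner_iters):
            F = update_weighted(X, F, w, cfg.norm)
        losses = cell_losses(X, F, cfg.norm)
        data_fit = objective(X, F, w, cfg.norm)
        obj = data_fit + spl_regularizer(w, lam, zeta, cfg.weighting)
        history.append(
            OuterRecord(outer, fraction, lam, zeta, int((w > 0).sum()), obj, data_fit)
        )
        if fraction >= 1.0:
            if (
                prev_full_obj is not None
                and abs(obj - prev_full_obj) <= cfg.tol * max(abs(prev_full_obj), EPS)
            ):
                converged = True
                break
            prev_full_obj = obj
        if fraction < 1.0:
            fraction = min(1.0, fraction + cfg.fraction_step)
        lam = schedule_lambda(losses, fraction)
        zeta = cfg.zeta_ratio * lam
        w = _weights(losses, lam, zeta, cfg.weighting)

    if not converged:
        warnings.warn(
            f"self-paced fit did not converge within {max_outer} outer "
            "iterations; returning best-so-far",
            stacklevel=2,
        )
    state = SPLState(w=w, losses=losses, lam=lam, zeta=zeta, selected_fraction=fraction)
    return FitResult(F, state, history, converged)
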