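"""K-means on the learned cell embedding V and the K ± radius scan."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .metrics import ari
from .nmf_core import Factorization
from .preprocess import ProcessedMatrix
from .selfpaced import SPaCConfig, fit

__all__ = ["ClusterResult", "kmeans_embed", "scan_k"]


@dataclass
class ClusterResult:
    assignments: np.ndarray  # 0-based cluster index per cell
    K: int
    centers: np.ndarray  # K × r
    inertia: float


def kmeans_embed(
    F: Factorization | np.ndarray, K: int, seed: int, n_restarts: int = 10
) -> ClusterResult:
    """Lloyd's algorithm with k-means++ seeding on the rows of V.

    Best of ``n_restarts`` initializations by inertia; deterministic for
    a fixed seed.
    """
    V = F.V if isinstance(F, Factorization) else np.asarray(F, dtype=float)
    n = V.shape[0]
    if not 1 <= K <= n:
        raise ValueError(f"K={K} out of range [1, {n}]")
    km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed).fit(V)
    return ClusterResult(
        assignments=km.labels_.astype(int),
        K=K,
        centers=km.cluster_centers_,
        inertia=float(km.inertia_),
    )


def scan_k(
    X: ProcessedMatrix | np.ndarray,
    cfg: SPaCConfig,
    k_center: int,
    radius: int = 3,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Refit and cluster for each K in [k_center − radius, k_center + radius].

    K values below 2 are reported as unavailable (score NaN). With
    ground-truth labels the score column is ``ari`` and the best K is its
    argmax; without labels only K-means ``inertia`` is reported and no
    best-K claim is made beyond its argmin (elbow inspection is left to
    the user). The NMF rank r follows K for each fit.
    """
    rows = []
    for K in range(k_center - radius, k_center + radius + 1):
        if K < 2:
            rows.append({"K": K, "available": False, "score": np.nan})
            continue
        res = fit(X, replace(cfg, r=K))
        cl = kmeans_embed(res.factors, K, cfg.seed)
        score = (
            ari(cl.assignments, labels) if labels is not None else cl.inertia
        )
        rows.append({"K": K, "available": True, "score": float(score)})
    df = pd.DataFrame(rows)
    df = df.rename(columns={"score": "ari" if labels is not None else "inertia"})
    col = "ari" if labels is not None else "inertia"
    avail = df["available"]
    best_idx = (
        df.loc[avail, col].idxmax() if labels is not None else df.loc[avail, col].idxmin()
    )
    df["best"] = False
    df.loc[best_idx, "best"] = True
    return df
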