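"""External clustering indices: adjusted Rand index, purity and NMI.

All three are computed from the contingency table n_kj counting cells
assigned to predicted cluster k whose true class is j. ARI is the
chance-corrected pair-counting Rand index (values in [−1, 1], 1 for a
perfect match, ≈0 at chance); purity is the weighted majority-class
fraction per cluster; NMI is 2·I(C,Y)/(H(C)+H(Y)) with natural-log
entropies (the base cancels). Machine output is on the raw [0, 1] scale;
``MetricReport.as_percent`` gives the ×100 convention used in summary
tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import comb

__all__ = ["MetricReport", "contingency", "ari", "purity", "nmi", "evaluate"]


@dataclass
class MetricReport:
    ari: float
    purity: float
    nmi: float
    contingency: np.ndarray  # clusters × classes
    N: int

    def as_percent(self) -> dict[str, float]:
        return {
            "ari": 100.0 * self.ari,
            "purity": 100.0 * self.purity,
            "nmi": 100.0 * self.nmi,
        }


def _encode(labels) -> np.ndarray:
    arr = np.asarray(labels)
    _, inv = np.unique(arr, return_inverse=True)
    return inv


def contingency(pred, truth) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Counts n_kj with row margins a_k (clusters) and column margins b_j."""
    p, t = np.asarray(pred), np.asarray(truth)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError(
            f"pred and truth must be equal-length vectors, got {p.shape} and {t.shape}"
        )
    if p.size == 0:
        raise ValueError("empty label vectors")
    pi, ti = _encode(p), _encode(t)
    M = np.zeros((pi.max() + 1, ti.max() + 1), dtype=int)
    np.add.at(M, (pi, ti), 1)
    return M, M.sum(axis=1), M.sum(axis=0)


def _check_pairable(pred) -> None:
    if np.asarray(pred).size < 2:
        raise ValueError("need at least 2 items for pair-counting indices")


def ari(pred, truth) -> float:
    """Adjusted Rand index via pair counts from the contingency table."""
    _check_pairable(pred)
    M, a, b = contingency(pred, truth)
    n = int(M.sum())
    sum_ij = comb(M, 2).sum()
    sum_a = comb(a, 2).sum()
    sum_b = comb(b, 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    maximum = 0.5 * (sum_a + sum_b)
    if maximum == expected:  # both partitions trivial: define as perfect
        return 1.0
    return float((sum_ij - expected) / (maximum - expected))


def purity(pred, truth) -> float:
    """(1/N) Σ_k max_j n_kj — majority-class mass over clusters."""
    _check_pairable(pred)
    M, _, _ = contingency(pred, truth)
    return float(M.max(axis=1).sum() / M.sum())


def nmi(pred, truth) -> float:
    """2·I(C,Y)/(H(C)+H(Y)); two single-cluster partitions score 1."""
    _check_pairable(pred)
    M, a, b = contingency(pred, truth)
    n = M.sum()
    pa, pb = a / n, b / n

    def _entropy(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    ha, hb = _entropy(pa), _entropy(pb)
    if ha + hb == 0.0:
        return 1.0
    pij = M / n
    nz = M > 0
    mi = float((pij[nz] * np.log(pij[nz] / np.outer(pa, pb)[nz])).sum())
    return float(np.clip(2.0 * mi / (ha + hb), 0.0, 1.0))


def evaluate(pred, truth) -> MetricReport:
    """All three indices plus the contingency table in one report."""
    M, _, _ = contingency(pred, truth)
    return MetricReport(
        ari=ari(pred, truth),
        purity=purity(pred, truth),
        nmi=nmi(pred, truth),
        contingency=M,
        N=int(M.sum()),
    )
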