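"""End-to-end orchestration: simulate/load → preprocess → fit → cluster →
evaluate, plus the repeated-run battery and the HVG sweep."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .cluster import kmeans_embed
from .io_matrix import CountMatrix, read_counts, read_labels, write_labels
from .metrics import MetricReport, evaluate
from .nmf_core import Factorization
from .preprocess import PreprocessConfig, ProcessedMatrix, preprocess_pipeline
from .selfpaced import SPaCConfig, fit
from .simulate import SimParams, simulate_counts

__all__ = [
    "RunConfig",
    "run_pipeline",
    "run_battery",
    "summarize_battery",
    "hvg_sweep",
    "METHODS",
]

# method name -> SPaCConfig overrides; K-means-on-X is handled separately
METHODS = {
    "scSPaC": dict(norm="frobenius", weighting="mixture"),
    "sscSPaC": dict(norm="l21", weighting="mixture"),
    "NMF": dict(norm="frobenius", weighting="hard", init_fraction=1.0),
    "l21-NMF": dict(norm="l21", weighting="hard", init_fraction=1.0),
}


@dataclass
class RunConfig:
    """Composite configuration for one pipeline run.

    Either ``counts_path`` (with optional ``labels_path``) or ``sim``
    must be provided; ``sim`` wins when both are present.
    """

    sim: SimParams | None = None
    counts_path: str | None = None
    counts_format: str = "dense_tsv"
    labels_path: str | None = None
    pre: PreprocessConfig = field(default_factory=PreprocessConfig)
    spac: SPaCConfig = field(default_factory=SPaCConfig)
    K: int = 2
    seed: int = 0


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_counts(cfg: RunConfig) -> CountMatrix:
    if cfg.sim is not None:
        return simulate_counts(replace(cfg.sim, seed=cfg.seed))
    if cfg.counts_path is None:
        raise ValueError("RunConfig needs either sim parameters or a counts_path")
    c = read_counts(cfg.counts_path, cfg.counts_format)
    if cfg.labels_path:
        c.labels = read_labels(cfg.labels_path, c.cell_ids)
    return c


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute all stages; returns factors, assignments and (with labels)
    the metric report. Artifacts and a manifest are written to ``outdir``
    when given."""
    counts = _load_counts(cfg)
    processed = preprocess_pipeline(counts, cfg.pre)
    spac = replace(cfg.spac, seed=cfg.seed)
    res = fit(processed, spac)
    cl = kmeans_embed(res.factors, cfg.K, cfg.seed)
    report = (
        evaluate(cl.assignments, processed.labels)
        if processed.labels is not None
        else None
    )
    out = {
        "processed": processed,
        "factors": res.factors,
        "state": res.state,
        "history": res.history,
        "converged": res.converged,
        "assignments": cl.assignments,
        "cluster": cl,
        "report": report,
        "config_hash": _config_hash(cfg),
    }
    if outdir is not None:
        _write_artifacts(cfg, out, Path(outdir))
    return out


def _write_artifacts(cfg: RunConfig, out: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    processed: ProcessedMatrix = out["processed"]
    pd.DataFrame(
        processed.X, index=processed.gene_ids, columns=processed.cell_ids
    ).to_csv(outdir / "processed.tsv", sep="\t")
    F: Factorization = out["factors"]
    np.savetxt(outdir / "U.tsv", F.U, delimiter="\t")
    np.savetxt(outdir / "V.tsv", F.V, delimiter="\t")
    write_labels(
        [str(a) for a in out["assignments"]],
        outdir / "assignments.tsv",
        processed.cell_ids,
    )
    hist = pd.DataFrame([dataclasses.asdict(h) for h in out["history"]])
    hist.to_csv(outdir / "history.tsv", sep="\t", index=False)
    if out["report"] is not None:
        rep: MetricReport = out["report"]
        pd.DataFrame([{"ari": rep.ari, "purity": rep.purity, "nmi": rep.nmi, "N": rep.N}]).to_csv(
            outdir / "metrics.tsv", sep="\t", index=False
        )
    manifest = {
        "package": "scspac",
        "version": _pkg_version,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": cfg.seed,
        "config_hash": out["config_hash"],
        "config": dataclasses.asdict(cfg),
        "converged": bool(out["converged"]),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _direct_kmeans_metrics(processed: ProcessedMatrix, K: int, seed: int) -> MetricReport:
    cl = kmeans_embed(processed.X.T, K, seed)
    return evaluate(cl.assignments, processed.labels)


def run_battery(
    cfg: RunConfig,
    seeds: list[int],
    methods: tuple[str, ...] = ("scSPaC", "sscSPaC", "NMF", "KMeans"),
) -> pd.DataFrame:
    """Repeat the pipeline over seeds × methods on freshly drawn data.

    Each seed draws its own simulation (or reuses the loaded matrix) and
    every method sees the same preprocessed input for that seed.
    Returns one row per (seed, method) with raw [0, 1] metrics.
    """
    rows = []
    for seed in seeds:
        run_cfg = replace(cfg, seed=int(seed))
        counts = _load_counts(run_cfg)
        processed = preprocess_pipeline(counts, cfg.pre)
        if processed.labels is None:
            raise ValueError("run_battery requires ground-truth labels")
        for method in methods:
            if method == "KMeans":
                rep = _direct_kmeans_metrics(processed, cfg.K, int(seed))
            else:
                spac = replace(cfg.spac, seed=int(seed), **METHODS[method])
                res = fit(processed, spac)
                cl = kmeans_embed(res.factors, cfg.K, int(seed))
                rep = evaluate(cl.assignments, processed.labels)
            rows.append(
                {"seed": int(seed), "method": method, "ari": rep.ari,
                 "purity": rep.purity, "nmi": rep.nmi}
            )
    return pd.DataFrame(rows)


def summarize_battery(battery: pd.DataFrame) -> pd.DataFrame:
    """Mean ± std per method on the ×100 scale of the summary tables."""
    g = battery.groupby("method")[["ari", "purity", "nmi"]]
    mean, std = g.mean() * 100, g.std(ddof=1) * 100
    out = mean.join(std, lsuffix="_mean", rsuffix="_std")
    return out.reset_index()


def hvg_sweep(
    cfg: RunConfig,
    hvg_list: tuple[int, ...] = (200, 500, 1000, 1500, 2000, 2500),
    seeds: list[int] | None = None,
    method: str = "scSPaC",
) -> pd.DataFrame:
    """Mean ± std ARI of one method as a function of the HVG count."""
    seeds = list(range(20)) if seeds is None else seeds
    rows = []
    for n_hvg in hvg_list:
        sweep_cfg = replace(cfg, pre=replace(cfg.pre, n_hvg=int(n_hvg)))
        battery = run_battery(sweep_cfg, seeds, methods=(method,))
        rows.append(
            {
                "n_hvg": int(n_hvg),
                "ari_mean": 100 * battery["ari"].mean(),
                "ari_std": 100 * battery["ari"].std(ddof=1),
            }
        )
    return pd.DataFrame(rows)
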