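"""End-to-end workflows: configuration, run grid, evaluation, consensus,
scoring and the machine-readable report.

Three usage scenarios are supported by one entry point:

1. no external truth — methods are compared by survival significance,
   silhouette and cross-method agreement, plus the consensus heatmap;
2. expert-defined subtypes supplied as true labels — NMI/ARI against the
   truth are added and a best method is flagged at k = number of true
   subtypes via the weighted performance score;
3. a user's own subtyping result (labels, optionally an integrated
   matrix) joins the comparison alongside the built-in methods.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .layers import OmicsLayer, ValidationError, read_layer
from .preprocess import PreprocessConfig, intersect_samples, preprocess_layer
from .methods import (
    BUILTIN_METHODS,
    MethodSpec,
    SubtypingResult,
    load_user_result,
    run_grid,
)
from .metrics import (
    SurvivalTable,
    agreement_tables,
    ari,
    cox_pvalue,
    km_curves,
    nmi,
    read_survival,
    read_true_labels,
    result_distance,
    silhouette,
)
from .consensus import (
    consensus_cluster,
    overall_consensus,
    performance_score,
)
from .turning import TurningConfig

__all__ = ["UserResultConfig", "RunConfig", "Report", "run_scenario", "emit_report"]


@dataclass
class UserResultConfig:
    """Paths describing one user-supplied subtyping result."""

    labels_path: str
    name: str = "user"
    matrix_path: Optional[str] = None
    matrix_kind: Optional[str] = None


@dataclass
class RunConfig:
    """Everything one platform run needs.

    ``layers`` maps layer name -> TSV path.  ``methods`` names built-in
    methods to run; user results are added via ``user_results``.
    """

    layers: dict[str, str] = field(default_factory=dict)
    survival_path: Optional[str] = None
    truth_path: Optional[str] = None
    user_results: list[UserResultConfig] = field(default_factory=list)
    methods: list[str] = field(default_factory=lambda: ["concat", "simfuse"])
    k_max: int = 5
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    turning: TurningConfig = field(default_factory=TurningConfig)
    consensus_k: Optional[int] = None
    out_dir: Optional[str] = None
    seed: int = 0
    make_plots: bool = False

    def validate(self) -> None:
        if self.k_max < 2:
            raise ValidationError("k_max must be >= 2")
        unknown = [m for m in self.methods if m not in BUILTIN_METHODS]
        if unknown:
            raise ValidationError(
                f"unknown method(s) {unknown}; built-ins: {sorted(BUILTIN_METHODS)}"
            )
        self.preprocess.validate()
        self.turning.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        pp = PreprocessConfig(**raw.pop("preprocess", {}))
        tp = TurningConfig(**raw.pop("turning", {}))
        users = [UserResultConfig(**u) for u in raw.pop("user_results", [])]
        return cls(preprocess=pp, turning=tp, user_results=users, **raw)


@dataclass
class Report:
    """Two-part machine-readable report.

    Part 1 (cross-method comparison): the metric table, cross-method
    agreement, consensus labels and heatmap order.  Part 2 (per-method
    detail): KM curves per (method, k).  Metadata records the config,
    seed and any failed grid cells so every requested cell is accounted
    for exactly once.
    """

    metric_table: pd.DataFrame
    agreement: pd.DataFrame
    consensus_votes: np.ndarray
    consensus_n_runs: int
    consensus_labels: np.ndarray
    consensus_leaf_order: np.ndarray
    consensus_k: int
    sample_ids: list[str]
    km: pd.DataFrame
    scores: Optional[pd.DataFrame]
    failed_cells: list[tuple[str, int, str]]
    config_echo: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config_echo,
            "sample_ids": self.sample_ids,
            "metric_table": self.metric_table.to_dict(orient="records"),
            "agreement": self.agreement.to_dict(orient="records"),
            "consensus": {
                "n_runs": self.consensus_n_runs,
                "k": self.consensus_k,
                "labels": self.consensus_labels.tolist(),
                "leaf_order": self.consensus_leaf_order.tolist(),
                "votes": self.consensus_votes.tolist(),
            },
            "km_curves": self.km.to_dict(orient="records"),
            "scores": None if self.scores is None else self.scores.to_dict(orient="records"),
            "failed_cells": [list(c) for c in self.failed_cells],
        }


def _evaluate_cell(
    r: SubtypingResult,
    surv: Optional[SurvivalTable],
    truth: Optional[np.ndarray],
    layers: list[OmicsLayer],
) -> dict:
    row: dict = {
        "method": r.method_name,
        "k": r.k,
        "runtime_seconds": r.runtime_seconds,
        "cox_p": np.nan,
        "sc": np.nan,
        "nmi": np.nan,
        "ari": np.nan,
    }
    if surv is not None:
        row["cox_p"] = cox_pvalue(r.labels, surv)
    # user results without a matrix fall back to the cohort layers
    dist = result_distance(r, layers if layers else None)
    if dist is not None and len(np.unique(r.labels)) >= 2:
        row["sc"] = silhouette(r.labels, dist)
    if truth is not None:
        row["nmi"] = nmi(r.labels, truth)
        row["ari"] = ari(r.labels, truth)
    return row


def run_scenario(
    cfg: RunConfig,
    layers: Optional[list[OmicsLayer]] = None,
    survival: Optional[SurvivalTable] = None,
    true_labels: Optional[np.ndarray] = None,
) -> Report:
    """Execute one full platform run and (optionally) write the report.

    Layers, survival and truth may be passed in memory; otherwise they
    are read from the paths in ``cfg``.  Returns the :class:`Report`;
    when ``cfg.out_dir`` is set the report is also written to disk.
    """
    cfg.validate()
    if layers is None:
        layers = [read_layer(path, name) for name, path in cfg.layers.items()]
    if len(layers) < 2 and not (layers and cfg.user_results):
        raise ValidationError(
            "need >= 2 omics layers, or >= 1 layer plus a user result"
        )
    if len(layers) >= 2:
        layers = intersect_samples(layers)
    layers = [preprocess_layer(layer, cfg.preprocess) for layer in layers]
    if len(layers) >= 2:
        layers = intersect_samples(layers)  # re-align if filtering dropped samples
    sample_ids = layers[0].sample_ids

    if survival is None and cfg.survival_path:
        survival = read_survival(cfg.survival_path)
    if survival is not None:
        survival = survival.aligned_to(sample_ids)
    if true_labels is None and cfg.truth_path:
        true_labels = read_true_labels(cfg.truth_path, sample_ids)

    specs = [BUILTIN_METHODS[m] for m in cfg.methods]
    results, failed = run_grid(specs, layers, cfg.k_max, cfg.seed)
    for uc in cfg.user_results:
        results.append(
            load_user_result(
                uc.labels_path,
                sample_ids,
                method_name=uc.name,
                matrix_path=uc.matrix_path,
                kind=uc.matrix_kind,
            )
        )

    rows = [_evaluate_cell(r, survival, true_labels, layers) for r in results]
    metric_table = pd.DataFrame(
        rows, columns=["method", "k", "cox_p", "sc", "nmi", "ari", "runtime_seconds"]
    )
    agreement = agreement_tables(results)
    cm = overall_consensus(results)
    cc = consensus_cluster(cm, k=cfg.consensus_k, k_max=cfg.k_max)

    km_frames = []
    if survival is not None:
        for r in results:
            frame = km_curves(r.labels, survival)
            frame.insert(0, "method", r.method_name)
            frame.insert(1, "k", r.k)
            km_frames.append(frame)
    km = (
        pd.concat(km_frames, ignore_index=True)
        if km_frames
        else pd.DataFrame(columns=["method", "k", "cluster", "time", "survival"])
    )

    scores = None
    if true_labels is not None:
        k_truth = int(len(np.unique(true_labels)))
        try:
            scores = performance_score(metric_table, k=k_truth)
        except ValidationError as exc:
            warnings.warn(f"performance scoring skipped: {exc}")

    report = Report(
        metric_table=metric_table,
        agreement=agreement,
        consensus_votes=cm.votes,
        consensus_n_runs=cm.n_runs,
        consensus_labels=cc.labels,
        consensus_leaf_order=cc.leaf_order,
        consensus_k=cc.k,
        sample_ids=sample_ids,
        km=km,
        scores=scores,
        failed_cells=failed,
        config_echo=_config_echo(cfg),
        seed=cfg.seed,
    )
    if cfg.out_dir:
        emit_report(report, cfg.out_dir, make_plots=cfg.make_plots)
    return report


def _config_echo(cfg: RunConfig) -> dict:
    echo = asdict(cfg)
    echo["preprocess"] = asdict(cfg.preprocess)
    echo["turning"] = asdict(cfg.turning)
    return echo


def emit_report(report: Report, out_dir: str | Path, make_plots: bool = False) -> dict[str, Path]:
    """Write the report: a reloadable JSON master plus TSV tables and,
    optionally, KM-curve and consensus-heatmap images."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    master = out_dir / "report.json"
    with open(master, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    paths["report"] = master

    report.metric_table.to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
    paths["metrics"] = out_dir / "metrics.tsv"
    report.agreement.to_csv(out_dir / "agreement.tsv", sep="\t", index=False)
    paths["agreement"] = out_dir / "agreement.tsv"
    votes = pd.DataFrame(
        report.consensus_votes, index=report.sample_ids, columns=report.sample_ids
    )
    votes.to_csv(out_dir / "consensus_votes.tsv", sep="\t")
    paths["consensus_votes"] = out_dir / "consensus_votes.tsv"
    pd.DataFrame(
        {"sample": report.sample_ids, "consensus_label": report.consensus_labels}
    ).to_csv(out_dir / "consensus_labels.tsv", sep="\t", index=False)
    paths["consensus_labels"] = out_dir / "consensus_labels.tsv"
    if not report.km.empty:
        report.km.to_csv(out_dir / "km_curves.tsv", sep="\t", index=False)
        paths["km_curves"] = out_dir / "km_curves.tsv"
    if report.scores is not None:
        report.scores.to_csv(out_dir / "scores.tsv", sep="\t", index=False)
        paths["scores"] = out_dir / "scores.tsv"

    if make_plots:
        paths.update(_plot_report(report, out_dir))
    return paths


def _plot_report(report: Report, out_dir: Path) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths: dict[str, Path] = {}
    order = report.consensus_leaf_order
    freq = report.consensus_votes / report.consensus_n_runs
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(freq[np.ix_(order, order)], cmap="viridis", vmin=0, vmax=1)
    ax.set_title("Consensus co-clustering frequency")
    fig.colorbar(im, ax=ax, label="co-clustering frequency")
    fig.savefig(out_dir / "consensus_heatmap.png", dpi=120)
    plt.close(fig)
    paths["consensus_heatmap"] = out_dir / "consensus_heatmap.png"

    if not report.km.empty:
        for (method, k), grp in report.km.groupby(["method", "k"]):
            fig, ax = plt.subplots(figsize=(5, 4))
            for cluster, cg in grp.groupby("cluster"):
                ax.step(cg["time"], cg["survival"], where="post", label=f"subtype {cluster}")
            ax.set(xlabel="time", ylabel="survival probability", ylim=(0, 1.02),
                   title=f"{method}, k={k}")
            ax.legend()
            p = out_dir / f"km_{method}_k{k}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            paths[f"km_{method}_k{k}"] = p
    return paths


def load_report(path: str | Path) -> dict:
    """Reload an emitted master report JSON."""
    with open(path) as fh:
        return json.load(fh)
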