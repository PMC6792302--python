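"""Evaluation metrics for subtyping results.

Clustering metrics — silhouette coefficient, normalized mutual
information (NMI) and adjusted Rand index (ARI) — are implemented
directly from their contingency/distance definitions so that the exact
conventions used platform-wide (degenerate-case rules, the silhouette
``b(i)`` variant) are explicit and testable.  Survival metrics (Cox
proportional-hazards p-value, Kaplan-Meier curves) are computed with
lifelines.

Silhouette note: the classical (Rousseeuw) definition takes ``b(i)`` as
the smallest *per-cluster average* distance to another cluster.  This
platform's primary definition instead takes ``b(i)`` as the minimum
distance from sample i to any individual out-of-cluster sample; the
classical variant is available via ``variant="cluster_mean"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy.spatial.distance import pdist, squareform

from .layers import OmicsLayer, ValidationError
from .methods import SubtypingResult, _stack_layers

__all__ = [
    "SurvivalTable",
    "read_survival",
    "read_true_labels",
    "silhouette",
    "nmi",
    "ari",
    "cox_pvalue",
    "km_curves",
    "agreement_tables",
    "result_distance",
]


@dataclass
class SurvivalTable:
    """Per-sample follow-up: positive time and 0/1 event indicator."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValidationError("time/event lengths must match sample_ids")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids in survival table")
        if (self.time <= 0).any():
            raise ValidationError("survival times must be positive")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValidationError("event indicators must be 0/1")

    def aligned_to(self, sample_ids: list[str]) -> "SurvivalTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"survival table lacks sample(s) {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return SurvivalTable(list(sample_ids), self.time[idx], self.event[idx])


def read_survival(path: str | Path) -> SurvivalTable:
    """Read a 3-column TSV (sample, time, event)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValidationError(f"{path}: expected columns sample, time, event")
    return SurvivalTable(
        sample_ids=df.iloc[:, 0].astype(str).tolist(),
        time=df.iloc[:, 1].to_numpy(),
        event=df.iloc[:, 2].to_numpy(),
    )


def read_true_labels(path: str | Path, sample_ids: list[str]) -> np.ndarray:
    """Read a 2-column TSV (sample, subtype); returns integer labels
    aligned to ``sample_ids`` (arbitrary label values are rank-encoded)."""
    df = pd.read_csv(path, sep="\t")
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].astype(str))
    missing = [s for s in sample_ids if s not in ser.index]
    if missing:
        raise ValidationError(f"{path}: no true label for sample(s) {missing[:5]}")
    _, labels = np.unique(ser.loc[sample_ids].to_numpy(), return_inverse=True)
    return labels + 1


def _as_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    _, enc = np.unique(arr, return_inverse=True)
    return enc


def silhouette(labels, dist: np.ndarray, variant: str = "nearest_sample") -> float:
    """Mean silhouette s(i) = (b(i) - a(i)) / max(a(i), b(i)) in [-1, 1].

    ``a(i)`` is the average distance to the other members of i's cluster.
    With ``variant="nearest_sample"`` (the platform default) ``b(i)`` is
    the minimum distance to any sample outside i's cluster; with
    ``variant="cluster_mean"`` it is the classical smallest per-cluster
    average distance.  Singleton clusters and all-zero distances
    contribute s(i) = 0.
    """
    labels = _as_labels(labels)
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if dist.shape != (n, n):
        raise ValidationError(f"distance matrix must be {n}x{n}, got {dist.shape}")
    if not np.allclose(dist, dist.T, atol=1e-8) or not np.allclose(np.diag(dist), 0):
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValidationError("silhouette is undefined for a single cluster")
    if variant not in ("nearest_sample", "cluster_mean"):
        raise ValidationError(f"unknown silhouette variant {variant!r}")
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            continue  # singleton: s(i) = 0
        a = dist[i, own].sum() / (n_own - 1)
        if variant == "nearest_sample":
            b = dist[i, ~own].min()
        else:
            b = min(
                dist[i, labels == c].mean() for c in clusters if c != labels[i]
            )
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def _contingency(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xi = _as_labels(x)
    yi = _as_labels(y)
    table = np.zeros((xi.max() + 1, yi.max() + 1), dtype=np.int64)
    np.add.at(table, (xi, yi), 1)
    return table


def nmi(labels_x, labels_y) -> float:
    """Normalized mutual information 2 I(X;Y) / (H(X) + H(Y)) in [0, 1].

    Two single-cluster partitions agree perfectly (1); exactly one
    single-cluster partition carries no information (0).
    """
    x = np.asarray(labels_x)
    y = np.asarray(labels_y)
    if x.shape != y.shape:
        raise ValidationError("partitions must cover the same samples")
    table = _contingency(x, y).astype(float)
    n = table.sum()
    px = table.sum(axis=1) / n
    py = table.sum(axis=0) / n
    hx = -np.sum(px[px > 0] * np.log(px[px > 0]))
    hy = -np.sum(py[py > 0] * np.log(py[py > 0]))
    if hx == 0 and hy == 0:
        return 1.0
    if hx == 0 or hy == 0:
        return 0.0
    p = table / n
    outer = np.outer(px, py)
    nz = p > 0
    mi = np.sum(p[nz] * np.log(p[nz] / outer[nz]))
    return float(2.0 * mi / (hx + hy))


def _comb2(a: np.ndarray) -> np.ndarray:
    return a * (a - 1) / 2.0


def ari(labels_u, labels_v) -> float:
    """Adjusted Rand index from the pair-counting contingency formula.

    1 means the partitions are identical up to relabeling; 0 is the
    chance level; negative values indicate below-chance agreement.
    """
    u = np.asarray(labels_u)
    v = np.asarray(labels_v)
    if u.shape != v.shape:
        raise ValidationError("partitions must cover the same samples")
    n = u.size
    if n < 2:
        raise ValidationError("ARI needs at least 2 samples")
    table = _contingency(u, v)
    sum_ij = _comb2(table).sum()
    sum_i = _comb2(table.sum(axis=1)).sum()
    sum_j = _comb2(table.sum(axis=0)).sum()
    total = n * (n - 1) / 2.0
    expected = sum_i * sum_j / total
    max_index = (sum_i + sum_j) / 2.0
    if max_index == expected:  # both partitions trivial: identical by convention
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def cox_pvalue(labels, surv: SurvivalTable) -> float:
    """Model-level likelihood-ratio p-value of a Cox proportional-hazards
    fit with k-1 subtype-indicator covariates.

    Returns NaN (with a warning) instead of raising when the fit cannot
    converge, e.g. under complete separation.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != len(surv.sample_ids):
        raise ValidationError("labels and survival table must cover the same samples")
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValidationError("Cox p-value needs at least 2 subtypes")
    df = pd.DataFrame({"time": surv.time, "event": surv.event})
    for g in groups[1:]:  # first group is the reference
        df[f"g{g}"] = (labels == g).astype(float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
            return float(cph.log_likelihood_ratio_test().p_value)
    except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
        warnings.warn(f"Cox model did not converge: {exc}")
        return float("nan")


def km_curves(labels, surv: SurvivalTable) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve per subtype.

    Returns a tidy frame (cluster, time, survival); each curve starts at
    probability 1 and is non-increasing.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != len(surv.sample_ids):
        raise ValidationError("labels and survival table must cover the same samples")
    rows = []
    kmf = KaplanMeierFitter()
    for g in np.unique(labels):
        sel = labels == g
        kmf.fit(surv.time[sel], surv.event[sel])
        sf = kmf.survival_function_
        for t, p in zip(sf.index.to_numpy(), sf.iloc[:, 0].to_numpy()):
            rows.append({"cluster": int(g), "time": float(t), "survival": float(p)})
    return pd.DataFrame(rows, columns=["cluster", "time", "survival"])


def agreement_tables(results: list[SubtypingResult]) -> pd.DataFrame:
    """Cross-method agreement: for each k with >= 2 methods, the mean NMI
    and mean ARI of each method's labels against every other method's."""
    by_k: dict[int, list[SubtypingResult]] = {}
    for r in results:
        by_k.setdefault(r.k, []).append(r)
    rows = []
    for k in sorted(by_k):
        group = by_k[k]
        if len(group) < 2:
            continue
        for r in group:
            others = [o for o in group if o is not r]
            rows.append(
                {
                    "method": r.method_name,
                    "k": k,
                    "mean_nmi": float(np.mean([nmi(r.labels, o.labels) for o in others])),
                    "mean_ari": float(np.mean([ari(r.labels, o.labels) for o in others])),
                }
            )
    return pd.DataFrame(rows, columns=["method", "k", "mean_nmi", "mean_ari"])


def result_distance(
    result: SubtypingResult, layers: list[OmicsLayer] | None = None
) -> np.ndarray | None:
    """Patient-patient distance matrix for silhouette/heatmap use.

    Derived from the result's integrated matrix when present (features ->
    Euclidean distances; distance -> as-is; similarity S -> max(S) - S
    with the diagonal re-zeroed), else Euclidean distance on the stacked
    z-scored layers; None (with a warning) when nothing is available.
    """
    if result.integrated_matrix is not None:
        M = result.integrated_matrix
        if result.matrix_kind == "distance":
            return M.copy()
        if result.matrix_kind == "similarity":
            D = M.max() - M
            np.fill_diagonal(D, 0.0)
            return D
        return squareform(pdist(M))  # features
    if layers:
        X = _stack_layers(layers, zscore=True)
        return squareform(pdist(X))
    warnings.warn(
        f"{result.method_name} k={result.k}: no integrated matrix or layers; "
        "silhouette/heatmap skipped"
    )
    return None
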