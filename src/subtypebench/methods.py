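"""Pluggable subtyping methods and the (method x k) run grid.

A subtyping method is any callable ``runner(layers, k, seed) ->
SubtypingResult``.  The platform runs every registered method for every
candidate number of subtypes k in 2..k_max, records wall-clock time per
cell, and degrades gracefully when a single cell fails.

Two baseline integrators are built in:

``concat``
    z-scores each layer feature-wise, stacks all features and runs
    best-of-300-restarts k-means — the simplest early-integration
    strategy.
``simfuse``
    builds a Gaussian-kernel patient-similarity matrix per layer,
    averages them and spectral-clusters the fused similarity — a
    late-integration strategy in the spirit of similarity-network
    approaches.
"""

from __future__ import annotations

import hashlib
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans, SpectralClustering

from .layers import OmicsLayer, ValidationError
from .preprocess import zscore_rows

__all__ = [
    "SubtypingResult",
    "MethodSpec",
    "EVCurve",
    "BUILTIN_METHODS",
    "kmeans_stable",
    "baseline_concat",
    "baseline_simfuse",
    "run_grid",
    "low_rank_ev",
    "load_user_result",
    "load_user_results_wide",
]

MATRIX_KINDS = ("similarity", "distance", "features")


@dataclass
class SubtypingResult:
    """Labels from one (method, k) run, plus the integrated matrix.

    ``labels`` are cluster ids in 1..k, one per sample in ``sample_ids``
    order.  ``integrated_matrix`` (optional) is either a patient-patient
    similarity, a patient-patient distance, or a patient-feature matrix,
    tagged by ``matrix_kind``.
    """

    method_name: str
    k: int
    sample_ids: list[str]
    labels: np.ndarray
    integrated_matrix: Optional[np.ndarray] = field(default=None, repr=False)
    matrix_kind: Optional[str] = None
    runtime_seconds: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.sample_ids)
        if self.labels.shape != (n,):
            raise ValidationError(
                f"{self.method_name} k={self.k}: {self.labels.shape[0] if self.labels.ndim else 0} "
                f"labels for {n} samples"
            )
        present = set(np.unique(self.labels))
        if not present <= set(range(1, self.k + 1)):
            raise ValidationError(
                f"{self.method_name} k={self.k}: labels outside 1..k: {sorted(present)}"
            )
        if self.runtime_seconds < 0:
            raise ValidationError("runtime_seconds must be non-negative")
        if self.integrated_matrix is not None:
            self._validate_matrix()

    def _validate_matrix(self) -> None:
        M = np.asarray(self.integrated_matrix, dtype=float)
        self.integrated_matrix = M
        if self.matrix_kind not in MATRIX_KINDS:
            raise ValidationError(
                f"matrix_kind must be one of {MATRIX_KINDS}, got {self.matrix_kind!r}"
            )
        n = len(self.sample_ids)
        if self.matrix_kind in ("similarity", "distance"):
            if M.shape != (n, n):
                raise ValidationError(
                    f"{self.matrix_kind} matrix must be {n}x{n}, got {M.shape}"
                )
            if not np.allclose(M, M.T, atol=1e-8):
                raise ValidationError(f"{self.matrix_kind} matrix must be symmetric")
            if (M < 0).any():
                raise ValidationError(f"{self.matrix_kind} matrix must be non-negative")
            if self.matrix_kind == "distance" and not np.allclose(np.diag(M), 0):
                raise ValidationError("distance matrix must have a zero diagonal")
        else:  # features
            if M.shape[0] != n:
                raise ValidationError(
                    f"feature matrix must have {n} sample rows, got {M.shape[0]}"
                )


@dataclass(frozen=True)
class MethodSpec:
    """A named subtyping method: ``runner(layers, k, seed) -> SubtypingResult``."""

    name: str
    runner: Callable[[list[OmicsLayer], int, int], SubtypingResult]


@dataclass
class EVCurve:
    """Explained variance at candidate reduced dimensions 1..n.

    ``ev[d-1]`` is the cumulative fraction of variance captured by the
    leading d dimensions; the sequence is non-decreasing in [0, 1].
    """

    dims: np.ndarray
    ev: np.ndarray

    def __post_init__(self) -> None:
        self.dims = np.asarray(self.dims, dtype=int)
        self.ev = np.asarray(self.ev, dtype=float)
        if self.dims.shape != self.ev.shape or self.dims.ndim != 1:
            raise ValidationError("dims and ev must be equal-length vectors")
        if len(self.dims) < 3:
            raise ValidationError("an EV curve needs at least 3 points")
        if np.any(np.diff(self.ev) < -1e-9):
            raise ValidationError("ev must be non-decreasing in the dimension")
        if self.ev.min() < -1e-9 or self.ev.max() > 1 + 1e-9:
            raise ValidationError("ev values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.dims)


def derive_seed(seed: int, *parts) -> int:
    """Stable per-cell seed below 2**31, derived from (seed, *parts)."""
    key = ":".join([str(seed), *map(str, parts)]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31 - 1)


def _stack_layers(layers: list[OmicsLayer], zscore: bool = True) -> np.ndarray:
    """Samples x features matrix of all layers, optionally z-scored per feature."""
    if not layers:
        raise ValidationError("no layers given")
    ids = layers[0].sample_ids
    for layer in layers[1:]:
        if layer.sample_ids != ids:
            raise ValidationError("layers are not sample-aligned; intersect first")
    blocks = []
    for layer in layers:
        if np.isnan(layer.values).any():
            raise ValidationError(f"layer {layer.name!r} has missing entries")
        X = zscore_rows(layer.values) if zscore else layer.values
        blocks.append(X.T)
    return np.hstack(blocks)


def kmeans_stable(
    points: np.ndarray, k: int, restarts: int = 300, seed: int = 0
) -> np.ndarray:
    """Best-of-``restarts`` k-means labels (1..k) on a samples x features matrix.

    Runs k-means from ``restarts`` seeded random initializations and
    keeps the labelling with the lowest within-cluster sum of squares,
    which is what makes the result stable across calls.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if k > n:
        raise ValidationError(f"k={k} exceeds n_samples={n}")
    if np.isnan(points).any():
        raise ValidationError("kmeans_stable requires a NaN-free matrix")
    if k == 1:
        return np.ones(n, dtype=int)
    km = KMeans(
        n_clusters=k, init="random", n_init=restarts, max_iter=300,
        random_state=seed % (2**32),
    )
    return km.fit_predict(points) + 1


def baseline_concat(layers: list[OmicsLayer], k: int, seed: int) -> SubtypingResult:
    """Early-integration baseline: stack z-scored layers, k-means."""
    t0 = time.perf_counter()
    X = _stack_layers(layers, zscore=True)
    labels = kmeans_stable(X, k, seed=seed)
    return SubtypingResult(
        method_name="concat",
        k=k,
        sample_ids=layers[0].sample_ids,
        labels=labels,
        integrated_matrix=X,
        matrix_kind="features",
        runtime_seconds=time.perf_counter() - t0,
    )


def gaussian_similarity(X: np.ndarray) -> np.ndarray:
    """exp(-d^2 / (2 sigma^2)) with sigma = median nonzero pairwise distance."""
    d = squareform(pdist(X))
    nz = d[d > 0]
    sigma = np.median(nz) if nz.size else 1.0
    return np.exp(-(d**2) / (2.0 * sigma**2))


def baseline_simfuse(layers: list[OmicsLayer], k: int, seed: int) -> SubtypingResult:
    """Late-integration baseline: average per-layer Gaussian similarities,
    then spectral clustering on the fused patient-similarity matrix."""
    t0 = time.perf_counter()
    n = layers[0].n_samples
    if n < k:
        raise ValidationError(f"k={k} exceeds n_samples={n}")
    sims = []
    for layer in layers:
        if np.isnan(layer.values).any():
            raise ValidationError(f"layer {layer.name!r} has missing entries")
        sims.append(gaussian_similarity(layer.values.T))
    S = np.mean(sims, axis=0)
    S = (S + S.T) / 2.0
    sc = SpectralClustering(
        n_clusters=k, affinity="precomputed", random_state=seed % (2**32),
        assign_labels="kmeans", n_init=30,
    )
    labels = sc.fit_predict(S) + 1
    return SubtypingResult(
        method_name="simfuse",
        k=k,
        sample_ids=layers[0].sample_ids,
        labels=labels,
        integrated_matrix=S,
        matrix_kind="similarity",
        runtime_seconds=time.perf_counter() - t0,
    )


BUILTIN_METHODS: dict[str, MethodSpec] = {
    "concat": MethodSpec("concat", baseline_concat),
    "simfuse": MethodSpec("simfuse", baseline_simfuse),
}


def run_grid(
    methods: list[MethodSpec],
    layers: list[OmicsLayer],
    k_max: int,
    seed: int,
) -> tuple[list[SubtypingResult], list[tuple[str, int, str]]]:
    """Run every method for every k in 2..k_max.

    Returns ``(results, failed_cells)`` where ``failed_cells`` lists
    ``(method, k, reason)`` for runners that raised; together they cover
    all ``p * (k_max - 1)`` grid cells.  Per-cell seeds are derived
    deterministically from ``(seed, method, k)``.
    """
    if k_max < 2:
        raise ValidationError("k_max must be >= 2")
    if not methods:
        raise ValidationError("at least one method is required")
    names = [m.name for m in methods]
    if len(set(names)) != len(names):
        raise ValidationError(f"method names must be unique: {names}")
    results: list[SubtypingResult] = []
    failed: list[tuple[str, int, str]] = []
    for m in methods:
        for k in range(2, k_max + 1):
            cell_seed = derive_seed(seed, m.name, k)
            t0 = time.perf_counter()
            try:
                res = m.runner(layers, k, cell_seed)
            except Exception as exc:  # a bad method must not sink the grid
                warnings.warn(f"method {m.name!r} failed at k={k}: {exc}")
                failed.append((m.name, k, str(exc)))
                continue
            if res.runtime_seconds == 0.0:
                res.runtime_seconds = time.perf_counter() - t0
            res.method_name = m.name
            results.append(res)
    if not results:
        raise ValidationError("every (method, k) cell failed")
    return results, failed


def low_rank_ev(layers: list[OmicsLayer], n_dims: int = 10) -> EVCurve:
    """Explained-variance curve of a low-rank embedding of the cohort.

    Stacks z-scored layers into one samples x features matrix, computes
    its singular values, and reports the cumulative squared-singular-value
    fraction at each candidate dimension 1..n_dims.
    """
    X = _stack_layers(layers, zscore=True)
    max_dims = min(X.shape)
    if n_dims < 3 or n_dims > max_dims:
        raise ValidationError(
            f"n_dims must be in [3, {max_dims}] for a {X.shape} matrix"
        )
    s = np.linalg.svd(X, compute_uv=False)
    total = float((s**2).sum())
    if total == 0:
        raise ValidationError("degenerate all-zero matrix has no EV curve")
    ev = np.cumsum(s**2) / total
    return EVCurve(dims=np.arange(1, n_dims + 1), ev=ev[:n_dims])


def _read_two_col_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected at least 2 columns (sample, label)")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].astype(str))


def _load_user_matrix(
    matrix_path: str | Path, sample_ids: list[str]
) -> np.ndarray:
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    missing = [s for s in sample_ids if s not in df.index]
    if missing:
        raise ValidationError(f"{matrix_path}: matrix lacks samples {missing[:5]}")
    return df.loc[sample_ids, sample_ids].to_numpy(dtype=float)


def load_user_result(
    labels_path: str | Path,
    sample_ids: list[str],
    method_name: str = "user",
    matrix_path: str | Path | None = None,
    kind: str | None = None,
) -> SubtypingResult:
    """Load a user-supplied subtyping result for the cohort.

    ``labels_path`` is a 2-column TSV (sample, label) covering every
    cohort sample; an optional integrated matrix (square similarity/
    distance with matching sample ids, or sample x feature) enables the
    silhouette and heatmap sections of the report.
    """
    ser = _read_two_col_labels(labels_path)
    missing = [s for s in sample_ids if s not in ser.index]
    if missing:
        raise ValidationError(
            f"{labels_path}: no label for cohort sample(s) {missing[:5]}"
        )
    unknown = [s for s in ser.index if s not in set(sample_ids)]
    if unknown:
        raise ValidationError(
            f"{labels_path}: label(s) for unknown sample(s) {unknown[:5]}"
        )
    raw = ser.loc[sample_ids].to_numpy()
    _, labels = np.unique(raw, return_inverse=True)
    labels = labels + 1
    k = int(labels.max())
    matrix = None
    if matrix_path is not None:
        if kind not in MATRIX_KINDS:
            raise ValidationError(
                f"matrix kind must be one of {MATRIX_KINDS}, got {kind!r}"
            )
        if kind == "features":
            df = pd.read_csv(matrix_path, sep="\t", index_col=0)
            df.index = df.index.astype(str)
            missing = [s for s in sample_ids if s not in df.index]
            if missing:
                raise ValidationError(
                    f"{matrix_path}: matrix lacks samples {missing[:5]}"
                )
            matrix = df.loc[sample_ids].to_numpy(dtype=float)
        else:
            matrix = _load_user_matrix(matrix_path, sample_ids)
    return SubtypingResult(
        method_name=method_name,
        k=k,
        sample_ids=list(sample_ids),
        labels=labels,
        integrated_matrix=matrix,
        matrix_kind=kind if matrix is not None else None,
        runtime_seconds=0.0,
    )


def load_user_results_wide(
    path: str | Path,
    sample_ids: list[str],
    method_name: str = "user",
) -> list[SubtypingResult]:
    """Load a wide TSV (sample, k2, k3, ...) into one result per k column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    missing = [s for s in sample_ids if s not in df.index]
    if missing:
        raise ValidationError(f"{path}: no labels for sample(s) {missing[:5]}")
    out = []
    for col in df.columns:
        raw = df.loc[sample_ids, col].to_numpy()
        _, labels = np.unique(raw, return_inverse=True)
        out.append(
            SubtypingResult(
                method_name=method_name,
                k=int(labels.max() + 1),
                sample_ids=list(sample_ids),
                labels=labels + 1,
            )
        )
    return out
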