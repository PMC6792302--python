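"""Vote-based consensus across all (method, k) runs, and best-method
selection by weighted z-scores.

Every run contributes a binary co-membership matrix M(t) (1 when two
patients share a cluster).  Summing over all runs gives an integer vote
matrix whose entries count how often each patient pair co-clustered —
a robust pairwise-similarity prediction that pools every method and
every candidate k.  Hierarchical clustering of the normalized vote
matrix yields the consensus subtyping and the leaf order used for
heatmap display.

When true labels are available, methods are ranked by a performance
score that weighs the clinical half (z-scored -log10 Cox p-value) and
the clustering half (mean of z-scored NMI, ARI and silhouette) equally:

    score(i) = alpha * z_cox(i) + (beta / 3) * (z_nmi + z_ari + z_sc)

with alpha = beta = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .layers import ValidationError
from .methods import SubtypingResult
from .metrics import silhouette

__all__ = [
    "ConsensusMatrix",
    "ConsensusClustering",
    "comembership",
    "overall_consensus",
    "consensus_cluster",
    "zscore_metric",
    "performance_score",
]


@dataclass
class ConsensusMatrix:
    """Integer co-clustering vote matrix over ``n_runs`` runs."""

    sample_ids: list[str]
    votes: np.ndarray = field(repr=False)
    n_runs: int = 0

    def __post_init__(self) -> None:
        self.votes = np.asarray(self.votes, dtype=int)
        n = len(self.sample_ids)
        if self.votes.shape != (n, n):
            raise ValidationError(f"votes must be {n}x{n}, got {self.votes.shape}")
        if not np.array_equal(self.votes, self.votes.T):
            raise ValidationError("vote matrix must be symmetric")
        if self.votes.min() < 0 or self.votes.max() > self.n_runs:
            raise ValidationError("votes must lie in [0, n_runs]")
        if not np.array_equal(np.diag(self.votes), np.full(n, self.n_runs)):
            raise ValidationError("vote diagonal must equal n_runs")


@dataclass
class ConsensusClustering:
    """Consensus labels plus the dendrogram leaf order for heatmaps."""

    labels: np.ndarray
    leaf_order: np.ndarray
    k: int


def comembership(result: SubtypingResult) -> np.ndarray:
    """Binary co-membership matrix M(t); diagonal 1 (a sample trivially
    shares its own cluster)."""
    lab = result.labels
    return (lab[:, None] == lab[None, :]).astype(int)


def overall_consensus(results: list[SubtypingResult]) -> ConsensusMatrix:
    """Sum the co-membership matrices of all runs into one vote matrix.

    Failed grid cells simply do not appear in ``results``, so ``n_runs``
    shrinks accordingly and ``votes / n_runs`` stays a valid
    co-clustering frequency.
    """
    if not results:
        raise ValidationError("need at least one run for a consensus")
    ids = results[0].sample_ids
    for r in results[1:]:
        if r.sample_ids != ids:
            raise ValidationError(
                f"{r.method_name} k={r.k}: sample set differs from the first run"
            )
    votes = np.zeros((len(ids), len(ids)), dtype=int)
    for r in results:
        votes += comembership(r)
    return ConsensusMatrix(sample_ids=list(ids), votes=votes, n_runs=len(results))


def consensus_cluster(
    cm: ConsensusMatrix,
    k: int | None = None,
    k_max: int = 5,
    k_select: str = "gap",
) -> ConsensusClustering:
    """Average-linkage hierarchical clustering of the consensus matrix.

    The dissimilarity between two patients is 1 minus their co-clustering
    frequency.  With ``k`` given the tree is cut to k clusters; otherwise
    k in 2..k_max is picked automatically:

    ``k_select="gap"`` (default) cuts where the dendrogram's merge
    heights jump the most — on vote matrices whose finer cuts reflect the
    grid's large-k runs this tracks the dominant block structure.
    ``k_select="silhouette"`` maximizes the silhouette coefficient on the
    consensus dissimilarity instead; on near-binary consensus distances
    it tends to reward over-split partitions (tight sub-blocks get
    a(i) = 0), which is why it is not the default.
    """
    n = len(cm.sample_ids)
    if n < 2:
        raise ValidationError("consensus clustering needs at least 2 samples")
    D = 1.0 - cm.votes / cm.n_runs
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    order = leaves_list(Z)
    if k is not None:
        labels = fcluster(Z, t=k, criterion="maxclust")
        chosen = k
    elif k_select == "gap":
        heights = Z[:, 2]  # ascending merge heights; cutting to k drops the top k-1
        best_gap, chosen = -np.inf, None
        for kk in range(2, min(k_max, n - 1) + 1):
            gap = heights[n - kk] - heights[n - kk - 1]
            if gap > best_gap:  # strict: ties go to the smallest k
                best_gap, chosen = gap, kk
        labels = fcluster(Z, t=chosen, criterion="maxclust")
    elif k_select == "silhouette":
        best_sc, chosen, labels = -np.inf, None, None
        for kk in range(2, min(k_max, n - 1) + 1):
            cand = fcluster(Z, t=kk, criterion="maxclust")
            if len(np.unique(cand)) < 2:
                continue
            sc = silhouette(cand, D)
            if sc > best_sc:
                best_sc, chosen, labels = sc, kk, cand
        if labels is None:
            raise ValidationError("no valid consensus cut in 2..k_max")
    else:
        raise ValidationError(f"unknown k_select {k_select!r}")
    _, enc = np.unique(labels, return_inverse=True)
    return ConsensusClustering(labels=enc + 1, leaf_order=order, k=int(chosen))


def zscore_metric(values, cox_p: bool = False) -> np.ndarray:
    """Standardize one metric across methods (population SD).

    Cox p-values are transformed to -log10 p first so that larger is
    better for every metric.  A zero-spread metric carries no
    discriminating information and maps to all-zero z-scores.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("z-scores need at least 2 methods")
    if cox_p:
        # clip so an (effectively) zero p-value keeps the transform finite
        x = -np.log10(np.clip(x, 1e-300, None))
    if np.ptp(x) == 0:  # no spread at all: no discriminating information
        return np.zeros_like(x)
    mu, sd = x.mean(), x.std()
    return (x - mu) / sd


def performance_score(
    table: pd.DataFrame,
    k: int,
    alpha: float = 0.5,
    beta: float = 0.5,
) -> pd.DataFrame:
    """Score each method at the given k and flag the best one.

    ``table`` needs columns method, k, cox_p, nmi, ari, sc (NMI/ARI
    against the true labels).  Methods missing any of the four metrics at
    k are excluded with a warning.  Ties break toward the smaller Cox
    p-value, then the lexicographically smaller name.
    """
    rows = table[table["k"] == k].copy()
    if rows.empty:
        raise ValidationError(f"no results at k={k}")
    needed = ["cox_p", "nmi", "ari", "sc"]
    complete = rows.dropna(subset=needed)
    dropped = sorted(set(rows["method"]) - set(complete["method"]))
    if dropped:
        import warnings

        warnings.warn(f"methods missing metrics at k={k}, excluded: {dropped}")
    if len(complete) < 2:
        raise ValidationError(f"need >= 2 fully scored methods at k={k}")
    complete = complete.sort_values("method").reset_index(drop=True)
    z_cox = zscore_metric(complete["cox_p"].to_numpy(), cox_p=True)
    z_nmi = zscore_metric(complete["nmi"].to_numpy())
    z_ari = zscore_metric(complete["ari"].to_numpy())
    z_sc = zscore_metric(complete["sc"].to_numpy())
    score = alpha * z_cox + (beta / 3.0) * (z_nmi + z_ari + z_sc)
    out = pd.DataFrame(
        {
            "method": complete["method"],
            "k": k,
            "z_cox": z_cox,
            "z_nmi": z_nmi,
            "z_ari": z_ari,
            "z_sc": z_sc,
            "score": score,
        }
    )
    ranked = out.assign(cox_p=complete["cox_p"].to_numpy()).sort_values(
        ["score", "cox_p", "method"], ascending=[False, True, True]
    )
    best = ranked.iloc[0]["method"]
    out["is_best"] = out["method"] == best
    return out
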