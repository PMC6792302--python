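"""Preprocessing: sample alignment, missingness filtering, imputation,
normalization and feature selection.

The default parameters mirror common practice for multi-omics subtyping
cohorts: drop features, then patients, with more than 20% missing values;
impute the rest by k-nearest-neighbour averaging in feature space;
z-score each feature; keep the top 10% of features by median absolute
deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .layers import OmicsLayer, ValidationError

__all__ = [
    "PreprocessConfig",
    "intersect_samples",
    "filter_missing",
    "impute",
    "normalize",
    "select_features",
    "preprocess_layer",
]

_IMPUTE_METHODS = ("mean", "median", "knn")
_NORMALIZE_METHODS = ("zscore", "log", "minmax", "quantile")
_SELECT_METHODS = ("variance", "mad", "pca")


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs for the preprocessing pipeline.

    ``feature_missing_max`` / ``sample_missing_max`` are the tolerated
    missing-value fractions (features are filtered first, then samples);
    ``feature_select_fraction`` is the fraction of features kept.
    """

    feature_missing_max: float = 0.20
    sample_missing_max: float = 0.20
    impute_method: str = "knn"
    knn_k: int = 10
    normalize_method: str = "zscore"
    feature_select_method: str = "mad"
    feature_select_fraction: float = 0.10

    def validate(self) -> None:
        for name in ("feature_missing_max", "sample_missing_max",
                     "feature_select_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if self.impute_method not in _IMPUTE_METHODS:
            raise ValidationError(f"impute_method must be one of {_IMPUTE_METHODS}")
        if self.normalize_method not in _NORMALIZE_METHODS:
            raise ValidationError(
                f"normalize_method must be one of {_NORMALIZE_METHODS}"
            )
        if self.feature_select_method not in _SELECT_METHODS:
            raise ValidationError(
                f"feature_select_method must be one of {_SELECT_METHODS}"
            )
        if self.knn_k < 1:
            raise ValidationError("knn_k must be >= 1")


def intersect_samples(layers: list[OmicsLayer]) -> list[OmicsLayer]:
    """Restrict all layers to their common samples, in sorted order.

    The canonical order (lexicographic on sample id) is shared by every
    returned layer so downstream matrices align column-for-column.
    """
    if len(layers) < 2:
        raise ValidationError("need at least two layers to intersect")
    common = set(layers[0].sample_ids)
    for layer in layers[1:]:
        common &= set(layer.sample_ids)
    if not common:
        raise ValidationError("sample intersection across layers is empty")
    order = sorted(common)
    return [layer.subset_samples(order) for layer in layers]


def filter_missing(layer: OmicsLayer, cfg: PreprocessConfig) -> OmicsLayer:
    """Drop features, then samples, exceeding the missingness thresholds.

    Features with missing fraction > ``feature_missing_max`` are removed
    first; sample fractions are then recomputed over the surviving
    features and samples above ``sample_missing_max`` removed.  Survivor
    order is preserved.
    """
    cfg.validate()
    mask = np.isnan(layer.values)
    feat_frac = mask.mean(axis=1)
    keep_f = np.flatnonzero(feat_frac <= cfg.feature_missing_max)
    if keep_f.size == 0:
        raise ValidationError(
            f"layer {layer.name!r}: all features exceed the missingness threshold"
        )
    values = layer.values[keep_f, :]
    samp_frac = np.isnan(values).mean(axis=0)
    keep_s = np.flatnonzero(samp_frac <= cfg.sample_missing_max)
    if keep_s.size == 0:
        raise ValidationError(
            f"layer {layer.name!r}: all samples exceed the missingness threshold"
        )
    return replace(
        layer,
        feature_ids=[layer.feature_ids[i] for i in keep_f],
        sample_ids=[layer.sample_ids[j] for j in keep_s],
        values=values[:, keep_s].copy(),
    )


def _knn_impute(values: np.ndarray, k: int) -> np.ndarray:
    """Fill NaNs feature-wise from the k nearest features (Euclidean over
    co-observed samples), restricted to neighbours observed at the target
    sample; falls back to the feature mean when no neighbour qualifies."""
    X = values.copy()
    obs = ~np.isnan(X)
    A = np.where(obs, X, 0.0)
    B = A * A
    # squared distance over co-observed samples, via masked inner products
    d2 = B @ obs.T + obs @ B.T - 2.0 * (A @ A.T)
    np.clip(d2, 0.0, None, out=d2)
    counts = obs.astype(float) @ obs.T.astype(float)
    d2[counts == 0] = np.inf
    np.fill_diagonal(d2, np.inf)
    feat_mean = np.nanmean(values, axis=1)
    out = X
    miss_f, miss_s = np.nonzero(~obs)
    for f, s in zip(miss_f, miss_s):
        cand = np.flatnonzero(obs[:, s] & np.isfinite(d2[:, f]))
        if cand.size == 0:
            out[f, s] = feat_mean[f]
            continue
        nearest = cand[np.argsort(d2[cand, f], kind="stable")[:k]]
        out[f, s] = values[nearest, s].mean()
    return out


def impute(layer: OmicsLayer, cfg: PreprocessConfig) -> OmicsLayer:
    """Fill every missing entry by the configured strategy.

    ``mean`` / ``median`` use the per-feature statistic over observed
    entries; ``knn`` averages the entries of the ``knn_k`` features
    nearest to the target feature (Euclidean distance over samples where
    both features are observed), among neighbours observed at the target
    sample.
    """
    cfg.validate()
    mask = np.isnan(layer.values)
    if not mask.any():
        return layer.copy()
    all_missing = np.flatnonzero(mask.all(axis=1))
    if all_missing.size:
        names = [layer.feature_ids[i] for i in all_missing[:5]]
        raise ValidationError(
            f"layer {layer.name!r}: feature(s) with no observed values: {names}"
        )
    if cfg.impute_method == "knn":
        if layer.n_features < cfg.knn_k + 1:
            raise ValidationError(
                f"knn imputation needs at least knn_k+1={cfg.knn_k + 1} features"
            )
        values = _knn_impute(layer.values, cfg.knn_k)
    else:
        stat = np.nanmean if cfg.impute_method == "mean" else np.nanmedian
        fill = stat(layer.values, axis=1)
        values = np.where(mask, fill[:, None], layer.values)
    return replace(layer, values=values)


def normalize(layer: OmicsLayer, cfg: PreprocessConfig) -> OmicsLayer:
    """Normalize each feature by the configured strategy.

    zscore: (x - mean) / population SD, constant features map to zeros.
    log: ln(1 + x), requiring all values > -1.
    minmax: per-feature rescale to [0, 1], constant features map to 0.5.
    quantile: ranks mapped to (rank - 0.5) / n (average ranks on ties).
    """
    cfg.validate()
    X = layer.values
    if np.isnan(X).any():
        raise ValidationError("normalize requires an imputed (NaN-free) layer")
    if cfg.normalize_method == "zscore":
        values = zscore_rows(X)
    elif cfg.normalize_method == "log":
        if (X <= -1).any():
            raise ValidationError("log normalization requires all values > -1")
        values = np.log1p(X)
    elif cfg.normalize_method == "minmax":
        lo = X.min(axis=1, keepdims=True)
        rng_ = X.max(axis=1, keepdims=True) - lo
        const = rng_[:, 0] == 0
        safe = np.where(rng_ == 0, 1.0, rng_)
        values = (X - lo) / safe
        values[const, :] = 0.5
    else:  # quantile
        n = X.shape[1]
        values = (stats.rankdata(X, axis=1, method="average") - 0.5) / n
    return replace(layer, values=values)


def zscore_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise z-score with population SD; constant rows become zeros."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)  # population SD
    out = np.where(sd == 0, 0.0, (X - mu) / np.where(sd == 0, 1.0, sd))
    return out


def select_features(layer: OmicsLayer, cfg: PreprocessConfig) -> OmicsLayer:
    """Keep the top ``ceil(fraction * n_features)`` features.

    ``variance`` and ``mad`` rank features by the statistic (MAD =
    median |x - median(x)|), ties broken by original feature order, and
    keep the winners in their original order.  ``pca`` instead replaces
    the features with the leading principal-component scores.
    """
    cfg.validate()
    X = layer.values
    if np.isnan(X).any():
        raise ValidationError("select_features requires an imputed layer")
    m = math.ceil(cfg.feature_select_fraction * layer.n_features)
    if m == 0:
        raise ValidationError("feature_select_fraction yields zero features")
    if cfg.feature_select_method == "pca":
        m = min(m, layer.n_samples)
        pca = PCA(n_components=m, svd_solver="full")
        scores = pca.fit_transform(X.T)  # samples x components
        return replace(
            layer,
            feature_ids=[f"PC{i + 1}" for i in range(m)],
            values=scores.T.copy(),
        )
    if cfg.feature_select_method == "variance":
        stat = X.var(axis=1)
    else:  # mad
        med = np.median(X, axis=1, keepdims=True)
        stat = np.median(np.abs(X - med), axis=1)
    order = np.argsort(-stat, kind="stable")  # ties keep original order
    keep = np.sort(order[:m])
    return layer.subset_features(list(keep))


def preprocess_layer(layer: OmicsLayer, cfg: PreprocessConfig) -> OmicsLayer:
    """filter -> impute -> normalize -> select, the standard pipeline."""
    out = filter_missing(layer, cfg)
    out = impute(out, cfg)
    out = normalize(out, cfg)
    out = select_features(out, cfg)
    assert not np.isnan(out.values).any(), "missing entries leaked past impute"
    return out
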