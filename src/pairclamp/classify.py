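"""FS / non-FS classification: UMAP embedding, k-means, silhouette, labels.

The scaled feature matrix is reduced to two dimensions with UMAP
(4 neighbors, min_dist 0.2, Euclidean metric), partitioned with k-means
(k = 2 a priori) on the embedding coordinates, validated by silhouette
analysis, and the cluster with the smaller median raw AP half-width is
labelled fast-spiking.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples, silhouette_score

from ._stats import mann_whitney
from .exceptions import InvalidParameterError, MissingFeatureError
from .features import MANDATORY_FEATURES, FeatureMatrix

#: UMAP hyperparameters used throughout
N_NEIGHBORS = 4
MIN_DIST = 0.2
#: below this mean silhouette the two-cluster partition is flagged
SILHOUETTE_FLAG_THRESHOLD = 0.25


@dataclass
class EmbeddingResult:
    coords: np.ndarray  # (n_cells, 2)
    cell_ids: list[str]
    seed: int
    n_neighbors: int = N_NEIGHBORS
    min_dist: float = MIN_DIST
    metric: str = "euclidean"


@dataclass
class ClassificationResult:
    cell_ids: list[str]
    cluster: np.ndarray  # int per cell
    labels: Optional[list[str]] = None  # FS / nonFS per cell
    silhouette_mean: float = np.nan
    silhouette_per_cell: Optional[np.ndarray] = None
    cluster_halfwidth_medians: Optional[dict[int, float]] = None
    validated: bool = True
    coords: Optional[np.ndarray] = None


def embed(matrix: FeatureMatrix, seed: int = 42) -> EmbeddingResult:
    """2-D UMAP embedding of the scaled feature matrix (reproducible)."""
    import umap  # deferred: numba compilation is slow at import time

    X = matrix.scaled.to_numpy()
    if X.shape[0] < N_NEIGHBORS + 1:
        raise InvalidParameterError(
            f"need at least {N_NEIGHBORS + 1} cells for n_neighbors={N_NEIGHBORS}; "
            "reduce n_neighbors for smaller cohorts"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=N_NEIGHBORS,
            min_dist=MIN_DIST,
            metric="euclidean",
            random_state=seed,
        )
        coords = reducer.fit_transform(X)
    return EmbeddingResult(coords=np.asarray(coords), cell_ids=matrix.cell_ids, seed=seed)


def cluster(embedding: EmbeddingResult, k: int = 2, seed: int = 42) -> ClassificationResult:
    """k-means on the embedding coordinates with silhouette validation."""
    X = embedding.coords
    if X.shape[0] < k:
        raise InvalidParameterError(f"cannot form {k} clusters from {X.shape[0]} points")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assign = km.fit_predict(X)
    if len(np.unique(assign)) > 1 and X.shape[0] > k:
        sil_mean = float(silhouette_score(X, assign))
        sil_cells = silhouette_samples(X, assign)
    else:
        sil_mean, sil_cells = np.nan, None
    return ClassificationResult(
        cell_ids=embedding.cell_ids,
        cluster=assign,
        silhouette_mean=sil_mean,
        silhouette_per_cell=sil_cells,
        validated=bool(sil_mean >= SILHOUETTE_FLAG_THRESHOLD) if np.isfinite(sil_mean) else False,
        coords=X,
    )


def assign_labels(result: ClassificationResult, matrix: FeatureMatrix) -> ClassificationResult:
    """Label the cluster with the smaller median raw AP half-width as FS.

    Ties break on the larger median maximum upstroke velocity.
    """
    hw = matrix.raw["ap_halfwidth"].reindex(result.cell_ids).to_numpy()
    medians: dict[int, float] = {}
    upstrokes: dict[int, float] = {}
    for c in np.unique(result.cluster):
        c = int(c)
        sel = result.cluster == c
        vals = hw[sel]
        if np.all(np.isnan(vals)):
            raise MissingFeatureError(f"ap_halfwidth missing for every cell of cluster {c}")
        medians[c] = float(np.nanmedian(vals))
        upstrokes[c] = float(
            np.nanmedian(matrix.raw["max_upstroke"].reindex(result.cell_ids).to_numpy()[sel])
        )
    clusters = sorted(medians)
    if len(clusters) != 2:
        raise InvalidParameterError("FS/non-FS labelling requires exactly two clusters")
    a, b = clusters
    if medians[a] < medians[b]:
        fs_cluster = a
    elif medians[b] < medians[a]:
        fs_cluster = b
    else:  # tie on half-width: faster upstroke wins
        fs_cluster = a if upstrokes[a] >= upstrokes[b] else b
    result.labels = ["FS" if c == fs_cluster else "nonFS" for c in result.cluster]
    result.cluster_halfwidth_medians = medians
    return result


def classify_cohort(
    matrix: FeatureMatrix, embed_seed: int = 42, cluster_seed: int = 42
) -> tuple[EmbeddingResult, ClassificationResult]:
    """Full pipeline: embed, cluster (k = 2), label FS / non-FS."""
    emb = embed(matrix, seed=embed_seed)
    res = cluster(emb, k=2, seed=cluster_seed)
    return emb, assign_labels(res, matrix)


def silhouette_diagnostics(
    embedding: EmbeddingResult, k_range: Sequence[int] = (2, 3, 4, 5), seed: int = 42
) -> dict[int, float]:
    """Mean silhouettes for a range of k (diagnostic report only; k stays 2)."""
    out = {}
    for k in k_range:
        if embedding.coords.shape[0] <= k:
            continue
        assign = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(embedding.coords)
        out[k] = float(silhouette_score(embedding.coords, assign))
    return out


def compare_groups(
    matrix: FeatureMatrix,
    labels: Sequence[str],
    features: Sequence[str] = MANDATORY_FEATURES,
) -> pd.DataFrame:
    """Per-feature FS vs non-FS group statistics with Mann-Whitney p-values.

    Groups of size < 2 yield flagged (NaN) statistics rather than an error.
    """
    labels = np.asarray(list(labels))
    rows = []
    for feat in features:
        vals = matrix.raw[feat].to_numpy(dtype=float)
        row: dict = {"feature": feat}
        groups = {}
        for lab in ("FS", "nonFS"):
            v = vals[labels == lab]
            v = v[np.isfinite(v)]
            groups[lab] = v
            row[f"{lab}_n"] = len(v)
            row[f"{lab}_mean"] = float(v.mean()) if len(v) else np.nan
            row[f"{lab}_sd"] = float(v.std(ddof=1)) if len(v) > 1 else np.nan
        if len(groups["FS"]) >= 2 and len(groups["nonFS"]) >= 2:
            _, p = mann_whitney(groups["FS"], groups["nonFS"])
            row["p_value"] = p
        else:
            row["p_value"] = np.nan
            row["flag"] = "group_too_small"
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")
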