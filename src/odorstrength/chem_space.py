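"""Descriptor-space characterization.

PCA on standardized descriptors with a deterministic sign convention for the
loadings, top-loading reports per component, and the
unsupervised-clustering-versus-label agreement analysis (K-means, Gaussian
mixture, DBSCAN, spectral, agglomerative scored by ARI/NMI/AMI) that probes
whether odor-strength categories form clusters in feature space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN, AgglomerativeClustering, KMeans, SpectralClustering
from sklearn.decomposition import PCA
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    normalized_mutual_info_score,
)
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

from .featurize import FeatureMatrix

CLUSTER_ALGORITHMS = ("kmeans", "gmm", "dbscan", "spectral", "agglomerative")


@dataclass
class PcaResult:
    scores: np.ndarray  # (n, k)
    loadings: np.ndarray  # (d, k), orthonormal columns
    explained_variance_ratio: np.ndarray
    feature_names: list[str]
    dropped_zero_variance: list[str]


def pca(features: FeatureMatrix, k: int) -> PcaResult:
    """Standardized PCA, deterministic up to the fixed sign convention.

    Zero-variance columns are dropped (and reported) before standardization;
    each loading column's largest-magnitude entry is made positive.
    """
    X = features.values
    sd = X.std(axis=0)
    keep = sd > 0
    dropped = [n for n, k_ in zip(features.feature_names, keep) if not k_]
    names = [n for n, k_ in zip(features.feature_names, keep) if k_]
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    n, d = X.shape
    if not 1 <= k <= min(n - 1, d):
        raise ValueError(f"k must lie in [1, min(n-1, d)] = [1, {min(n - 1, d)}]")
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T.copy()
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PcaResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=model.explained_variance_ratio_,
        feature_names=names,
        dropped_zero_variance=dropped,
    )


def top_loadings(result: PcaResult, component: int, m: int) -> list[tuple[str, float]]:
    """m features with the largest absolute loading on a component; ties by name."""
    d = result.loadings.shape[0]
    if component >= result.loadings.shape[1]:
        raise ValueError("component out of range")
    if m > d:
        warnings.warn(f"m={m} clamped to {d} features")
        m = d
    col = result.loadings[:, component]
    order = sorted(range(d), key=lambda i: (-abs(col[i]), result.feature_names[i]))
    return [(result.feature_names[i], float(col[i])) for i in order[:m]]


def _dbscan_eps(X: np.ndarray) -> float:
    """Median distance to the 5th nearest neighbour — a scale-free density radius."""
    nn = NearestNeighbors(n_neighbors=min(6, len(X))).fit(X)
    dist, _ = nn.kneighbors(X)
    eps = float(np.median(dist[:, -1]))
    return eps if eps > 0 else 1.0


def clustering_agreement(
    features: FeatureMatrix,
    labels,
    algorithms=CLUSTER_ALGORITHMS,
    n_clusters: int = 4,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Fit unsupervised clusterings on features, score against ordinal labels.

    Partitional methods use ``n_clusters`` (default 4, matching the category
    count); DBSCAN's radius comes from the median 5th-neighbour distance.
    A single-cluster outcome is scored (ARI = 0 on mixed labels) and flagged.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("agreement needs at least two distinct labels")
    X = features.values
    sd = X.std(axis=0)
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    out = {}
    for name in algorithms:
        if name == "kmeans":
            part = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit_predict(X)
        elif name == "gmm":
            part = GaussianMixture(n_components=n_clusters, random_state=seed).fit_predict(X)
        elif name == "dbscan":
            part = DBSCAN(eps=_dbscan_eps(X), min_samples=5).fit_predict(X)
        elif name == "spectral":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                part = SpectralClustering(
                    n_clusters=n_clusters, random_state=seed, assign_labels="discretize"
                ).fit_predict(X)
        elif name == "agglomerative":
            part = AgglomerativeClustering(n_clusters=n_clusters).fit_predict(X)
        else:
            raise ValueError(f"unknown clustering algorithm {name!r}")
        out[name] = {
            "ari": float(adjusted_rand_score(labels, part)),
            "nmi": float(normalized_mutual_info_score(labels, part)),
            "ami": float(adjusted_mutual_info_score(labels, part)),
            "n_clusters_found": int(len(set(part.tolist()) - {-1})),
            "single_cluster": bool(len(set(part.tolist()) - {-1}) <= 1),
        }
    return out
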