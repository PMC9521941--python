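"""K-means, between-cluster scatter, and the centroid-subspace / PC-span link.

For samples x_j in R^N clustered into S clusters with centroids m_s and sizes
n_s, the within-cluster objective J_S = sum_s sum_{j in C_s} ||x_j - m_s||^2
and the between-cluster scatter trace Tr S_b = sum_s n_s ||m_s||^2 decompose
the total scatter: J_S + Tr S_b = sum_j ||x_j - xbar||^2 for centered data.
Writing the normalized cluster indicators h_s (entries 1/sqrt(n_s) on
members), S_b = X (sum_s h_s h_s^T) X^T, so Tr S_b = sum_s ||X h_s||^2 —
computable in the M-dimensional sample space without ever forming the N x N
scatter matrix.

At the K-means optimum the centroid subspace span{X h_s} (dimension S-1 for
centered data) approximately coincides with the span of the leading S-1 PC
score vectors u_1..u_{S-1} — the relaxation that lets an unsupervised SVD
stand in for an explicit clustering.  The agreement is measured by principal
angles between the two subspaces.

K-means itself is delegated to scikit-learn (Lloyd iterations, random
initial centroids, best of n_init restarts; empty clusters re-seeded by the
library's largest-distance rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import orth, subspace_angles
from sklearn.cluster import KMeans

from .containers import ExpressionMatrix

__all__ = [
    "ClusteringResult",
    "kmeans",
    "between_scatter_trace",
    "centroid_subspace_agreement",
    "total_scatter",
]


@dataclass(frozen=True)
class ClusteringResult:
    """Sample clustering with centroids and normalized indicator vectors."""

    assignments: np.ndarray  # cluster index per sample
    sizes: np.ndarray
    centroids: np.ndarray  # (N, S): centroid per cluster in feature space
    indicators: np.ndarray  # (M, S): h_s columns, entries 1/sqrt(n_s)
    objective: float  # J_S

    @property
    def n_clusters(self) -> int:
        return self.sizes.size


def kmeans(matrix: ExpressionMatrix, n_clusters: int, seed: int = 0, n_init: int = 10) -> ClusteringResult:
    """Cluster the samples (columns) of an expression matrix.

    Lloyd iterations from random initial centroids, best of ``n_init``
    seeded restarts.
    """
    m = matrix.n_samples
    if n_clusters > m:
        raise ValueError(f"cannot form {n_clusters} clusters from {m} samples")
    pts = matrix.values.T  # samples as rows
    km = KMeans(
        n_clusters=n_clusters,
        init="random",
        n_init=n_init,
        algorithm="lloyd",
        random_state=seed,
    ).fit(pts)
    labels = km.labels_
    sizes = np.bincount(labels, minlength=n_clusters)
    indicators = np.zeros((m, n_clusters))
    indicators[np.arange(m), labels] = 1.0 / np.sqrt(sizes[labels])
    centroids = km.cluster_centers_.T
    objective = float(((pts - km.cluster_centers_[labels]) ** 2).sum())
    return ClusteringResult(
        assignments=labels,
        sizes=sizes,
        centroids=centroids,
        indicators=indicators,
        objective=objective,
    )


def total_scatter(matrix: ExpressionMatrix) -> float:
    """Total scatter of samples about the grand mean, sum_j ||x_j - xbar||^2."""
    pts = matrix.values
    centered = pts - pts.mean(axis=1, keepdims=True)
    return float((centered**2).sum())


def between_scatter_trace(clustering: ClusteringResult, matrix: ExpressionMatrix) -> float:
    """Tr S_b = sum_s ||X h_s||^2, in the M-dimensional representation.

    Equals the centroid form sum_s n_s ||m_s||^2; never materializes the
    N x N scatter matrix.
    """
    if clustering.indicators.shape[0] != matrix.n_samples:
        raise ValueError("clustering does not match the matrix's samples")
    proj = matrix.values @ clustering.indicators  # (N, S), column s = sqrt(n_s) m_s
    return float((proj**2).sum())


def centroid_subspace_agreement(
    matrix: ExpressionMatrix,
    n_clusters: int,
    seed: int = 0,
    n_init: int = 10,
) -> np.ndarray:
    """Principal angles (radians) between centroid subspace and leading PC span.

    The matrix columns are centered about the grand mean; K-means with
    ``n_clusters`` clusters is run on the samples and span{X h_s} (dimension
    at most S-1 after centering) is compared against span{u_1..u_{S-1}} of
    the centered matrix's SVD.  Returns the angles in descending order.
    """
    if n_clusters < 2:
        raise ValueError("need at least two clusters")
    centered = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    cm = ExpressionMatrix(centered, matrix.feature_ids, matrix.sample_ids)
    clustering = kmeans(cm, n_clusters, seed=seed, n_init=n_init)
    centroid_span = orth(cm.values @ clustering.indicators)
    if centroid_span.shape[1] == 0:
        raise ValueError("centroid subspace is degenerate (zero)")
    u, _, _ = np.linalg.svd(centered, full_matrices=False)
    pc_span = u[:, : n_clusters - 1]
    return np.sort(subspace_angles(centroid_span, pc_span))[::-1]
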