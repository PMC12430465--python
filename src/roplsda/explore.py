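"""Unsupervised exploration: PCA and Ward-linkage hierarchical clustering."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from .preprocess import FeatureTable


@dataclass
class PcaResult:
    scores: np.ndarray                    # samples x k
    loadings: np.ndarray                  # features x k
    explained_variance_fraction: np.ndarray  # per retained axis


@dataclass
class Dendrogram:
    merges: np.ndarray      # scipy linkage matrix (n-1 x 4)
    leaf_order: np.ndarray
    labels: np.ndarray      # cluster labels at the requested cut
    cut_k: int


def _as_matrix(table) -> np.ndarray:
    if isinstance(table, FeatureTable):
        return table.values
    return np.asarray(table, dtype=float)


def pca(table, k: int) -> PcaResult:
    """SVD-based PCA with a deterministic sign convention.

    Scores are centered; each loading vector's largest-magnitude entry is
    made positive so repeated runs produce identical output. Explained
    fractions are reported relative to the total variance.
    """
    X = _as_matrix(table)
    n, d = X.shape
    if not 1 <= k <= min(n - 1, d):
        raise ValueError(f"k={k} outside [1, min(n_samples-1, n_features)={min(n-1, d)}]")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s ** 2).sum())
    frac = (s ** 2) / total if total > 0 else np.zeros_like(s)
    loadings = Vt[:k].T.copy()
    scores = U[:, :k] * s[:k]
    for j in range(k):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PcaResult(scores=scores, loadings=loadings,
                     explained_variance_fraction=frac[:k])


def hca_ward(table, cut_k: int) -> Dendrogram:
    """Agglomerative Ward clustering on Euclidean distances, cut at cut_k."""
    X = _as_matrix(table)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not 1 <= cut_k <= n:
        raise ValueError(f"cut_k={cut_k} outside [1, {n}]")
    Z = linkage(pdist(X, metric="euclidean"), method="ward")
    labels = fcluster(Z, t=cut_k, criterion="maxclust")
    return Dendrogram(merges=Z, leaf_order=leaves_list(Z), labels=labels, cut_k=cut_k)


def dendrogram_newick(dendro: Dendrogram, leaf_names=None) -> str:
    """Render the merge tree as a Newick string with merge heights as lengths."""
    Z = dendro.merges
    n = Z.shape[0] + 1
    if leaf_names is None:
        leaf_names = [f"S{i}" for i in range(n)]
    height = {i: 0.0 for i in range(n)}
    node = {i: str(leaf_names[i]) for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = h - height[a]
        lb = h - height[b]
        node[n + k] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
        height[n + k] = h
    return node[n + Z.shape[0] - 1] + ";"
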