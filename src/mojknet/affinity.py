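"""Per-modality patient affinity graphs.

Pairwise patient similarity within one omics layer is measured with a
Gaussian kernel on squared euclidean distances, using a locally adaptive
bandwidth in the similarity-network-fusion lineage: for patients i and j,

    eps_ij = (mean_kNN_dist(i) + mean_kNN_dist(j) + d_ij) / 3
    s_ij   = exp(-d_ij / (2 * mu * eps_ij))

where ``mean_kNN_dist(i)`` is the mean distance from i to its k nearest
neighbors (self excluded), ``mu`` a scale parameter (default 0.5) and d the
squared euclidean distance. Local scaling keeps the kernel informative for
omics layers of very different dimensionality, where any single global
bandwidth either saturates or collapses the similarities.

The kernel matrix is then sparsified to a k-nearest-neighbor graph
(default k = 20): each row keeps its k strongest off-diagonal similarities
and the result is symmetrized by elementwise maximum so every retained
edge survives in both directions.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datatypes import AffinityGraph, OmicsMatrix

__all__ = [
    "pairwise_distance",
    "gaussian_affinity",
    "knn_sparsify",
    "build_affinity_graph",
    "write_graph",
]

_EPS_FLOOR = 1e-12  # bandwidth floor for degenerate all-identical inputs


def pairwise_distance(matrix: OmicsMatrix | np.ndarray, metric: str = "sqeuclidean") -> np.ndarray:
    """Symmetric pairwise patient distance matrix (zero diagonal).

    ``metric`` is ``"sqeuclidean"`` (default) or ``"euclidean"``. The input
    must contain no missing values.
    """
    X = matrix.values if isinstance(matrix, OmicsMatrix) else np.asarray(matrix, float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples for pairwise distances")
    if not np.isfinite(X).all():
        raise ValueError("input contains non-finite values; impute first")
    if metric not in ("sqeuclidean", "euclidean"):
        raise ValueError(f"unsupported metric {metric!r}")
    D = squareform(pdist(X, metric=metric))
    np.fill_diagonal(D, 0.0)
    return D


def _mean_knn_dist(distances: np.ndarray, k: int) -> np.ndarray:
    """Mean distance from each point to its k nearest neighbors (self excluded)."""
    n = distances.shape[0]
    D = distances.copy()
    np.fill_diagonal(D, np.inf)
    # stable partial sort: k smallest off-diagonal entries per row
    part = np.sort(D, axis=1)[:, :k]
    return part.mean(axis=1)


def gaussian_affinity(distances: np.ndarray, mu: float = 0.5, k: int = 20) -> np.ndarray:
    """Locally scaled Gaussian kernel on a distance matrix.

    Returns a symmetric matrix with entries in (0, 1] and unit diagonal.
    An epsilon floor guards the bandwidth when all points coincide.
    """
    n = distances.shape[0]
    if mu <= 0:
        raise ValueError("mu must be positive")
    if not (1 <= k < n):
        raise ValueError(f"k must satisfy 1 <= k < n (got k={k}, n={n})")
    mean_knn = _mean_knn_dist(distances, k)
    eps = (mean_knn[:, None] + mean_knn[None, :] + distances) / 3.0
    eps = np.maximum(eps, _EPS_FLOOR)
    S = np.exp(-distances / (2.0 * mu * eps))
    S = (S + S.T) / 2.0  # exact symmetry against float round-off
    np.fill_diagonal(S, 1.0)
    return S


def knn_sparsify(
    affinity: np.ndarray,
    k: int,
    sample_ids: list[str] | None = None,
    modality: str = "fused",
    warn_disconnected: bool = True,
) -> AffinityGraph:
    """Keep each row's k strongest off-diagonal similarities, then symmetrize.

    Symmetrization is by elementwise maximum with the transpose, so an edge
    retained from either endpoint survives. Ties in the top-k rank are
    broken by lower sample index for reproducibility. The diagonal is set
    to 1 (standalone affinity convention). A warning reports the component
    count if the resulting graph is disconnected.
    """
    A = np.asarray(affinity, dtype=np.float64)
    n = A.shape[0]
    if not (1 <= k < n):
        raise ValueError(f"k must satisfy 1 <= k < n (got k={k}, n={n})")
    off = A.copy()
    np.fill_diagonal(off, -np.inf)
    # argsort descending; stable so equal values keep lower index first
    order = np.argsort(-off, axis=1, kind="stable")
    keep = np.zeros_like(A, dtype=bool)
    rows = np.repeat(np.arange(n), k)
    keep[rows, order[:, :k].ravel()] = True
    W = np.where(keep, A, 0.0)
    W = np.maximum(W, W.T)
    np.fill_diagonal(W, 1.0)
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(n)]
    graph = AffinityGraph(sample_ids=ids, weights=W, k=k, modality=modality)
    if warn_disconnected:
        n_comp = graph.n_components()
        if n_comp > 1:
            warnings.warn(
                f"k-NN affinity graph ({modality}) has {n_comp} connected components",
                stacklevel=2,
            )
    return graph


def build_affinity_graph(
    matrix: OmicsMatrix, k: int = 20, mu: float = 0.5, metric: str = "sqeuclidean"
) -> AffinityGraph:
    """Distance -> locally scaled kernel -> k-NN sparsified patient graph."""
    D = pairwise_distance(matrix, metric=metric)
    S = gaussian_affinity(D, mu=mu, k=k)
    return knn_sparsify(
        S, k=k, sample_ids=list(matrix.sample_ids), modality=matrix.modality.value
    )


def write_graph(graph: AffinityGraph, path, fmt: str = "matrix", sep: str = "\t") -> None:
    """Serialize a graph as a dense delimited matrix or an edge list."""
    import pandas as pd

    if fmt == "matrix":
        pd.DataFrame(
            graph.weights, index=graph.sample_ids, columns=graph.sample_ids
        ).to_csv(path, sep=sep)
    elif fmt == "edgelist":
        rows = []
        n = graph.n
        for i in range(n):
            for j in range(i + 1, n):
                w = graph.weights[i, j]
                if w > 0:
                    rows.append((graph.sample_ids[i], graph.sample_ids[j], w))
        pd.DataFrame(rows, columns=["id_a", "id_b", "weight"]).to_csv(
            path, sep=sep, index=False
        )
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
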