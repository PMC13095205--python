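"""Similarity network fusion: merge per-omics patient graphs into a consensus.

Cross-diffusion in the classic SNF form. Each view v contributes

* a full kernel P(v): mass-preserving row normalization with diagonal 1/2,
  off-diagonal p_ij = w_ij / (2 * sum_{l != i} w_il)  (rows sum to 1);
* a local kernel S(v): w_ij / sum_{l in kNN(i)} w_il on the k-nearest-
  neighbor support of row i (self excluded), zero elsewhere.

At every iteration each view's status matrix is updated through its local
kernel with the average of the *other* views' status matrices,

    P(v)  <-  S(v) @ mean_{u != v} P(u) @ S(v)^T,

then symmetrized and row-renormalized. After ``t_max`` iterations (default
20, with a reported max-abs-change diagnostic in place of an early-stopping
rule) the fused consensus network is the view average of the status
matrices, symmetrized.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import AffinityGraph

__all__ = ["SNFState", "normalize_kernels", "snf_fuse", "fuse_graphs"]


@dataclass
class SNFState:
    """Carrier for the per-view status and local kernels during fusion."""

    status_matrices: list[np.ndarray]
    local_kernels: list[np.ndarray]
    sample_ids: list[str]
    k: int
    iteration: int = 0
    t_max: int = 20
    max_change: list[float] = field(default_factory=list)


def _full_kernel(W: np.ndarray) -> np.ndarray:
    """Mass-preserving row normalization: diag 1/2, off-diag rows sum to 1/2."""
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    rowsum = off.sum(axis=1)
    if (rowsum <= 0).any():
        warnings.warn("isolated node in affinity graph; epsilon-regularizing row",
                      stacklevel=3)
        off = off + np.where(rowsum <= 0, 1.0, 0.0)[:, None] * (np.ones((n, n)) - np.eye(n)) / max(n - 1, 1)
        rowsum = off.sum(axis=1)
    P = off / (2.0 * rowsum[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def _local_kernel(W: np.ndarray, k: int) -> np.ndarray:
    """Row-stochastic kernel restricted to each row's k strongest neighbors."""
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, -np.inf)
    order = np.argsort(-off, axis=1, kind="stable")
    S = np.zeros_like(W)
    for i in range(n):
        nbrs = order[i, :k]
        w = W[i, nbrs]
        total = w.sum()
        if total <= 0:
            S[i, nbrs] = 1.0 / k
        else:
            S[i, nbrs] = w / total
    return S


def normalize_kernels(graphs: list[AffinityGraph], k: int | None = None) -> SNFState:
    """Build the per-view full (P) and local (S) kernels from affinity graphs.

    All graphs must share sample ids and order. ``k`` defaults to the
    neighbor count stored on the first graph.
    """
    if len(graphs) < 2:
        raise ValueError("similarity network fusion needs at least 2 views")
    ids = list(graphs[0].sample_ids)
    for g in graphs[1:]:
        if list(g.sample_ids) != ids:
            raise ValueError("all views must share identical sample ids and order")
    if k is None:
        k = graphs[0].k
    n = len(ids)
    if not (1 <= k < n):
        raise ValueError(f"k must satisfy 1 <= k < n (got k={k}, n={n})")
    P = [_full_kernel(g.weights) for g in graphs]
    S = [_local_kernel(g.weights, k) for g in graphs]
    return SNFState(status_matrices=P, local_kernels=S, sample_ids=ids, k=k)


def snf_fuse(state: SNFState, t_max: int = 20) -> AffinityGraph:
    """Run cross-diffusion for ``t_max`` iterations and average the views.

    Raises on any non-finite entry, reporting the iteration index. The
    per-iteration max-abs change of the stacked status matrices is recorded
    on ``state.max_change`` as a convergence diagnostic.
    """
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    m = len(state.status_matrices)
    P = [p.copy() for p in state.status_matrices]
    S = state.local_kernels
    state.t_max = t_max
    for t in range(1, t_max + 1):
        prev = [p.copy() for p in P]
        total = np.sum(prev, axis=0)
        new = []
        for v in range(m):
            others = (total - prev[v]) / (m - 1)
            Pv = S[v] @ others @ S[v].T
            Pv = (Pv + Pv.T) / 2.0
            Pv = _full_kernel(Pv)
            if not np.isfinite(Pv).all():
                raise FloatingPointError(f"non-finite fusion state at iteration {t}")
            new.append(Pv)
        P = new
        state.max_change.append(
            float(max(np.abs(P[v] - prev[v]).max() for v in range(m)))
        )
        state.iteration = t
    fused = np.mean(P, axis=0)
    fused = (fused + fused.T) / 2.0
    state.status_matrices = P
    return AffinityGraph(
        sample_ids=list(state.sample_ids), weights=fused, k=state.k, modality="fused"
    )


def fuse_graphs(
    graphs: list[AffinityGraph], k: int | None = None, t_max: int = 20
) -> tuple[AffinityGraph, SNFState]:
    """Convenience wrapper: normalize then fuse; returns (fused, state)."""
    state = normalize_kernels(graphs, k=k)
    fused = snf_fuse(state, t_max=t_max)
    return fused, state
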