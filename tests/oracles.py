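"""Independent brute-force oracles for the test suite.

Everything here is written as plain double loops / direct transcriptions of
the defining formulas, deliberately ignoring vectorization, so that each
oracle is an independent route to the quantity the library computes.
"""
from __future__ import annotations

import numpy as np


def pairwise_sqeuclidean(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = sum((X[i, k] - X[j, k]) ** 2 for k in range(X.shape[1]))
    return D


def local_gaussian_kernel(D: np.ndarray, mu: float, k: int) -> np.ndarray:
    """exp(-d_ij / (2*mu*eps_ij)) with eps_ij = (knn_i + knn_j + d_ij)/3."""
    n = D.shape[0]
    mean_knn = np.zeros(n)
    for i in range(n):
        others = sorted(D[i, j] for j in range(n) if j != i)
        mean_knn[i] = sum(others[:k]) / k
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                S[i, j] = 1.0
            else:
                eps = (mean_knn[i] + mean_knn[j] + D[i, j]) / 3.0
                S[i, j] = np.exp(-D[i, j] / (2.0 * mu * max(eps, 1e-12)))
    return S


def topk_edges(A: np.ndarray, k: int) -> np.ndarray:
    """Keep each row's k largest off-diagonal entries, union with transpose."""
    n = A.shape[0]
    keep = np.zeros((n, n), dtype=bool)
    for i in range(n):
        vals = [(-A[i, j], j) for j in range(n) if j != i]
        vals.sort()  # descending by value, ties to lower index
        for _, j in vals[:k]:
            keep[i, j] = True
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if keep[i, j] or keep[j, i]:
                W[i, j] = A[i, j]
    for i in range(n):
        W[i, i] = 1.0
    return W


def snf_reference(weight_list: list[np.ndarray], k: int, t_max: int) -> np.ndarray:
    """Single-file loop transcription of the cross-diffusion recursion."""

    def full_norm(W):
        n = W.shape[0]
        P = np.zeros((n, n))
        for i in range(n):
            row = sum(W[i, l] for l in range(n) if l != i)
            for j in range(n):
                P[i, j] = 0.5 if i == j else W[i, j] / (2.0 * row)
        return P

    def local_norm(W):
        n = W.shape[0]
        S = np.zeros((n, n))
        for i in range(n):
            nbrs = sorted(((-W[i, j], j) for j in range(n) if j != i))[:k]
            total = sum(W[i, j] for _, j in nbrs)
            for _, j in nbrs:
                S[i, j] = W[i, j] / total
        return S

    m = len(weight_list)
    P = [full_norm(W) for W in weight_list]
    S = [local_norm(W) for W in weight_list]
    for _ in range(t_max):
        prev = [p.copy() for p in P]
        new = []
        for v in range(m):
            others = sum(prev[u] for u in range(m) if u != v) / (m - 1)
            Pv = S[v] @ others @ S[v].T
            Pv = (Pv + Pv.T) / 2.0
            new.append(full_norm(Pv))
        P = new
    fused = sum(P) / m
    return (fused + fused.T) / 2.0


def macro_from_labels(y, p, n_classes):
    precisions, recalls, f1s = [], [], []
    for c in range(n_classes):
        tp = sum(1 for a, b in zip(y, p) if a == c and b == c)
        fp = sum(1 for a, b in zip(y, p) if a != c and b == c)
        fn = sum(1 for a, b in zip(y, p) if a == c and b != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
    return (sum(precisions) / n_classes, sum(recalls) / n_classes,
            sum(f1s) / n_classes)


def km_curve(times, events):
    """Product-limit estimate over distinct event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    event_times = sorted(set(times[events == 1]))
    s = 1.0
    out_t, out_s = [0.0], [1.0]
    for t in event_times:
        at_risk = sum(1 for ti in times if ti >= t)
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        s *= 1.0 - d / at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def logrank_chi2(times1, events1, times2, events2):
    """Tabulate every event time's 2x2 table; chi2 = (O1-E1)^2/V1."""
    all_t = sorted(set(list(np.asarray(times1)[np.asarray(events1) == 1]) +
                       list(np.asarray(times2)[np.asarray(events2) == 1])))
    O1 = E1 = V1 = 0.0
    for t in all_t:
        n1 = sum(1 for ti in times1 if ti >= t)
        n2 = sum(1 for ti in times2 if ti >= t)
        d1 = sum(1 for ti, ei in zip(times1, events1) if ti == t and ei == 1)
        d2 = sum(1 for ti, ei in zip(times2, events2) if ti == t and ei == 1)
        n, d = n1 + n2, d1 + d2
        if n < 1:
            continue
        O1 += d1
        E1 += n1 * d / n
        if n > 1:
            V1 += n1 * n2 * d * (n - d) / (n**2 * (n - 1))
    return (O1 - E1) ** 2 / V1


def cindex_pairs(risk, times, events):
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


def normalized_adjacency_loop(A: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    At = A.copy()
    for i in range(n):
        At[i, i] = 0.0
    At = At + np.eye(n)
    d = At.sum(axis=1)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = At[i, j] / np.sqrt(d[i] * d[j])
    return out
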