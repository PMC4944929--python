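"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: betweenness by
explicit enumeration of all shortest paths, the map-equation optimum by
exhaustive enumeration of set partitions, modularity and the adjusted Rand
index by their textbook double sums.
"""

from __future__ import annotations

import heapq
from itertools import permutations

import numpy as np


def all_shortest_paths(weights: np.ndarray, lengths: np.ndarray, s: int):
    """Dijkstra from s returning, per target, the list of all geodesics."""
    n = weights.shape[0]
    dist = np.full(n, np.inf)
    dist[s] = 0.0
    preds = [[] for _ in range(n)]
    heap = [(0.0, s)]
    done = np.zeros(n, dtype=bool)
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        for v in range(n):
            if weights[u, v] <= 0:
                continue
            nd = d + lengths[u, v]
            if nd < dist[v] - 1e-12:
                dist[v] = nd
                preds[v] = [u]
                heapq.heappush(heap, (nd, v))
            elif abs(nd - dist[v]) <= 1e-12 and u not in preds[v]:
                preds[v].append(u)

    def unwind(t):
        if t == s:
            return [[s]]
        out = []
        for p in preds[t]:
            out.extend(path + [t] for path in unwind(p))
        return out

    return dist, [unwind(t) if np.isfinite(dist[t]) else [] for t in range(n)]


def brute_betweenness(weights: np.ndarray, use_weights: bool = False):
    """Unordered-pair nBC (endpoints excluded) and eBC by path enumeration."""
    n = weights.shape[0]
    lengths = np.where(weights > 0, 1.0 / weights if use_weights else 1.0,
                       np.inf)
    nbc = np.zeros(n)
    ebc = {}
    for s in range(n):
        _, paths_to = all_shortest_paths(weights, lengths, s)
        for t in range(s + 1, n):
            paths = paths_to[t]
            if not paths:
                continue
            credit = 1.0 / len(paths)
            for path in paths:
                for v in path[1:-1]:
                    nbc[v] += credit
                for a, b in zip(path[:-1], path[1:]):
                    e = (min(a, b), max(a, b))
                    ebc[e] = ebc.get(e, 0.0) + credit
    return nbc, ebc


def set_partitions(n: int):
    """All set partitions of range(n) as restricted-growth label lists."""
    def rec(s, m):
        if len(s) == n:
            yield list(s)
            return
        for v in range(m + 1):
            s.append(v)
            yield from rec(s, max(m, v + 1))
            s.pop()

    yield from rec([], 0)


def _plogp(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x * np.log2(np.maximum(x, 1e-300)), 0.0)


def exhaustive_min_codelength(weights: np.ndarray,
                              labels_matrix: np.ndarray) -> float:
    """Minimum two-level map-equation codelength over the given partitions.

    ``labels_matrix`` is (P, n) of labels 0..n-1 (all set partitions).
    Vectorized evaluation of L = plogp(q) − 2Σplogp(q_m) + Σplogp(p_m+q_m)
    − Σplogp(p_i) for every partition.
    """
    n = weights.shape[0]
    k = weights.sum(axis=1)
    total = k.sum()
    p = k / total
    onehot = labels_matrix[:, :, None] == np.arange(n)[None, None, :]  # P,n,M
    p_m = np.einsum("pnm,n->pm", onehot, p)
    k_m = np.einsum("pnm,n->pm", onehot, k)
    within = np.einsum("pim,pjm,ij->pm", onehot, onehot, weights)
    q_m = (k_m - within) / total
    q_tot = q_m.sum(axis=1)
    L = (
        _plogp(q_tot)
        - 2 * _plogp(q_m).sum(axis=1)
        + _plogp(p_m + q_m).sum(axis=1)
        - _plogp(p).sum()
    )
    return float(L.min())


def brute_modularity(weights: np.ndarray, labels: np.ndarray) -> float:
    """Q by the O(n²) double sum."""
    k = weights.sum(axis=1)
    two_w = k.sum()
    q = 0.0
    n = len(labels)
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += weights[i, j] - k[i] * k[j] / two_w
    return q / two_w


def contingency_ari(l1, l2) -> float:
    """Adjusted Rand index from the contingency table, textbook formula."""
    l1 = np.asarray(l1)
    l2 = np.asarray(l2)
    u1, inv1 = np.unique(l1, return_inverse=True)
    u2, inv2 = np.unique(l2, return_inverse=True)
    cont = np.zeros((len(u1), len(u2)), dtype=np.int64)
    for a, b in zip(inv1, inv2):
        cont[a, b] += 1

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(cont).sum()
    a_sum = comb2(cont.sum(axis=1)).sum()
    b_sum = comb2(cont.sum(axis=0)).sum()
    n = len(l1)
    expected = a_sum * b_sum / comb2(n)
    max_index = (a_sum + b_sum) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def hop_distances_by_matrix_powers(weights: np.ndarray) -> np.ndarray:
    """Geodesic hop counts via boolean adjacency powers (reachability)."""
    n = weights.shape[0]
    adj = weights > 0
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reach = np.eye(n, dtype=bool)
    power = np.eye(n, dtype=bool)
    for step in range(1, n):
        power = power @ adj
        new = power & ~reach
        dist[new] = step
        reach |= new
        if reach.all():
            break
    return dist


def procrustes_disparity(x: np.ndarray, y: np.ndarray) -> float:
    """Min RMS difference after translation/rotation/reflection (no scaling)."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    u, _, vt = np.linalg.svd(yc.T @ xc)
    r = u @ vt
    return float(np.sqrt(((yc @ r - xc) ** 2).sum() / len(x)))
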