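"""Independent brute-force oracles used by the test suite.

Every oracle here is a deliberately naive re-derivation (dense linear
algebra, dynamic programming, exhaustive enumeration, flood fill) kept free
of the package's own code paths.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def dense_laplacian_scores(F: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Laplacian scores by explicit dense matrix products, one feature at a time."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    D = np.diag(W.sum(axis=1))
    L = D - W
    one = np.ones(n)
    scores = []
    for f in np.asarray(F, dtype=float).T:
        ft = f - ((f @ D @ one) / (one @ D @ one)) * one
        den = ft @ D @ ft
        scores.append(np.inf if den <= 0 else float(ft @ L @ ft) / den)
    return np.array(scores)


def brute_force_knn_weights(X: np.ndarray, n_neighbors: int, t: float) -> np.ndarray:
    """Symmetric union-of-kNN heat-kernel weights from dense pairwise distances."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    W = np.zeros((n, n))
    for i in range(n):
        order = np.argsort(d2[i])
        neighbors = [j for j in order if j != i][:n_neighbors]
        for j in neighbors:
            w = np.exp(-d2[i, j] / t)
            W[i, j] = max(W[i, j], w)
            W[j, i] = max(W[j, i], w)
    return W


def _segment_within_ss(x_sorted: np.ndarray, i: int, j: int) -> float:
    seg = x_sorted[i:j]
    return float(((seg - seg.mean()) ** 2).sum())


def dp_optimal_contiguous_within_ss(x: np.ndarray, k: int) -> float:
    """Exact minimal within-SS over all contiguous partitions (dynamic program)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    pre = np.concatenate([[0.0], np.cumsum(x)])
    pre2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def cost(i: int, j: int) -> float:
        s, s2, m = pre[j] - pre[i], pre2[j] - pre2[i], j - i
        return s2 - s * s / m

    D = np.full((k + 1, n + 1), np.inf)
    D[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            D[kk, j] = min(D[kk - 1, i] + cost(i, j) for i in range(kk - 1, j))
    return float(D[k, n])


def exhaustive_contiguous_within_ss(x: np.ndarray, k: int) -> float:
    """Same optimum by enumerating every set of k-1 cut points (tiny n only)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        edges = (0,) + cuts + (n,)
        ss = sum(_segment_within_ss(x, i, j) for i, j in zip(edges[:-1], edges[1:]))
        best = min(best, ss)
    return float(best)


_NEIGHBOR_OFFSETS = {
    6: [o for o in itertools.product((-1, 0, 1), repeat=3) if sum(abs(v) for v in o) == 1],
    18: [o for o in itertools.product((-1, 0, 1), repeat=3) if 1 <= sum(abs(v) for v in o) <= 2],
    26: [o for o in itertools.product((-1, 0, 1), repeat=3) if any(o)],
}


def flood_fill_components(mask: np.ndarray, connectivity: int = 26) -> list[int]:
    """Connected-component extents by breadth-first flood fill, sorted descending."""
    mask = np.asarray(mask).astype(bool)
    offsets = _NEIGHBOR_OFFSETS[connectivity]
    seen = np.zeros_like(mask)
    extents = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        size = 0
        while queue:
            v = queue.popleft()
            size += 1
            for o in offsets:
                w = tuple(a + b for a, b in zip(v, o))
                if all(0 <= wi < si for wi, si in zip(w, mask.shape)) and mask[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        extents.append(size)
    return sorted(extents, reverse=True)


def pairwise_auroc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUROC as the explicit pairwise-comparison probability (ties count 1/2)."""
    y_true = np.asarray(y_true).astype(bool)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true]
    neg = scores[~y_true]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))
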