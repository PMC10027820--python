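"""Independent brute-force oracles for the graph metrics.

Everything here is written in the most literal way possible — explicit
triple loops and exhaustive path enumeration — and shares no code with the
implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def bf_triangle_counts(w: np.ndarray) -> np.ndarray:
    """t_i = 1/2 sum_{j != h, both != i} (w_ij+w_ji)(w_ih+w_hi)(w_jh+w_hj)."""
    n = w.shape[0]
    t = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                acc += (w[i, j] + w[j, i]) * (w[i, h] + w[h, i]) * (w[j, h] + w[h, j])
        t[i] = acc / 2.0
    return t


def bf_strengths(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    return np.array([w[i, :].sum() + w[:, i].sum() for i in range(n)])


def bf_transitivity(w: np.ndarray) -> float:
    t = bf_triangle_counts(w)
    k = bf_strengths(w)
    denom = 0.0
    for i in range(w.shape[0]):
        recip = sum(w[i, j] * w[j, i] for j in range(w.shape[0]))
        denom += k[i] * (k[i] - 1) - 2 * recip
    if denom <= 0:
        return 0.0
    return float(t.sum() / denom)


def bf_clustering(w: np.ndarray) -> float:
    t = bf_triangle_counts(w)
    k = bf_strengths(w)
    total = 0.0
    for i in range(w.shape[0]):
        if k[i] * (k[i] - 1) > 0:
            total += 2 * t[i] / (k[i] * (k[i] - 1))
    return float(total / w.shape[0])


def bf_centralization(w: np.ndarray) -> float:
    k = bf_strengths(w)
    n = w.shape[0]
    return float((k.max() - k).sum() / ((n - 1) * (n - 2)))


def bf_shortest_distances(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest distance (edge length 1/w) by exhaustive simple-path
    enumeration. Only tractable for tiny graphs (n <= 6)."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    nodes = list(range(n))
    for src in nodes:
        for dst in nodes:
            if src == dst:
                continue
            best = np.inf
            for length in range(1, n):
                for mids in itertools.permutations(
                    [v for v in nodes if v not in (src, dst)], length - 1
                ):
                    path = (src, *mids, dst)
                    cost = 0.0
                    ok = True
                    for a, b in zip(path, path[1:]):
                        if w[a, b] <= 0:
                            ok = False
                            break
                        cost += 1.0 / w[a, b]
                    if ok:
                        best = min(best, cost)
            d[src, dst] = best
    return d


def bf_global_efficiency(w: np.ndarray) -> float:
    d = bf_shortest_distances(w)
    n = w.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def classic_global_clustering(adj: np.ndarray) -> float:
    """Classic binary global clustering coefficient: 3 x triangles / triples.

    ``adj`` must be a symmetric 0/1 matrix with empty diagonal.
    """
    n = adj.shape[0]
    closed = 0
    triples = 0
    for i in range(n):
        neighbors = [j for j in range(n) if adj[i, j]]
        for a, b in itertools.combinations(neighbors, 2):
            triples += 1
            if adj[a, b]:
                closed += 1
    if triples == 0:
        return 0.0
    return closed / triples
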