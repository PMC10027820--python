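"""The five scanpath-network metrics.

All metrics operate on a directed weighted :class:`~scanpathnet.network.ScanpathNetwork`
with weight matrix W (empty diagonal). Throughout, the degree (strength) of
node i is

    k_i = sum_j (w_ij + w_ji),

i.e. the total saccade weight landing on and departing from the word.

* density           D = sum_{i != j} w_ij / (N (N - 1))
* centralization    C = sum_i (C_max - C_i) / ((N - 1)(N - 2)),  C_i = k_i
                    (Freeman's graph centralization over degree scores;
                    0 ~ chain, 1 = star for unit-weight graphs)
* transitivity      T = sum_i t_i / sum_i [k_i (k_i - 1) - 2 sum_j w_ij w_ji]
                    with the directed-weighted triangle count
                    t_i = 1/2 sum_{j,h} (w_ij + w_ji)(w_ih + w_hi)(w_jh + w_hj)
* global efficiency E = (1/N) sum_i [ sum_{j != i} 1/d_ij ] / (N - 1), where
                    d_ij is the shortest-path distance with edge length
                    1/w (stronger transitions are "closer"); unreachable
                    pairs contribute zero
* small-worldness   S = (C_clust / L) / (C_rand / L_rand), clustering and
                    characteristic path length normalized by a random
                    reference ensemble with the same number of nodes and
                    directed edges (Humphries-Gurney style; S > 1 indicates
                    small-world organization)

Two conventions are deliberately configurable and always recorded in the
result provenance: the characteristic-path-length mode (``mean_distance``,
the standard mean shortest distance over reachable ordered pairs, or
``as_printed``, the mean inverse distance, which is algebraically identical
to E) and whether centralization binarizes weights before computing degree
scores (the [0, 1] bound only holds for binary graphs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

from .network import ScanpathNetwork, to_adjacency

__all__ = [
    "MetricSet",
    "DistanceMatrix",
    "RandomReferenceEnsemble",
    "UndefinedMetricError",
    "weight_matrix",
    "density",
    "freeman_centralization",
    "classify_topology",
    "triangle_counts",
    "transitivity",
    "clustering_coefficient",
    "shortest_distances",
    "global_efficiency",
    "characteristic_path_length",
    "random_reference",
    "small_worldness",
    "metric_set",
]

LMode = Literal["mean_distance", "as_printed"]


class UndefinedMetricError(ValueError):
    """The metric is undefined on this network (too few nodes, no paths...)."""


def weight_matrix(net: ScanpathNetwork) -> np.ndarray:
    """Dense weight matrix in the network's node order (zero diagonal)."""
    return to_adjacency(net, directed_view=True).matrix


def _strengths(w: np.ndarray) -> np.ndarray:
    return w.sum(axis=1) + w.sum(axis=0)


def density(net: ScanpathNetwork) -> float:
    """Total edge weight over the number of possible directed edges."""
    n = net.n
    if n < 2:
        raise UndefinedMetricError(f"density needs N >= 2 nodes, got {n}")
    return net.total_weight / (n * (n - 1))


def freeman_centralization(net: ScanpathNetwork, binarize: bool = False) -> float:
    """Freeman graph centralization of the node degree scores.

    With ``binarize=True`` each stored edge counts 1 regardless of weight,
    which restores the classic [0, 1] range on any graph.
    """
    n = net.n
    if n < 3:
        raise UndefinedMetricError(f"centralization needs N >= 3 nodes, got {n}")
    w = weight_matrix(net)
    if binarize:
        w = (w > 0).astype(float)
    k = _strengths(w)
    return float((k.max() - k).sum() / ((n - 1) * (n - 2)))


_TOPOLOGY_BANDS = (
    (0.2, "linear"),
    (0.4, "hierarchical"),
    (0.6, "network"),
    (np.inf, "star"),
)


def classify_topology(c: float) -> str:
    """Map a centralization score onto the linear/hierarchical/network/star bands."""
    if not 0.0 <= c <= 1.0:
        warnings.warn(
            f"centralization {c:g} outside [0, 1]; clamping before classification",
            stacklevel=2,
        )
        c = min(max(c, 0.0), 1.0)
    for upper, label in _TOPOLOGY_BANDS:
        if c < upper:
            return label
    return "star"


def triangle_counts(net: ScanpathNetwork) -> np.ndarray:
    """Directed-weighted triangle count t_i around each node.

    t_i = 1/2 sum over ordered pairs (j, h), j != h != i, of
    (w_ij + w_ji)(w_ih + w_hi)(w_jh + w_hj). Because the symmetrized matrix
    S = W + W^T has a zero diagonal, this equals diag(S^3) / 2.
    """
    w = weight_matrix(net)
    s = w + w.T
    return np.einsum("ij,jk,ki->i", s, s, s) / 2.0


def transitivity(net: ScanpathNetwork) -> float:
    """Directed-weighted transitivity: triangles over connected triples.

    Returns 0.0 (with a warning) when the network has no connected triples,
    rather than raising a division error.
    """
    w = weight_matrix(net)
    t = triangle_counts(net)
    k = _strengths(w)
    reciprocal = (w * w.T).sum(axis=1)
    denom = (k * (k - 1) - 2 * reciprocal).sum()
    if denom <= 0:
        warnings.warn("no connected triples; transitivity set to 0", stacklevel=2)
        return 0.0
    return float(t.sum() / denom)


def clustering_coefficient(net: ScanpathNetwork) -> float:
    """Mean local clustering C = (1/n) sum_i 2 t_i / (k_i (k_i - 1)).

    Nodes with k_i (k_i - 1) <= 0 (isolated nodes, leaves, or fractional
    strengths below 1 on averaged networks) contribute zero.
    """
    if net.n < 1:
        raise UndefinedMetricError("clustering needs at least one node")
    w = weight_matrix(net)
    t = triangle_counts(net)
    k = _strengths(w)
    denom = k * (k - 1)
    local = np.where(denom > 0, 2 * t / np.where(denom > 0, denom, 1.0), 0.0)
    return float(local.mean())


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs shortest distances with edge length 1/weight; inf if unreachable."""

    nodes: tuple[str, ...]
    d: np.ndarray

    def distance(self, i: str, j: str) -> float:
        idx = {n: k for k, n in enumerate(self.nodes)}
        return float(self.d[idx[i], idx[j]])


def shortest_distances(net: ScanpathNetwork) -> DistanceMatrix:
    """Directed all-pairs shortest paths; each edge's length is 1/w_ij."""
    w = weight_matrix(net)
    n = net.n
    if n == 0:
        return DistanceMatrix(nodes=(), d=np.zeros((0, 0)))
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    d = dijkstra(csr_array(lengths), directed=True)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(nodes=net.nodes, d=d)


def global_efficiency(net: ScanpathNetwork) -> float:
    """Mean inverse shortest-path distance over ordered node pairs."""
    n = net.n
    if n < 2:
        raise UndefinedMetricError(f"global efficiency needs N >= 2 nodes, got {n}")
    d = shortest_distances(net).d
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def characteristic_path_length(net: ScanpathNetwork, mode: LMode = "mean_distance") -> float:
    """Characteristic path length L.

    ``mean_distance`` (default): mean shortest distance over reachable
    ordered pairs — the standard definition. ``as_printed``: the mean
    inverse distance, which coincides exactly with global efficiency.
    """
    if mode == "as_printed":
        return global_efficiency(net)
    if mode != "mean_distance":
        raise ValueError(f"unknown L mode {mode!r}")
    n = net.n
    if n < 2:
        raise UndefinedMetricError(f"path length needs N >= 2 nodes, got {n}")
    d = shortest_distances(net).d
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise UndefinedMetricError("no reachable node pairs; path length undefined")
    return float(d[finite].mean())


@dataclass(frozen=True)
class RandomReferenceEnsemble:
    """Size-matched random reference graphs and their mean C / L."""

    references: tuple[ScanpathNetwork, ...]
    c_rand: float
    l_rand: float
    seed: int
    l_mode: LMode


def random_reference(
    net: ScanpathNetwork,
    n_refs: int = 20,
    seed: int = 0,
    l_mode: LMode = "mean_distance",
) -> RandomReferenceEnsemble:
    """Random null ensemble with the same node count and directed edge count.

    Each reference places the original multiset of edge weights onto
    directed edges drawn uniformly at random without replacement (no
    duplicates, no self-loops), then the clustering coefficient and
    characteristic path length are averaged across the ensemble.
    """
    if n_refs < 1:
        raise ValueError("n_refs must be >= 1")
    m = net.n_edges
    if m < 1:
        raise UndefinedMetricError("random reference needs at least one edge")
    n = net.n
    rng = np.random.default_rng(seed)
    wvals = np.array([net.weights[e] for e in sorted(net.weights)], dtype=float)
    slots = n * (n - 1)
    refs: list[ScanpathNetwork] = []
    cs, ls = [], []
    for _ in range(n_refs):
        chosen = rng.choice(slots, size=m, replace=False)
        perm = rng.permutation(m)
        weights: dict[tuple[str, str], float] = {}
        for slot, widx in zip(chosen, perm):
            i, r = divmod(int(slot), n - 1)
            j = r if r < i else r + 1
            weights[(net.nodes[i], net.nodes[j])] = float(wvals[widx])
        ref = ScanpathNetwork(nodes=net.nodes, weights=weights, provenance="random-reference")
        refs.append(ref)
        cs.append(clustering_coefficient(ref))
        ls.append(characteristic_path_length(ref, mode=l_mode))
    return RandomReferenceEnsemble(
        references=tuple(refs),
        c_rand=float(np.mean(cs)),
        l_rand=float(np.mean(ls)),
        seed=seed,
        l_mode=l_mode,
    )


def small_worldness(
    net: ScanpathNetwork,
    n_refs: int = 20,
    seed: int = 0,
    l_mode: LMode = "mean_distance",
) -> float:
    """S = (C/L) / (C_rand/L_rand) against the size-matched random ensemble."""
    c = clustering_coefficient(net)
    l = characteristic_path_length(net, mode=l_mode)
    ens = random_reference(net, n_refs=n_refs, seed=seed, l_mode=l_mode)
    if ens.c_rand <= 0:
        raise UndefinedMetricError(
            "random-reference clustering is zero across the ensemble; "
            "raise n_refs or check the network size"
        )
    if l <= 0 or ens.l_rand <= 0:
        raise UndefinedMetricError("non-positive path length; small-worldness undefined")
    return float((c / l) / (ens.c_rand / ens.l_rand))


@dataclass(frozen=True)
class MetricSet:
    """The five metrics for one network, with full provenance.

    A metric that is undefined on the given network (e.g. centralization on
    a 2-node graph, small-worldness on a graph with fewer than 4 nodes or
    no edges) is ``None`` and the reason is recorded in ``flags``.
    """

    density: float | None
    centralization: float | None
    transitivity: float | None
    global_efficiency: float | None
    small_worldness: float | None
    n_nodes: int
    n_edges: int
    n_random_refs: int
    seed: int
    l_mode: LMode
    flags: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "density": self.density,
            "centralization": self.centralization,
            "transitivity": self.transitivity,
            "global_efficiency": self.global_efficiency,
            "small_worldness": self.small_worldness,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_random_refs": self.n_random_refs,
            "seed": self.seed,
            "l_mode": self.l_mode,
        }


def metric_set(
    net: ScanpathNetwork,
    n_refs: int = 20,
    seed: int = 0,
    l_mode: LMode = "mean_distance",
    binarize_centralization: bool = False,
) -> MetricSet:
    """Bundle all five metrics; undefined members become None + a flag."""
    values: dict[str, float | None] = {}
    flags: dict[str, str] = {}

    def attempt(name, fn):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                values[name] = fn()
        except UndefinedMetricError as exc:
            values[name] = None
            flags[name] = str(exc)

    attempt("density", lambda: density(net))
    attempt(
        "centralization",
        lambda: freeman_centralization(net, binarize=binarize_centralization),
    )
    attempt("transitivity", lambda: transitivity(net))
    attempt("global_efficiency", lambda: global_efficiency(net))
    if net.n >= 4 and net.n_edges >= 1:
        attempt(
            "small_worldness",
            lambda: small_worldness(net, n_refs=n_refs, seed=seed, l_mode=l_mode),
        )
    else:
        values["small_worldness"] = None
        flags["small_worldness"] = "needs >= 4 nodes and >= 1 edge"
    return MetricSet(
        density=values["density"],
        centralization=values["centralization"],
        transitivity=values["transitivity"],
        global_efficiency=values["global_efficiency"],
        small_worldness=values["small_worldness"],
        n_nodes=net.n,
        n_edges=net.n_edges,
        n_random_refs=n_refs,
        seed=seed,
        l_mode=l_mode,
        flags=flags,
    )
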