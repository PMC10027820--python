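"""Directed weighted scanpath networks.

A scanpath network encodes a reader's pass through a text as a graph: each
fixated word (recurrences merged onto one node) is a node, and each saccade
between two different words is a directed edge whose weight counts how many
times that transition occurred. Consecutive refixations of the same word
produce no self-loop — every downstream metric sums over ordered pairs of
distinct nodes, and the adjacency matrix keeps an empty diagonal.

The module also provides adjacency-matrix views (directed, or symmetrized
"regardless of direction" for presentation), cross-reader averaging with
absent edges counted as zero, and the degree/weight mask used before
visualizing group-average networks.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import networkx as nx
import numpy as np

from .fixation_io import Scanpath

logger = logging.getLogger(__name__)

__all__ = [
    "ScanpathNetwork",
    "AdjacencyMatrix",
    "MaskedNetwork",
    "build_network",
    "from_edges",
    "to_adjacency",
    "from_adjacency",
    "node_degree",
    "average_networks",
    "apply_mask",
    "to_networkx",
    "write_graphml",
    "write_gexf",
    "write_adjacency_csv",
]


@dataclass(frozen=True)
class ScanpathNetwork:
    """Directed weighted graph over merged word nodes.

    ``weights`` maps ordered node pairs ``(i, j)``, ``i != j``, to positive
    weights (saccade counts for individual readers, fractional means for
    averaged networks). Nodes are kept in first-fixation order, which makes
    matrix views and exports deterministic.
    """

    nodes: tuple[str, ...]
    weights: Mapping[tuple[str, str], float] = field(default_factory=dict)
    directed: bool = True
    provenance: str = ""

    def __post_init__(self) -> None:
        self._validate(min_nodes=1)

    def _validate(self, min_nodes: int) -> None:
        if len(self.nodes) < min_nodes:
            raise ValueError("a scanpath network needs at least one node")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node keys")
        node_set = set(self.nodes)
        for (i, j), w in self.weights.items():
            if i == j:
                raise ValueError(f"self-loop stored on node {i!r}")
            if i not in node_set or j not in node_set:
                raise ValueError(f"edge ({i!r}, {j!r}) references unknown node")
            if w < 0:
                raise ValueError(f"negative weight on ({i!r}, {j!r})")

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    @property
    def total_weight(self) -> float:
        return float(sum(self.weights.values()))

    def weight(self, i: str, j: str) -> float:
        return float(self.weights.get((i, j), 0.0))

    def strength(self, node: str) -> float:
        """Node degree k_i: sum of weights of edges into and out of ``node``."""
        if node not in set(self.nodes):
            raise KeyError(f"unknown node {node!r}")
        return float(
            sum(w for (i, j), w in self.weights.items() if i == node or j == node)
        )


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Matrix view of a network: node order plus an N x N weight array."""

    nodes: tuple[str, ...]
    matrix: np.ndarray
    directed: bool = True

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("matrix shape does not match node count")
        if np.any(np.diag(m) != 0):
            raise ValueError("adjacency diagonal must be empty (no self-loops)")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class MaskedNetwork(ScanpathNetwork):
    """A network after degree/weight masking; may legitimately be empty."""

    degree_threshold: float = 5.0
    weight_threshold: float = 0.3

    def __post_init__(self) -> None:
        self._validate(min_nodes=0)


def build_network(scanpath: Scanpath) -> ScanpathNetwork:
    """Encode a scanpath as a directed weighted transition network.

    Each consecutive pair of fixations on different words increments the
    weight of the corresponding directed edge by one; consecutive
    refixations of the same word are ignored.
    """
    keys = scanpath.node_keys
    if len(keys) < 1:
        raise ValueError("cannot build a network from an empty scanpath")
    nodes: list[str] = []
    seen: set[str] = set()
    for k in keys:
        if k not in seen:
            seen.add(k)
            nodes.append(k)
    weights: dict[tuple[str, str], float] = {}
    for a, b in zip(keys, keys[1:]):
        if a == b:
            continue
        weights[(a, b)] = weights.get((a, b), 0.0) + 1.0
    return ScanpathNetwork(
        nodes=tuple(nodes),
        weights=weights,
        provenance=f"{scanpath.participant_id}/{scanpath.text_id}",
    )


def from_edges(
    edges: Iterable[tuple[str, str, float]],
    nodes: Sequence[str] | None = None,
    provenance: str = "",
) -> ScanpathNetwork:
    """Build a network directly from ``(source, target, weight)`` triples."""
    weights: dict[tuple[str, str], float] = {}
    order: list[str] = list(nodes) if nodes is not None else []
    seen = set(order)
    for i, j, w in edges:
        for node in (i, j):
            if node not in seen:
                seen.add(node)
                order.append(node)
        if i == j:
            raise ValueError(f"self-loop on {i!r}")
        weights[(i, j)] = weights.get((i, j), 0.0) + float(w)
    return ScanpathNetwork(nodes=tuple(order), weights=weights, provenance=provenance)


def to_adjacency(net: ScanpathNetwork, directed_view: bool = True) -> AdjacencyMatrix:
    """Matrix view; ``directed_view=False`` symmetrizes, cell = w_ij + w_ji."""
    index = {node: k for k, node in enumerate(net.nodes)}
    m = np.zeros((net.n, net.n))
    for (i, j), w in net.weights.items():
        m[index[i], index[j]] += w
    if not directed_view:
        m = m + m.T
    return AdjacencyMatrix(nodes=net.nodes, matrix=m, directed=directed_view)


def from_adjacency(adj: AdjacencyMatrix, provenance: str = "") -> ScanpathNetwork:
    """Inverse of :func:`to_adjacency` for the directed view (lossless)."""
    if not adj.directed:
        raise ValueError(
            "the symmetrized view is a presentation format and cannot be "
            "converted back to a directed network without loss"
        )
    weights = {
        (adj.nodes[i], adj.nodes[j]): float(adj.matrix[i, j])
        for i in range(len(adj.nodes))
        for j in range(len(adj.nodes))
        if i != j and adj.matrix[i, j] != 0
    }
    return ScanpathNetwork(nodes=adj.nodes, weights=weights, provenance=provenance)


def node_degree(net: ScanpathNetwork, node: str) -> float:
    """Degree of a word node: total saccade weight landing on plus departing it."""
    return net.strength(node)


def average_networks(nets: Sequence[ScanpathNetwork]) -> ScanpathNetwork:
    """Edge-wise mean over readers, absent edges counted as zero.

    Node set is the union of input node sets (readers fixate different word
    subsets; the union with absent-as-zero is the only alignment under which
    the mean is well defined). All inputs must come from the same text.
    """
    if not nets:
        raise ValueError("average_networks needs at least one network")
    texts = {n.provenance.split("/", 1)[1] for n in nets if "/" in n.provenance}
    if len(texts) > 1:
        raise ValueError(f"cannot average networks built over different texts: {sorted(texts)}")
    order: list[str] = []
    seen: set[str] = set()
    for net in nets:
        for node in net.nodes:
            if node not in seen:
                seen.add(node)
                order.append(node)
    sums: dict[tuple[str, str], float] = {}
    for net in nets:
        for edge, w in net.weights.items():
            sums[edge] = sums.get(edge, 0.0) + w
    k = len(nets)
    weights = {edge: s / k for edge, s in sums.items() if s != 0}
    return ScanpathNetwork(
        nodes=tuple(order), weights=weights, provenance="averaged"
    )


def apply_mask(
    net: ScanpathNetwork,
    degree_gt: float = 5.0,
    weight_gt: float = 0.3,
) -> MaskedNetwork:
    """Keep only edges with weight > ``weight_gt`` and, on the edge-filtered
    graph, nodes with degree > ``degree_gt`` (both strictly).

    Edges are filtered first and degrees recomputed before node removal;
    edges incident to removed nodes are dropped. A fully sub-threshold
    network yields an empty :class:`MaskedNetwork` (allowed, with a warning).
    """
    if degree_gt < 0 or weight_gt < 0:
        raise ValueError("mask thresholds must be non-negative")
    edge_kept = {e: w for e, w in net.weights.items() if w > weight_gt}
    degree: dict[str, float] = {node: 0.0 for node in net.nodes}
    for (i, j), w in edge_kept.items():
        degree[i] += w
        degree[j] += w
    node_kept = [node for node in net.nodes if degree[node] > degree_gt]
    if not node_kept:
        logger.warning("mask removed every node (thresholds %g/%g)", degree_gt, weight_gt)
    kept_set = set(node_kept)
    weights = {
        (i, j): w for (i, j), w in edge_kept.items() if i in kept_set and j in kept_set
    }
    return MaskedNetwork(
        nodes=tuple(node_kept),
        weights=weights,
        provenance=net.provenance,
        degree_threshold=degree_gt,
        weight_threshold=weight_gt,
    )


def to_networkx(net: ScanpathNetwork) -> nx.DiGraph:
    """Convert to a networkx DiGraph (edge attribute ``weight``, node ``degree``)."""
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for (i, j), w in net.weights.items():
        g.add_edge(i, j, weight=float(w))
    for node in net.nodes:
        g.nodes[node]["degree"] = net.strength(node)
    return g


def write_graphml(net: ScanpathNetwork, path: Union[str, Path]) -> None:
    nx.write_graphml(to_networkx(net), str(path))


def write_gexf(net: ScanpathNetwork, path: Union[str, Path]) -> None:
    nx.write_gexf(to_networkx(net), str(path))


def write_adjacency_csv(
    net: ScanpathNetwork, path: Union[str, Path], directed_view: bool = True
) -> None:
    """Adjacency matrix as CSV with node keys in the header row and column."""
    adj = to_adjacency(net, directed_view=directed_view)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([""] + list(adj.nodes))
        for i, node in enumerate(adj.nodes):
            writer.writerow([node] + [f"{v:g}" for v in adj.matrix[i]])
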