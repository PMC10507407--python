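"""Topological indices of an unweighted undirected interaction network.

Per-node: degree k, betweenness centrality BC (unnormalized pair fractions,
with a normalized variant alongside), eccentricity Ecc (hop metric), and
closeness centrality CC.  Global: mean degree <k> and the average clustering
coefficient Acc.  Edge confidence scores play no role here — they gate which
edges exist (see :mod:`osteonet.network_io`), after which every edge counts
as one hop, matching the defaults of common network-analysis tools.

Disconnected inputs are handled per component: distances, Ecc and CC are
computed within a node's component (an isolated node gets Ecc = 0, CC = 0),
and each node's component index is reported so consumers can exclude
stragglers explicitly.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import pandas as pd

from .network_io import InteractionNetwork

__all__ = [
    "NodeTopology",
    "NetworkTopology",
    "node_degree",
    "shortest_path_lengths",
    "betweenness_centrality",
    "eccentricity",
    "closeness_centrality",
    "local_clustering",
    "average_clustering",
    "compute_topology",
]


@dataclass
class NodeTopology:
    identifier: str
    k: int
    bc: float
    bc_normalized: float
    ecc: int
    cc: float
    component: int


@dataclass
class NetworkTopology:
    n_nodes: int
    n_edges: int
    mean_degree: float
    avg_clustering: float
    per_node: list[NodeTopology]

    def node(self, identifier: str) -> NodeTopology:
        for nt in self.per_node:
            if nt.identifier == identifier:
                return nt
        raise KeyError(identifier)

    def as_frame(self) -> pd.DataFrame:
        """Tidy per-node table (one row per node)."""
        return pd.DataFrame(
            [
                {
                    "identifier": nt.identifier,
                    "k": nt.k,
                    "BC": nt.bc,
                    "BC_normalized": nt.bc_normalized,
                    "Ecc": nt.ecc,
                    "CC": nt.cc,
                    "component": nt.component,
                }
                for nt in self.per_node
            ]
        )

    def global_summary(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "mean_degree": self.mean_degree,
            "avg_clustering": self.avg_clustering,
        }


def node_degree(net: InteractionNetwork, node: str) -> int:
    """Number of edges incident to ``node`` (raises ``KeyError`` if absent)."""
    if node not in net:
        raise KeyError(node)
    return net.degree(node)


def shortest_path_lengths(net: InteractionNetwork, source: str) -> dict[str, int]:
    """Hop distances from ``source`` to every reachable node (BFS)."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for u in net.neighbors(v):
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    return dist


def betweenness_centrality(net: InteractionNetwork) -> dict[str, float]:
    """Unnormalized betweenness: BC(v) = sum over unordered pairs {s, t}
    (s != v != t) of the fraction of shortest s-t paths through v.

    Brandes' dependency-accumulation algorithm; pairs in different
    components contribute nothing; path endpoints are excluded.
    """
    bc = {v: 0.0 for v in net.node_ids()}
    for s in net.node_ids():
        # single-source shortest paths with path counts
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in bc}
        sigma = {v: 0.0 for v in bc}
        dist = {v: -1 for v in bc}
        sigma[s] = 1.0
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in net.neighbors(v):
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = {v: 0.0 for v in bc}
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair was accumulated from both endpoints
    return {v: x / 2.0 for v, x in bc.items()}


def eccentricity(net: InteractionNetwork) -> dict[str, int]:
    """Ecc(v): maximum hop distance to any node of v's component.

    Isolated nodes get 0.
    """
    return {
        v: max(shortest_path_lengths(net, v).values()) for v in net.node_ids()
    }


def closeness_centrality(net: InteractionNetwork) -> dict[str, float]:
    """CC(v) = (n_c - 1) / sum of distances to the n_c - 1 other nodes of
    v's component; 0 for isolated nodes."""
    cc = {}
    for v in net.node_ids():
        dist = shortest_path_lengths(net, v)
        total = sum(dist.values())
        cc[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return cc


def local_clustering(net: InteractionNetwork, node: str) -> float:
    """C(v) = 2 T(v) / (k (k - 1)) with T(v) edges among v's neighbors;
    0 by convention when k < 2."""
    nbrs = net.neighbors(node)
    k = len(nbrs)
    if k < 2:
        return 0.0
    t = sum(
        1
        for i in range(k)
        for j in range(i + 1, k)
        if net.has_edge(nbrs[i], nbrs[j])
    )
    return 2.0 * t / (k * (k - 1))


def average_clustering(net: InteractionNetwork) -> float:
    """Mean local clustering coefficient over all nodes (Acc)."""
    ids = net.node_ids()
    if not ids:
        return 0.0
    return sum(local_clustering(net, v) for v in ids) / len(ids)


def compute_topology(net: InteractionNetwork) -> NetworkTopology:
    """All per-node and global indices in one deterministic pass.

    Output is independent of node insertion order (all iteration is over
    sorted identifiers).  An empty network is an error.
    """
    n = net.n_nodes
    if n == 0:
        raise ValueError("cannot compute topology of an empty network")
    e = net.n_edges
    bc = betweenness_centrality(net)
    ecc = eccentricity(net)
    cc = closeness_centrality(net)
    comps = net.connected_components()
    comp_index = {v: i for i, comp in enumerate(comps) for v in comp}
    norm = (n - 1) * (n - 2) / 2.0 if n > 2 else 0.0
    per_node = [
        NodeTopology(
            identifier=v,
            k=net.degree(v),
            bc=bc[v],
            bc_normalized=bc[v] / norm if norm else 0.0,
            ecc=ecc[v],
            cc=cc[v],
            component=comp_index[v],
        )
        for v in net.node_ids()
    ]
    return NetworkTopology(
        n_nodes=n,
        n_edges=e,
        mean_degree=2.0 * e / n,
        avg_clustering=average_clustering(net),
        per_node=per_node,
    )
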