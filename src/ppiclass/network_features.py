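"""Per-interaction network-topology features.

The network block of the feature vector has 71 values per interaction:
edge degree, edge betweenness, PageRank affinity, and the 68 normalized
EGDV entries (orbits 1-68).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graphlets import EGDV_LENGTH, OrbitCatalog, count_edge_orbits, normalize_egdv
from .network import EdgeRef, InteractionNetwork

__all__ = [
    "NetworkFeatureBlock",
    "edge_degree",
    "edge_betweenness",
    "all_edge_betweenness",
    "pagerank_affinity",
    "network_feature_block",
    "NETWORK_FEATURE_NAMES",
]

NETWORK_FEATURE_NAMES: list[str] = (
    ["Degree", "Betweeness", "APR"]
    + [f"orbit{i}" for i in range(1, EGDV_LENGTH + 1)]
)


@dataclass
class NetworkFeatureBlock:
    degree: int
    betweenness: float
    apr: float
    egdv: np.ndarray  # normalized, length 68

    def as_array(self) -> np.ndarray:
        return np.concatenate(
            [[self.degree, self.betweenness, self.apr], self.egdv])


def _require_edge(net: InteractionNetwork, e: EdgeRef) -> None:
    if not net.has_edge(e.u, e.v):
        raise ValueError(f"edge {e.u!r}-{e.v!r} not in network")


def edge_degree(net: InteractionNetwork, e: EdgeRef) -> int:
    """Number of edges sharing at least one endpoint with e.

    For a simple graph this is deg(u) + deg(v) - 2: e itself is excluded
    once at each endpoint, and no other edge is counted twice.
    """
    _require_edge(net, e)
    return net.graph.degree(e.u) + net.graph.degree(e.v) - 2


def all_edge_betweenness(net: InteractionNetwork) -> dict[EdgeRef, float]:
    """Unnormalized edge betweenness for every edge.

    Counts unordered node pairs whose shortest paths run through the
    edge, with equal fractional splitting across tied shortest paths
    (Brandes accumulation, via networkx).  A pair contributes to its own
    connecting edge, so an isolated edge scores 1.
    """
    bc = nx.edge_betweenness_centrality(net.graph, normalized=False)
    return {EdgeRef(u, v): value for (u, v), value in bc.items()}


def edge_betweenness(net: InteractionNetwork, e: EdgeRef) -> float:
    _require_edge(net, e)
    return all_edge_betweenness(net)[EdgeRef(e.u, e.v)]


def pagerank_affinity(net: InteractionNetwork, e: EdgeRef,
                      damping: float = 0.85, tol: float = 1e-10,
                      combine: str = "min", max_iter: int = 1000) -> float:
    """PageRank affinity of the two endpoints of e.

    Runs personalized PageRank seeded at u and at v (restart probability
    1 - damping) and combines the cross-visit probabilities pr_u(v) and
    pr_v(u) symmetrically — by default their minimum.  Nodes in the same
    densely connected cluster visit each other often from either side,
    so intra-cluster edges score high.
    """
    _require_edge(net, e)
    if not 0 < damping < 1:
        raise ValueError("damping must be in (0, 1)")
    if combine not in ("min", "product", "mean"):
        raise ValueError(f"unknown combine rule {combine!r}")
    pr_u = nx.pagerank(net.graph, alpha=damping, personalization={e.u: 1.0},
                       tol=tol, max_iter=max_iter)
    pr_v = nx.pagerank(net.graph, alpha=damping, personalization={e.v: 1.0},
                       tol=tol, max_iter=max_iter)
    a, b = pr_u[e.v], pr_v[e.u]
    if combine == "min":
        return min(a, b)
    if combine == "product":
        return a * b
    return (a + b) / 2.0


def network_feature_block(net: InteractionNetwork, e: EdgeRef,
                          catalog: OrbitCatalog,
                          betweenness: dict[EdgeRef, float] | None = None,
                          damping: float = 0.85,
                          combine: str = "min") -> NetworkFeatureBlock:
    """Assemble the 71-value network block for one interaction.

    *betweenness* may be precomputed once per network (it is a
    whole-graph quantity) and passed in to avoid recomputation.
    """
    _require_edge(net, e)
    if betweenness is None:
        betweenness = all_edge_betweenness(net)
    vec = normalize_egdv(count_edge_orbits(net, e, catalog))
    return NetworkFeatureBlock(
        degree=edge_degree(net, e),
        betweenness=betweenness[EdgeRef(e.u, e.v)],
        apr=pagerank_affinity(net, e, damping=damping, combine=combine),
        egdv=vec.normalized,
    )
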