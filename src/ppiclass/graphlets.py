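"""Edge graphlet degree vectors (EGDV).

Graphlets are the small connected induced subgraphs of a network; on 2-5
nodes there are 30 of them (1 + 2 + 6 + 21).  The edges of each graphlet
fall into *edge orbits* — equivalence classes under the graphlet's
automorphism group — and across all 30 graphlets there are exactly 69
such orbits.  The EGDV of an edge e counts, for every orbit, how often e
occupies that orbit over all graphlet occurrences containing e.

Orbit 0 is the 2-node graphlet's single edge: every existing edge
touches it exactly once, so it carries no information and is excluded
from the feature vector, which therefore has 68 entries (orbits 1-68).

Global orbit ids are deterministic: graphlets are ordered by (node
count, edge count, canonical adjacency code) and orbits within a
graphlet by their lexicographically smallest edge.  This fixes orbit 0
as the single edge and orbit 68 as the 5-clique's edge orbit; the ids of
intermediate orbits are a convention of this package (the catalog can be
exported as JSON so users can relabel against any published numbering).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations, permutations

import networkx as nx
import numpy as np

from .network import EdgeRef, InteractionNetwork

__all__ = [
    "Graphlet",
    "OrbitCatalog",
    "EdgeGraphletVector",
    "build_orbit_catalog",
    "enumerate_containing_subgraphs",
    "count_edge_orbits",
    "count_edge_orbits_bruteforce",
    "normalize_egdv",
    "write_egdv_table",
    "N_ORBITS",
    "N_GRAPHLETS",
    "EGDV_LENGTH",
]

N_ORBITS = 69
N_GRAPHLETS = 30
EGDV_LENGTH = 68  # orbits 1..68; orbit 0 excluded

_MAX_BRUTEFORCE_NODES = 15


def _pairs(k: int) -> list[tuple[int, int]]:
    return list(combinations(range(k), 2))


def _permute_bits(bits: int, perm: tuple[int, ...],
                  pairs: list[tuple[int, int]],
                  pair_index: dict[tuple[int, int], int]) -> int:
    out = 0
    for idx, (i, j) in enumerate(pairs):
        if bits >> idx & 1:
            a, b = perm[i], perm[j]
            out |= 1 << pair_index[(a, b) if a < b else (b, a)]
    return out


def _is_connected_bits(bits: int, k: int, pairs: list[tuple[int, int]]) -> bool:
    adj = [0] * k
    for idx, (i, j) in enumerate(pairs):
        if bits >> idx & 1:
            adj[i] |= 1 << j
            adj[j] |= 1 << i
    seen = 1
    frontier = 1
    while frontier:
        nxt = 0
        for i in range(k):
            if frontier >> i & 1:
                nxt |= adj[i]
        frontier = nxt & ~seen
        seen |= frontier
    return seen == (1 << k) - 1


@dataclass(frozen=True)
class Graphlet:
    """One canonical connected graph on 2-5 nodes with its edge orbits."""

    index: int                                   # 0..29
    n_nodes: int
    bits: int                                    # canonical adjacency code
    edges: tuple[tuple[int, int], ...]
    orbits: tuple[tuple[tuple[int, int], ...], ...]   # orbit -> member edges
    orbit_ids: dict[tuple[int, int], int] = field(hash=False)  # edge -> global id


class OrbitCatalog:
    """The 30 graphlets on 2-5 nodes and their 69 global edge orbits."""

    def __init__(self, graphlets: list[Graphlet]):
        self.graphlets = graphlets
        self.n_orbits = sum(len(g.orbits) for g in graphlets)
        # canonical code -> graphlet, per node count
        self._by_bits: dict[tuple[int, int], Graphlet] = {
            (g.n_nodes, g.bits): g for g in graphlets
        }
        self._pairs = {k: _pairs(k) for k in (2, 3, 4, 5)}
        self._pair_index = {
            k: {p: i for i, p in enumerate(ps)} for k, ps in self._pairs.items()
        }
        self._perms = {k: list(permutations(range(k))) for k in (2, 3, 4, 5)}
        # (k, labeled bits, edge position) -> global orbit id
        self._orbit_cache: dict[tuple[int, int, int, int], int] = {}

    def canonicalize(self, k: int, bits: int) -> tuple[int, tuple[int, ...]]:
        """Minimum adjacency code over node permutations, and one
        permutation achieving it."""
        pairs, pidx = self._pairs[k], self._pair_index[k]
        best, best_perm = None, None
        for perm in self._perms[k]:
            cand = _permute_bits(bits, perm, pairs, pidx)
            if best is None or cand < best:
                best, best_perm = cand, perm
        return best, best_perm

    def orbit_of(self, k: int, bits: int, iu: int, iv: int) -> int:
        """Global orbit id of the edge at positions (iu, iv) inside the
        labeled k-node graph with adjacency code *bits*.

        Any canonicalizing permutation gives the same orbit: two such
        permutations differ by an automorphism of the canonical graph.
        """
        if iu > iv:
            iu, iv = iv, iu
        key = (k, bits, iu, iv)
        cached = self._orbit_cache.get(key)
        if cached is not None:
            return cached
        canon, perm = self.canonicalize(k, bits)
        g = self._by_bits.get((k, canon))
        if g is None:
            raise ValueError("subgraph is not connected — not a graphlet")
        a, b = perm[iu], perm[iv]
        orbit = g.orbit_ids[(a, b) if a < b else (b, a)]
        self._orbit_cache[key] = orbit
        return orbit

    def to_json(self) -> str:
        """Export graphlet adjacency lists and the orbit map."""
        payload = []
        for g in self.graphlets:
            payload.append({
                "graphlet": g.index,
                "n_nodes": g.n_nodes,
                "edges": [list(e) for e in g.edges],
                "orbits": [
                    {"orbit_id": g.orbit_ids[orb[0]],
                     "edges": [list(e) for e in orb]}
                    for orb in g.orbits
                ],
            })
        return json.dumps(payload, indent=1)


def build_orbit_catalog() -> OrbitCatalog:
    """Enumerate all connected graphs on 2-5 nodes and their edge orbits.

    Graphs are deduplicated by brute-force canonicalization (minimum
    adjacency code over all node permutations; cheap at <= 5 nodes).
    Edge orbits are the equivalence classes of edges under the
    automorphism group, found by direct automorphism enumeration.
    """
    graphlets: list[Graphlet] = []
    next_orbit = 0
    index = 0
    for k in (2, 3, 4, 5):
        pairs = _pairs(k)
        pidx = {p: i for i, p in enumerate(pairs)}
        perms = list(permutations(range(k)))
        canon_seen: set[int] = set()
        canon_list: list[int] = []
        for bits in range(1 << len(pairs)):
            if not _is_connected_bits(bits, k, pairs):
                continue
            canon = min(_permute_bits(bits, p, pairs, pidx) for p in perms)
            if canon not in canon_seen:
                canon_seen.add(canon)
                canon_list.append(canon)
        canon_list.sort(key=lambda b: (bin(b).count("1"), b))
        for canon in canon_list:
            edges = tuple(pairs[i] for i in range(len(pairs)) if canon >> i & 1)
            autos = [p for p in perms
                     if _permute_bits(canon, p, pairs, pidx) == canon]
            # orbit of each edge = its image set under the automorphisms
            orbit_map: dict[tuple[int, int], frozenset] = {}
            for e in edges:
                images = set()
                for p in autos:
                    a, b = p[e[0]], p[e[1]]
                    images.add((a, b) if a < b else (b, a))
                orbit_map[e] = frozenset(images)
            distinct = sorted({o for o in orbit_map.values()},
                              key=lambda o: min(o))
            orbit_ids: dict[tuple[int, int], int] = {}
            orbit_edges: list[tuple[tuple[int, int], ...]] = []
            for orb in distinct:
                members = tuple(sorted(orb))
                orbit_edges.append(members)
                for e in members:
                    orbit_ids[e] = next_orbit
                next_orbit += 1
            graphlets.append(Graphlet(index, k, canon, edges,
                                      tuple(orbit_edges), orbit_ids))
            index += 1
    return OrbitCatalog(graphlets)


@dataclass
class EdgeGraphletVector:
    """Per-edge orbit counts for orbits 1-68 (orbit 0 excluded)."""

    edge: EdgeRef
    raw_counts: np.ndarray           # int64, length 68; index i -> orbit i+1
    orbit0: int = 1                  # sanity: the edge itself, always 1
    normalized: np.ndarray | None = None

    def orbit_count(self, orbit: int) -> int:
        if orbit == 0:
            return self.orbit0
        return int(self.raw_counts[orbit - 1])


def enumerate_containing_subgraphs(net: InteractionNetwork, e: EdgeRef, k: int):
    """Yield every k-node subset S with {u,v} in S whose induced subgraph
    is connected, exactly once.

    Neighborhood-expansion enumeration in the FANMOD/ESU style, seeded
    with the edge's two endpoints: the extension set holds nodes adjacent
    to the current subset but outside its closed neighborhood, so each
    connected superset is produced by a unique branch.
    """
    G = net.graph
    u, v = e.u, e.v
    if not G.has_edge(u, v):
        raise ValueError(f"edge {u!r}-{v!r} not in network")
    if not 2 <= k <= 5:
        raise ValueError("graphlet size k must be in 2..5")
    seed = frozenset((u, v))
    if k == 2:
        yield seed
        return
    nbhd = set(seed)
    ext = set()
    for s in seed:
        for w in G[s]:
            if w not in nbhd:
                ext.add(w)
    nbhd |= ext

    def extend(sub: frozenset, ext: set, nbhd: frozenset):
        if len(sub) == k:
            yield sub
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            new = {x for x in G[w] if x not in nbhd}
            yield from extend(sub | {w}, ext | new, nbhd | new)

    yield from extend(seed, ext, frozenset(nbhd))


def _count_from_subsets(net: InteractionNetwork, e: EdgeRef,
                        catalog: OrbitCatalog, subset_iter) -> EdgeGraphletVector:
    G = net.graph
    raw = np.zeros(EGDV_LENGTH, dtype=np.int64)
    orbit0 = 0
    for subset in subset_iter:
        S = sorted(subset)
        k = len(S)
        pos = {n: i for i, n in enumerate(S)}
        pidx = catalog._pair_index[k]
        bits = 0
        for i, j in catalog._pairs[k]:
            if G.has_edge(S[i], S[j]):
                bits |= 1 << pidx[(i, j)]
        orbit = catalog.orbit_of(k, bits, pos[e.u], pos[e.v])
        if orbit == 0:
            orbit0 += 1
        else:
            raw[orbit - 1] += 1
    return EdgeGraphletVector(edge=e, raw_counts=raw, orbit0=orbit0)


def count_edge_orbits(net: InteractionNetwork, e: EdgeRef,
                      catalog: OrbitCatalog) -> EdgeGraphletVector:
    """Raw EGDV of edge e: orbit counts over all 2-5-node graphlet
    occurrences containing e."""

    def subsets():
        for k in (2, 3, 4, 5):
            yield from enumerate_containing_subgraphs(net, e, k)

    return _count_from_subsets(net, e, catalog, subsets())


def count_edge_orbits_bruteforce(net: InteractionNetwork, e: EdgeRef,
                                 catalog: OrbitCatalog) -> EdgeGraphletVector:
    """Reference EGDV by exhaustive subset scan; test oracle only."""
    n = net.number_of_nodes()
    if n > _MAX_BRUTEFORCE_NODES:
        raise ValueError(
            f"brute-force enumeration limited to {_MAX_BRUTEFORCE_NODES} nodes "
            f"(got {n})")
    G = net.graph
    if not G.has_edge(e.u, e.v):
        raise ValueError(f"edge {e.u!r}-{e.v!r} not in network")
    others = [x for x in G.nodes if x not in (e.u, e.v)]

    def subsets():
        for k in (2, 3, 4, 5):
            for extra in combinations(others, k - 2):
                S = {e.u, e.v, *extra}
                if nx.is_connected(G.subgraph(S)):
                    yield frozenset(S)

    return _count_from_subsets(net, e, catalog, subsets())


def write_egdv_table(vectors: list[EdgeGraphletVector], path,
                     normalized: bool = False) -> None:
    """Write EGDVs as TSV: u, v, then orbit1..orbit68 (raw counts, or
    the normalized values with ``normalized=True``)."""
    header = ["u", "v"] + [f"orbit{i}" for i in range(1, EGDV_LENGTH + 1)]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for vec in vectors:
            values = vec.normalized if normalized else vec.raw_counts
            if values is None:
                raise ValueError("vector has no normalized values; "
                                 "run normalize_egdv first")
            row = [vec.edge.u, vec.edge.v] + [repr(x) for x in values.tolist()]
            fh.write("\t".join(row) + "\n")


def normalize_egdv(vec: EdgeGraphletVector) -> EdgeGraphletVector:
    """Log-scale then normalize: v = ln(1 + raw), divided by its sum.

    Raw orbit counts span orders of magnitude; ln(1+x) compresses them
    (and is defined at 0), and dividing by the total makes every EGDV sum
    to 1.  An all-zero vector stays all-zero.
    """
    logged = np.log1p(vec.raw_counts.astype(float))
    total = logged.sum()
    vec.normalized = logged / total if total > 0 else np.zeros_like(logged)
    return vec
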