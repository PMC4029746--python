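import math

import networkx as nx
import numpy as np
import pytest

from ppiclass.graphlets import (EGDV_LENGTH, EdgeGraphletVector,
                                count_edge_orbits,
                                count_edge_orbits_bruteforce,
                                enumerate_containing_subgraphs,
                                normalize_egdv)
from ppiclass.network import EdgeRef, InteractionNetwork

from .conftest import make_net


def clique_orbit_ids(catalog):
    """Global orbit id of the k-clique edge orbit, k=2..5."""
    out = {}
    for g in catalog.graphlets:
        if len(g.edges) == g.n_nodes * (g.n_nodes - 1) // 2:
            out[g.n_nodes] = next(iter(g.orbit_ids.values()))
    return out


class TestCatalog:
    def test_orbit_and_graphlet_totals(self, catalog):
        assert catalog.n_orbits == 69
        assert len(catalog.graphlets) == 30

    def test_connected_graph_counts_per_size(self, catalog):
        by_size = {}
        for g in catalog.graphlets:
            by_size[g.n_nodes] = by_size.get(g.n_nodes, 0) + 1
        assert by_size == {2: 1, 3: 2, 4: 6, 5: 21}

    def test_three_node_graphlets_have_one_orbit_each(self, catalog):
        three = [g for g in catalog.graphlets if g.n_nodes == 3]
        assert [len(g.orbits) for g in three] == [1, 1]

    def test_orbit_zero_and_sixtyeight(self, catalog):
        ids = clique_orbit_ids(catalog)
        assert ids[2] == 0
        assert ids[5] == 68

    def test_orbits_partition_edges(self, catalog):
        for g in catalog.graphlets:
            members = [e for orb in g.orbits for e in orb]
            assert sorted(members) == sorted(g.edges)

    def test_automorphism_closure_of_orbits(self, catalog):
        # two edge positions share an orbit iff an automorphism maps one
        # onto the other: check the forward direction by brute force
        from itertools import permutations
        for g in catalog.graphlets:
            edge_set = set(g.edges)
            autos = [p for p in permutations(range(g.n_nodes))
                     if all(tuple(sorted((p[a], p[b]))) in edge_set
                            for a, b in g.edges)]
            for e in g.edges:
                for p in autos:
                    img = tuple(sorted((p[e[0]], p[e[1]])))
                    assert g.orbit_ids[img] == g.orbit_ids[e]


class TestEnumeration:
    def test_triangle_k3(self, triangle):
        subsets = list(enumerate_containing_subgraphs(
            triangle, EdgeRef("A", "B"), 3))
        assert subsets == [frozenset({"A", "B", "C"})]

    def test_path4_k4(self):
        net = make_net([("A", "B"), ("B", "C"), ("C", "D")])
        subsets = list(enumerate_containing_subgraphs(net, EdgeRef("B", "C"), 4))
        assert subsets == [frozenset("ABCD")]

    def test_missing_edge_errors(self, path3):
        with pytest.raises(ValueError):
            list(enumerate_containing_subgraphs(path3, EdgeRef("A", "C"), 3))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_subset_scan(self, seed):
        G = nx.gnp_random_graph(10, 0.4, seed=seed)
        net = InteractionNetwork(G)
        u, v = next(iter(G.edges()))
        e = EdgeRef(u, v)
        from itertools import combinations
        others = [x for x in G.nodes if x not in (u, v)]
        for k in (2, 3, 4, 5):
            expected = {
                frozenset({u, v, *extra})
                for extra in combinations(others, k - 2)
                if nx.is_connected(G.subgraph({u, v, *extra}))
            }
            got = list(enumerate_containing_subgraphs(net, e, k))
            assert len(got) == len(set(got)), "duplicate subsets emitted"
            assert set(got) == expected


class TestCounting:
    def test_isolated_triangle(self, catalog, triangle):
        vec = count_edge_orbits(triangle, EdgeRef("A", "B"), catalog)
        tri_orbit = clique_orbit_ids(catalog)[3]
        assert vec.orbit_count(tri_orbit) == 1
        assert vec.raw_counts.sum() == 1
        assert vec.orbit0 == 1

    def test_isolated_5_clique(self, catalog):
        net = InteractionNetwork(nx.complete_graph(5))
        vec = count_edge_orbits(net, EdgeRef(0, 1), catalog)
        ids = clique_orbit_ids(catalog)
        # C(3,1)=3 triangles, C(3,2)=3 4-cliques, C(3,3)=1 5-clique
        assert vec.orbit_count(ids[3]) == 3
        assert vec.orbit_count(ids[4]) == 3
        assert vec.orbit_count(ids[5]) == 1
        assert vec.raw_counts.sum() == 7

    def test_k10_subclique_totals(self, catalog):
        """Aggregated over all 45 edges, K10 contains its 3-, 4- and
        5-node sub-cliques 120, 210 and 252 times."""
        net = InteractionNetwork(nx.complete_graph(10))
        vec = count_edge_orbits(net, EdgeRef(0, 1), catalog)
        ids = clique_orbit_ids(catalog)
        per_edge = {k: vec.orbit_count(ids[k]) for k in (3, 4, 5)}
        assert per_edge == {3: 8, 4: 28, 5: 56}  # C(8,1), C(8,2), C(8,3)
        edges_per_clique = {3: 3, 4: 6, 5: 10}
        totals = {k: 45 * per_edge[k] // edges_per_clique[k] for k in per_edge}
        assert totals == {3: 120, 4: 210, 5: 252}
        # every edge of a clique is equivalent: no other orbit touched
        assert vec.raw_counts.sum() == sum(per_edge.values())

    def test_single_isolated_edge_all_zero(self, catalog):
        net = make_net([("A", "B")])
        vec = count_edge_orbits_bruteforce(net, EdgeRef("A", "B"), catalog)
        assert vec.raw_counts.sum() == 0 and vec.orbit0 == 1

    def test_star_center_leaf_hand_count(self, catalog):
        """Star with 5 leaves: the centre-leaf edge lies in C(4,1) 3-node
        paths, C(4,2) 4-node stars, C(4,3) 5-node stars."""
        net = InteractionNetwork(nx.star_graph(5))
        vec = count_edge_orbits_bruteforce(net, EdgeRef(0, 1), catalog)
        nz = sorted(int(c) for c in vec.raw_counts if c)
        assert nz == [4, 4, 6]

    @pytest.mark.parametrize("n,p,seed", [
        (8, 0.2, 0), (8, 0.5, 1), (8, 0.8, 2),
        (10, 0.5, 3), (12, 0.3, 4),
    ])
    def test_oracle_equivalence(self, catalog, n, p, seed):
        G = nx.gnp_random_graph(n, p, seed=seed)
        if G.number_of_edges() == 0:
            pytest.skip("empty draw")
        net = InteractionNetwork(G)
        rng = np.random.default_rng(seed)
        edges = list(G.edges())
        for i in rng.choice(len(edges), size=min(3, len(edges)), replace=False):
            e = EdgeRef(*edges[i])
            fast = count_edge_orbits(net, e, catalog)
            slow = count_edge_orbits_bruteforce(net, e, catalog)
            assert (fast.raw_counts == slow.raw_counts).all()
            assert fast.orbit0 == slow.orbit0 == 1

    def test_conservation_per_graphlet(self, catalog):
        """Summed over all edges, each orbit's count equals (graphlet
        occurrences) x (edges in that orbit per occurrence)."""
        G = nx.gnp_random_graph(9, 0.45, seed=7)
        net = InteractionNetwork(G)
        total = np.zeros(EGDV_LENGTH, dtype=np.int64)
        for e in net.edge_refs():
            total += count_edge_orbits(net, e, catalog).raw_counts
        # independent occurrence count per graphlet via subset scan
        from itertools import combinations
        occurrences = {}
        nodes = list(G.nodes)
        for k in (3, 4, 5):
            for S in combinations(nodes, k):
                sub = G.subgraph(S)
                if not nx.is_connected(sub):
                    continue
                pos = {n: i for i, n in enumerate(sorted(S))}
                pidx = catalog._pair_index[k]
                bits = 0
                for i, j in catalog._pairs[k]:
                    si = sorted(S)[i], sorted(S)[j]
                    if G.has_edge(*si):
                        bits |= 1 << pidx[(i, j)]
                canon, _ = catalog.canonicalize(k, bits)
                occurrences[(k, canon)] = occurrences.get((k, canon), 0) + 1
        for g in catalog.graphlets:
            if g.n_nodes == 2:
                continue
            occ = occurrences.get((g.n_nodes, g.bits), 0)
            for orb in g.orbits:
                oid = g.orbit_ids[orb[0]]
                assert total[oid - 1] == occ * len(orb)

    @pytest.mark.parametrize("n", [5, 6, 7, 8])
    def test_clique_edges_identical_egdv(self, catalog, n):
        net = InteractionNetwork(nx.complete_graph(n))
        ids = clique_orbit_ids(catalog)
        ref = None
        for e in net.edge_refs()[:4]:
            vec = count_edge_orbits_bruteforce(net, e, catalog)
            expected = {
                ids[3]: math.comb(n - 2, 1),
                ids[4]: math.comb(n - 2, 2),
                ids[5]: math.comb(n - 2, 3),
            }
            nz = {i + 1: int(c) for i, c in enumerate(vec.raw_counts) if c}
            assert nz == expected
            if ref is None:
                ref = vec.raw_counts
            assert (vec.raw_counts == ref).all()

    def test_planted_clique_and_hub_enrichment(self, catalog):
        """Clique-internal edges dominate the 5-clique orbit; hub edges
        dominate star-like orbits instead."""
        from ppiclass.synthetic import SyntheticSpec, gen_network
        spec = SyntheticSpec(seed=11, n_nodes=40, p_background=0.05,
                             clique_sizes=(6,), hub_degrees=(10,), bridges=())
        net, manifest = gen_network(spec)
        ids = clique_orbit_ids(catalog)
        k5 = ids[5]
        clique_edges = {EdgeRef(*e) for e in manifest["cliques"][0]["edges"]}
        hub_edges = [EdgeRef(*e) for e in manifest["hubs"][0]["edges"]]
        background = [EdgeRef(*e) for e in manifest["background_edges"]]
        clique_k5 = min(
            count_edge_orbits(net, e, catalog).orbit_count(k5)
            for e in clique_edges)
        bg_k5 = max(
            (count_edge_orbits(net, e, catalog).orbit_count(k5)
             for e in background), default=0)
        assert clique_k5 > bg_k5
        hub_vec = count_edge_orbits(net, hub_edges[0], catalog)
        # star-like counts exceed clique-internal counts on hub edges
        star_total = hub_vec.raw_counts.sum() - sum(
            hub_vec.orbit_count(ids[k]) for k in (3, 4, 5))
        clique_total = sum(hub_vec.orbit_count(ids[k]) for k in (3, 4, 5))
        assert star_total > clique_total


class TestEgdvTable:
    def test_round_trip_raw_and_normalized(self, catalog, tmp_path, triangle):
        import pandas as pd

        from ppiclass.graphlets import write_egdv_table
        vecs = [normalize_egdv(count_edge_orbits(triangle, e, catalog))
                for e in triangle.edge_refs()]
        raw_path = tmp_path / "egdv_raw.tsv"
        norm_path = tmp_path / "egdv_norm.tsv"
        write_egdv_table(vecs, raw_path)
        write_egdv_table(vecs, norm_path, normalized=True)
        raw = pd.read_csv(raw_path, sep="\t")
        norm = pd.read_csv(norm_path, sep="\t")
        assert list(raw.columns[:2]) == ["u", "v"]
        assert raw.shape == norm.shape == (3, 70)
        assert raw.iloc[0, 2:].sum() == vecs[0].raw_counts.sum()
        assert norm.iloc[0, 2:].sum() == pytest.approx(1.0)


class TestNormalize:
    def test_all_zero_stays_zero(self, catalog):
        vec = EdgeGraphletVector(EdgeRef("A", "B"),
                                 np.zeros(EGDV_LENGTH, dtype=np.int64))
        assert normalize_egdv(vec).normalized.sum() == 0

    def test_single_nonzero_normalizes_to_one(self, catalog):
        raw = np.zeros(EGDV_LENGTH, dtype=np.int64)
        raw[4] = 17
        vec = normalize_egdv(EdgeGraphletVector(EdgeRef("A", "B"), raw))
        assert vec.normalized[4] == pytest.approx(1.0)
        assert vec.normalized.sum() == pytest.approx(1.0)

    def test_log_then_normalize_arithmetic(self):
        raw = np.zeros(EGDV_LENGTH)
        raw[0] = math.e - 1          # ln -> 1
        raw[1] = math.e ** 2 - 1     # ln -> 2
        vec = normalize_egdv(EdgeGraphletVector(EdgeRef("A", "B"), raw))
        assert vec.normalized[0] == pytest.approx(1 / 3)
        assert vec.normalized[1] == pytest.approx(2 / 3)

    def test_normalized_sums_to_one_on_real_counts(self, catalog, triangle):
        vec = normalize_egdv(count_edge_orbits(triangle, EdgeRef("A", "B"),
                                               catalog))
        assert vec.normalized.sum() == pytest.approx(1.0)
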