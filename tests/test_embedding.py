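import numpy as np
import pytest
from scipy.stats import chisquare

import networkx as nx

from mirloc.datamodel import AssociationNetwork
from mirloc.embedding import (
    Node2vecParams,
    biased_random_walks,
    build_bipartite_graph,
    embed_network,
    skipgram_embed,
)


def _net(adjacency):
    adjacency = np.array(adjacency)
    return AssociationNetwork(
        tuple(f"m{i}" for i in range(adjacency.shape[0])),
        tuple(f"d{j}" for j in range(adjacency.shape[1])),
        "disease",
        adjacency,
    )


class TestBipartiteGraph:
    def test_identity_adjacency_gives_two_disjoint_edges(self):
        g = build_bipartite_graph(_net(np.eye(2, dtype=int)))
        assert g.number_of_nodes() == 4
        assert g.number_of_edges() == 2

    def test_all_zero_adjacency_gives_edgeless_graph(self):
        g = build_bipartite_graph(_net(np.zeros((2, 2), dtype=int)))
        assert g.number_of_edges() == 0

    def test_degree_counts_associations(self):
        g = build_bipartite_graph(_net([[1, 1]]))
        assert g.degree["mirna::m0"] == 2


class TestWalks:
    def test_single_edge_walk_alternates(self):
        g = nx.Graph([("a", "b")])
        params = Node2vecParams(num_walks=1, walk_length=3, seed=0)
        walks = biased_random_walks(g, params)
        assert ["a", "b", "a"] in walks and ["b", "a", "b"] in walks

    def test_isolated_node_yields_singleton_walk(self):
        g = nx.Graph()
        g.add_node("lonely")
        walks = biased_random_walks(g, Node2vecParams(num_walks=2, walk_length=5, seed=0))
        assert walks == [["lonely"], ["lonely"]]

    def test_walks_reproducible_from_seed(self):
        g = nx.gnp_random_graph(12, 0.4, seed=4)
        params = Node2vecParams(num_walks=3, walk_length=10, seed=9)
        assert biased_random_walks(g, params) == biased_random_walks(g, params)

    @pytest.mark.parametrize("p,q", [(1.0, 1.0)])
    def test_unit_p_q_matches_uniform_neighbour_choice(self, p, q):
        # on a 4-cycle every step has two neighbours; chi-square against 50/50
        g = nx.cycle_graph(4)
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in range(4)})
        params = Node2vecParams(num_walks=40, walk_length=80, p=p, q=q, seed=2)
        walks = biased_random_walks(g, params)
        counts = {}
        for w in walks:
            for prev, cur in zip(w, w[1:]):
                counts.setdefault(prev, {}).setdefault(cur, 0)
                counts[prev][cur] += 1
        observed = []
        for node, nbrs in counts.items():
            if len(nbrs) == 2:
                observed.append(sorted(nbrs.values()))
        flat = np.array(observed).ravel()
        assert flat.sum() >= 10_000
        stat, pval = chisquare(flat)
        assert pval > 0.01

    def test_second_order_return_parameter_discourages_backtracking(self):
        # p >> 1 makes returning to the previous node unlikely on a path graph
        g = nx.path_graph(3)
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in range(3)})
        params = Node2vecParams(num_walks=50, walk_length=20, p=100.0, q=1.0, seed=0)
        walks = biased_random_walks(g, params)
        backtracks = total = 0
        for w in walks:
            for a, b, c in zip(w, w[1:], w[2:]):
                if b == "v1":  # middle node has a real choice
                    total += 1
                    backtracks += a == c
        assert total > 100
        assert backtracks / total < 0.2


class TestSkipgram:
    def test_vector_length_and_coverage(self):
        g = nx.karate_club_graph()
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes})
        params = Node2vecParams(dim=16, num_walks=3, walk_length=15, window=3,
                                epochs=1, seed=0)
        walks = biased_random_walks(g, params)
        vecs = skipgram_embed(walks, params)
        assert set(vecs) == set(g.nodes)
        assert all(v.shape == (16,) for v in vecs.values())

    def test_same_seed_gives_identical_vectors(self):
        g = nx.cycle_graph(8)
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in range(8)})
        params = Node2vecParams(dim=8, num_walks=2, walk_length=10, window=2,
                                epochs=2, seed=5)
        walks = biased_random_walks(g, params)
        v1 = skipgram_embed(walks, params)
        v2 = skipgram_embed(walks, params)
        for n in v1:
            assert np.array_equal(v1[n], v2[n])

    def test_disconnected_cliques_separate_in_cosine_similarity(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes})
        params = Node2vecParams(dim=16, num_walks=20, walk_length=20, window=4,
                                epochs=5, seed=1)
        walks = biased_random_walks(g, params)
        vecs = skipgram_embed(walks, params)
        mat = np.stack([vecs[f"v{i}"] for i in range(10)])
        mat = mat / np.linalg.norm(mat, axis=1, keepdims=True)
        cos = mat @ mat.T
        block = np.zeros((10, 10), dtype=bool)
        block[:5, :5] = block[5:, 5:] = True
        np.fill_diagonal(block, False)
        intra = cos[block].mean()
        inter = cos[~block & ~np.eye(10, dtype=bool)].mean()
        assert intra > inter


class TestEmbedNetwork:
    def test_output_shape_and_order(self):
        net = _net(np.eye(3, dtype=int))
        params = Node2vecParams(dim=8, num_walks=2, walk_length=6, window=2,
                                epochs=1, seed=0)
        fm = embed_network(net, params)
        assert fm.values.shape == (3, 8)
        assert fm.mirna_ids == net.mirna_ids
        assert fm.branch == "disease"

    def test_isolated_mirna_gets_zero_vector(self):
        adj = np.array([[1, 0], [0, 0]])
        params = Node2vecParams(dim=8, num_walks=2, walk_length=6, window=2,
                                epochs=1, seed=0)
        fm = embed_network(_net(adj), params)
        # m1 has no edges: only singleton walks, never a context pair
        assert np.allclose(fm.values[1], 0.0)
        assert not np.allclose(fm.values[0], 0.0)
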