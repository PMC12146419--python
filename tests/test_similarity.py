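import numpy as np
import pytest

from mirloc.datamodel import AssociationNetwork, DiseaseDAG, MirnaSet
from mirloc.similarity import (
    ScoringScheme,
    disease_semantic_similarity,
    disease_set_similarity,
    fuse_similarities,
    functional_similarity_matrix,
    gip_similarity_matrix,
    semantic_contributions,
    semantic_value,
    sequence_similarity_matrix,
    smith_waterman_score,
)

from .oracles import dag_semantic_similarity, gip_entrywise, sw_affine_dp


def random_rna(rng, length):
    return "".join(rng.choice(list("ACGU"), size=length))


class TestSmithWaterman:
    def test_perfect_match_scores_length_times_match(self):
        s = ScoringScheme(1, -1, -2, -2)
        assert smith_waterman_score("ACGU", "ACGU", s) == 4

    def test_no_positive_alignment_scores_zero(self):
        assert smith_waterman_score("AAAA", "CCCC", ScoringScheme(1, -1, -2, -2)) == 0

    def test_classic_gapped_example(self):
        # optimal local alignment of these two requires an internal gap
        s = ScoringScheme(3, -3, -2, -2)
        assert smith_waterman_score("UGUUACGG", "GGUUGACUA", s) == 13

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman_score("", "ACGU")

    def test_matches_independent_dp_oracle_exactly(self):
        rng = np.random.default_rng(42)
        s = ScoringScheme(2.0, -1.5, -3.0, -1.0)
        for _ in range(200):
            a = random_rna(rng, rng.integers(1, 31))
            b = random_rna(rng, rng.integers(1, 31))
            got = smith_waterman_score(a, b, s)
            want = sw_affine_dp(a, b, s.match, s.mismatch, s.gap_open, s.gap_extend)
            assert got == pytest.approx(want, abs=0), (a, b)


class TestSequenceSimilarityMatrix:
    def test_single_a_match_normalises_to_one_quarter(self):
        m = MirnaSet(("x", "y"), {"x": "ACGU", "y": "AAAA"})
        sim = sequence_similarity_matrix(m)  # sp(x,y)=1, self scores 4 and 4
        assert sim.values[0, 1] == pytest.approx(0.25)

    def test_matches_oracle_matrix_on_random_22mers(self):
        rng = np.random.default_rng(7)
        ids = tuple(f"m{i}" for i in range(5))
        seqs = {i: random_rna(rng, 22) for i in ids}
        s = ScoringScheme()
        sim = sequence_similarity_matrix(MirnaSet(ids, seqs), s)
        for i, mi in enumerate(ids):
            for j, mj in enumerate(ids):
                sp = sw_affine_dp(seqs[mi], seqs[mj], s.match, s.mismatch,
                                  s.gap_open, s.gap_extend)
                sii = sw_affine_dp(seqs[mi], seqs[mi], s.match, s.mismatch,
                                   s.gap_open, s.gap_extend)
                sjj = sw_affine_dp(seqs[mj], seqs[mj], s.match, s.mismatch,
                                   s.gap_open, s.gap_extend)
                assert sim.values[i, j] == pytest.approx(sp / np.sqrt(sii * sjj), abs=1e-12)


class TestSemanticSimilarity:
    def test_chain_contributions(self, chain_dag):
        sv = semantic_contributions(chain_dag, "A", 0.5)
        assert sv.values == {"A": 1.0, "B": 0.5, "C": 0.25}
        assert semantic_value(sv) == pytest.approx(1.75)

    def test_diamond_uses_shortest_layer(self, diamond_dag):
        sv = semantic_contributions(diamond_dag, "A", 0.5)
        assert sv.values["D"] == pytest.approx(0.25)
        assert semantic_value(sv) == pytest.approx(2.25)

    def test_isolated_node_value_is_one(self):
        dag = DiseaseDAG(frozenset("A"), frozenset())
        assert semantic_value(semantic_contributions(dag, "A", 0.5)) == 1.0

    def test_chain_pair_value(self, chain_dag):
        # SV_A = {A:1,B:.5,C:.25}, SV_B = {B:1,C:.5}; shared {B,C}
        got = disease_semantic_similarity(chain_dag, "A", "B", 0.5)
        assert got == pytest.approx(2.25 / 3.25)

    def test_self_similarity_is_one(self, diamond_dag):
        assert disease_semantic_similarity(diamond_dag, "B", "B") == pytest.approx(1.0)

    def test_disjoint_components_share_nothing(self):
        dag = DiseaseDAG(frozenset("ABXY"), frozenset({("A", "B"), ("X", "Y")}))
        assert disease_semantic_similarity(dag, "A", "X") == 0.0

    def test_matches_bfs_oracle_on_random_dags(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(2, 16))
            nodes = [f"d{i}" for i in range(n)]
            edges = set()
            for i in range(1, n):
                for p in rng.choice(i, size=min(i, int(rng.integers(1, 3))), replace=False):
                    edges.add((nodes[i], nodes[int(p)]))
            dag = DiseaseDAG(frozenset(nodes), frozenset(edges))
            a, b = (nodes[int(k)] for k in rng.choice(n, size=2))
            got = disease_semantic_similarity(dag, a, b, 0.5)
            want = dag_semantic_similarity(edges, a, b, 0.5)
            assert got == pytest.approx(want, abs=1e-12)


class TestSetAndFunctionalSimilarity:
    def test_membership_dominates_max(self, chain_dag):
        assert disease_set_similarity(chain_dag, "A", ["A", "C"]) == 1.0

    def test_chain_set_value(self, chain_dag):
        got = disease_set_similarity(chain_dag, "A", ["B"])
        assert got == pytest.approx(2.25 / 3.25)

    def test_empty_set_rejected(self, chain_dag):
        with pytest.raises(ValueError):
            disease_set_similarity(chain_dag, "A", [])

    def _net(self, adjacency, diseases):
        return AssociationNetwork(
            tuple(f"m{i}" for i in range(len(adjacency))),
            tuple(diseases), "disease", np.array(adjacency),
        )

    def test_identical_singleton_sets(self, chain_dag):
        fs = functional_similarity_matrix(chain_dag, self._net([[1, 0], [1, 0]], "AB"))
        assert fs.values[0, 1] == pytest.approx(1.0)

    def test_cross_set_value_on_chain(self, chain_dag):
        fs = functional_similarity_matrix(chain_dag, self._net([[1, 0], [0, 1]], "AB"))
        assert fs.values[0, 1] == pytest.approx(2.25 / 3.25)

    def test_unannotated_mirna_gets_zero_offdiagonal(self, chain_dag):
        fs = functional_similarity_matrix(chain_dag, self._net([[1, 0], [0, 0]], "AB"))
        assert fs.values[0, 1] == 0.0
        assert fs.values[1, 1] == 1.0

    def test_unknown_disease_is_an_error(self, chain_dag):
        with pytest.raises(Exception, match="Z"):
            functional_similarity_matrix(chain_dag, self._net([[1]], "Z"))


class TestGip:
    def test_identity_profiles_give_exp_minus_two(self):
        net = AssociationNetwork(("m1", "m2"), ("d1", "d2"), "disease", np.eye(2, dtype=int))
        gip = gip_similarity_matrix(net)
        assert gip.values[0, 1] == pytest.approx(np.exp(-2))

    def test_identical_rows_give_one(self):
        net = AssociationNetwork(("m1", "m2"), ("d1", "d2"), "disease",
                                 np.array([[1, 0], [1, 0]]))
        assert gip_similarity_matrix(net).values[0, 1] == pytest.approx(1.0)

    def test_larger_bandwidth_scale_shrinks_offdiagonals(self):
        rng = np.random.default_rng(0)
        adj = rng.integers(0, 2, size=(6, 8))
        adj[0, 0] = 1  # ensure nonzero
        net = AssociationNetwork(tuple(f"m{i}" for i in range(6)),
                                 tuple(f"d{j}" for j in range(8)), "disease", adj)
        g1 = gip_similarity_matrix(net, 1.0).values
        g2 = gip_similarity_matrix(net, 2.0).values
        off = ~np.eye(6, dtype=bool) & (g1 < 1)
        assert (g2[off] < g1[off]).all()

    def test_matches_entrywise_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            adj = rng.integers(0, 2, size=(7, 9))
            if not adj.any():
                adj[0, 0] = 1
            net = AssociationNetwork(tuple(f"m{i}" for i in range(7)),
                                     tuple(f"d{j}" for j in range(9)), "disease", adj)
            got = gip_similarity_matrix(net, 1.3).values
            want = gip_entrywise(adj, 1.3)
            np.fill_diagonal(want, 1.0)
            assert np.allclose(got, want, atol=1e-12)


class TestFusion:
    def test_functional_wins_where_positive(self, tiny_bundle):
        synth, bundle = tiny_bundle
        fs = functional_similarity_matrix(synth.dataset.dag, synth.dataset.disease_net)
        gip = gip_similarity_matrix(synth.dataset.disease_net)
        fused = fuse_similarities(fs, gip)
        pos = fs.values > 0
        assert np.array_equal(fused.values[pos], fs.values[pos])
        assert np.array_equal(fused.values[~pos], gip.values[~pos])

    def test_fused_output_entries_come_from_inputs(self):
        ids = ("a", "b")
        fs_vals = np.array([[1.0, 0.0], [0.0, 1.0]])
        gip_vals = np.array([[1.0, 0.2], [0.2, 1.0]])
        from mirloc.datamodel import SimilarityMatrix

        fused = fuse_similarities(SimilarityMatrix(ids, fs_vals),
                                  SimilarityMatrix(ids, gip_vals))
        assert fused.values[0, 1] == 0.2
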