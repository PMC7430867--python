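"""Analysis protocols: rankings, delta, selection, classical comparison."""

from fractions import Fraction

import numpy as np
import pytest

from gtcentrality import (
    BinaryFeatureMatrix,
    GeneNetwork,
    align_to_network,
    classical_centralities,
    combined_weights,
    first_analysis,
    graph_game,
    overlap_matrix,
    rank_genes,
    second_analysis,
    shapley_bruteforce,
    unit_weights,
    network_shapley,
)
from gtcentrality.datasets import EXAMPLE_MATRIX_SHAPLEY, random_binary_matrix
from gtcentrality.microarray import MatrixError
from gtcentrality.network import NetworkError


def extended_case_matrix(network: GeneNetwork) -> BinaryFeatureMatrix:
    """The 4×3 example matrix padded with all-zero rows to 14 genes."""
    rows = {"g1": [1, 1, 0], "g2": [0, 0, 1], "g3": [1, 1, 1], "g4": [0, 0, 1]}
    entries = [rows.get(g, [0, 0, 0]) for g in network.nodes]
    return BinaryFeatureMatrix(network.nodes, ("s1", "s2", "s3"), np.array(entries))


class TestRanking:
    def test_sorted_descending_with_lexicographic_ties(self):
        r = rank_genes({"b": 1.0, "a": 1.0, "c": 2.0})
        assert r.gene_ids == ("c", "a", "b")
        assert [rank for _, _, rank in r.entries] == [1, 2, 3]

    def test_top_fraction_uses_floor(self):
        r = rank_genes({f"g{i}": float(i) for i in range(965)})
        assert len(r.top_fraction(0.05)) == 48

    def test_top_fraction_bounds(self):
        r = rank_genes({"a": 1.0})
        with pytest.raises(ValueError):
            r.top_fraction(0.0)


class TestFirstAnalysis:
    def test_top_two_are_the_leaf_hubs(self, example_network):
        ranking, selected = first_analysis(example_network, top_fraction=2 / 14)
        assert selected == ("g4", "g3")

    def test_single_node_network_selects_it(self):
        net = GeneNetwork(nodes=("only",), edges=frozenset())
        _, selected = first_analysis(net, top_fraction=1.0)
        assert selected == ("only",)

    def test_empty_network_rejected(self):
        with pytest.raises(NetworkError):
            first_analysis(GeneNetwork(nodes=(), edges=frozenset()))


class TestCombinedWeights:
    def test_weights_are_microarray_shapley(self, example_matrix):
        assert combined_weights(example_matrix, exact=True) == EXAMPLE_MATRIX_SHAPLEY

    def test_all_zero_matrix_gives_zero_weights(self):
        m = BinaryFeatureMatrix(("a", "b"), ("s1",), np.zeros((2, 1)))
        assert set(combined_weights(m).values()) == {0.0}

    def test_weights_sum_to_nonzero_column_fraction(self, rng):
        m = random_binary_matrix(6, 4, 0.3, rng)
        total = sum(combined_weights(m, exact=True).values())
        nonzero = int((m.entries.sum(axis=0) > 0).sum())
        assert total == Fraction(nonzero, 4)


class TestSecondAnalysis:
    def test_identical_matrices_give_zero_delta(self, example_network):
        case = extended_case_matrix(example_network)
        delta, ranking, _ = second_analysis(case, case, example_network, 0.5)
        assert set(delta.delta.values()) == {0}

    def test_zero_control_reduces_to_case_centrality(self, example_network):
        """With an all-zero control, δ is exactly the case-weighted
        centrality — verified against the brute-force solver."""
        case = extended_case_matrix(example_network)
        control = BinaryFeatureMatrix(
            case.gene_ids, case.sample_ids, np.zeros_like(case.entries)
        )
        delta, _, _ = second_analysis(case, control, example_network, 0.05, exact=True)
        from gtcentrality.network import WeightVector

        k = WeightVector(combined_weights(case, exact=True), example_network)
        direct = network_shapley(example_network, k, exact=True)
        brute = shapley_bruteforce(
            graph_game(example_network, k, exact=True), exact=True
        )
        assert delta.delta == dict(direct.scores) == dict(brute.scores)

    def test_delta_symmetric_under_case_control_swap(self, example_network, rng):
        case = extended_case_matrix(example_network)
        entries = (rng.random(case.entries.shape) < 0.3).astype(int)
        control = BinaryFeatureMatrix(case.gene_ids, case.sample_ids, entries)
        d1, r1, _ = second_analysis(case, control, example_network, 0.05)
        d2, r2, _ = second_analysis(control, case, example_network, 0.05)
        assert d1.delta == d2.delta
        assert r1 == r2

    def test_disconnected_gene_scores_its_own_weight(self, example_network):
        """A gene with no interactions still carries its empirical
        evidence: its combined score is exactly its microarray weight."""
        case = extended_case_matrix(example_network)
        entries = case.entries.copy()
        entries[example_network.nodes.index("g14")] = [1, 1, 1]
        case14 = BinaryFeatureMatrix(case.gene_ids, case.sample_ids, entries)
        w = combined_weights(case14, exact=True)
        from gtcentrality.network import WeightVector

        phi = network_shapley(
            example_network, WeightVector(w, example_network), exact=True
        )
        assert phi.scores["g14"] == w["g14"] > 0

    def test_gene_set_mismatch_rejected(self, example_matrix, example_network):
        with pytest.raises(NetworkError, match="align"):
            second_analysis(example_matrix, example_matrix, example_network, 0.05)

    def test_case_control_gene_mismatch_rejected(self, example_network):
        case = extended_case_matrix(example_network)
        other = BinaryFeatureMatrix(("x", "y"), ("s1",), np.array([[1], [0]]))
        with pytest.raises(MatrixError, match="share"):
            second_analysis(case, other, example_network, 0.05)

    def test_align_adds_isolated_nodes_and_zero_weights(self, example_matrix):
        net = GeneNetwork.from_edges([("g1", "g2")])
        aligned, weights = align_to_network(
            net, combined_weights(example_matrix)
        )
        assert set(aligned.nodes) == {"g1", "g2", "g3", "g4"}
        assert aligned.isolated_nodes() == {"g3", "g4"}
        assert weights["g3"] > 0  # carried over from the matrix


class TestClassicalCentralities:
    def test_star_center_tops_all_measures(self):
        net = GeneNetwork.from_edges([("hub", leaf) for leaf in ("a", "b", "c")])
        for ranking in classical_centralities(net).values():
            assert ranking.gene_ids[0] == "hub"

    def test_path_midpoint_has_highest_betweenness(self):
        net = GeneNetwork.from_edges([("g", "h"), ("h", "i")])
        ranking = classical_centralities(net)["betweenness"]
        assert ranking.gene_ids[0] == "h"

    def test_degree_ranking_of_example_network(self, example_network):
        ranking = classical_centralities(example_network)["degree"]
        # degree sequence: g4 has 4, then g1/g3 tie at 3 (broken by id)
        assert ranking.gene_ids[:3] == ("g4", "g1", "g3")


class TestOverlapMatrix:
    def test_identical_rankings_overlap_fully(self):
        r = rank_genes({f"g{i:03d}": float(i) for i in range(100)})
        m = overlap_matrix({"a": r, "b": r}, 0.10)
        assert m["a", "b"] == m["a", "a"] == 10

    def test_disjoint_top_sets_share_nothing(self):
        up = rank_genes({f"g{i:02d}": float(i) for i in range(10)})
        down = rank_genes({f"g{i:02d}": float(-i) for i in range(10)})
        m = overlap_matrix({"up": up, "down": down}, 0.2)
        assert m["up", "down"] == 0

    def test_symmetric_with_top_size_diagonal(self, rng):
        genes = [f"g{i:03d}" for i in range(100)]
        rankings = {
            name: rank_genes(dict(zip(genes, rng.random(100))))
            for name in ("m1", "m2", "m3")
        }
        m = overlap_matrix(rankings, 0.10)
        for a in m.measures:
            assert m[a, a] == 10
            for b in m.measures:
                assert m[a, b] == m[b, a]

    def test_exclusion_applies_before_truncation(self):
        scores = {f"g{i:02d}": float(10 - i) for i in range(10)}
        r = rank_genes(scores)
        m = overlap_matrix({"a": r, "b": r}, 0.5, exclude=["g00", "g01"])
        assert m["a", "a"] == 4  # floor(0.5 * 8) of the remaining universe

    def test_universe_mismatch_rejected(self):
        r1 = rank_genes({"a": 1.0})
        r2 = rank_genes({"b": 1.0})
        with pytest.raises(ValueError, match="universe"):
            overlap_matrix({"x": r1, "y": r2}, 0.5)
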