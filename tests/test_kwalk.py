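"""Absorbing-walk core checked against three independent oracles.

The oracles (tests/conftest.py) are: explicit enumeration of every absorbed
walk, a plain matrix-power transcription of the defining formulas, and the
Monte-Carlo simulator. None shares the implementation's convolution
recursion.
"""

import numpy as np
import pytest

from conftest import (
    direct_form_edge_relevance,
    enumerated_passages,
    enumerate_absorbed_walks,
    random_network,
)
from pathrewire.kwalk import (
    AbsorbingWalkProblem,
    NegligibleAbsorption,
    absorbed_length_distribution,
    edge_relevance,
    expected_edge_passages,
    simulate_walks,
    transition_probabilities,
)
from pathrewire.network import WeightedNetwork


class TestTransitionProbabilities:
    def test_uniform_triangle(self):
        net = WeightedNetwork(
            nodes=("A", "B", "C"),
            edges=(("A", "B"), ("A", "C"), ("B", "C")),
            edge_weights=np.array([0.5, 0.5, 0.5]),
        )
        P = transition_probabilities(net)
        off_diag = P[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off_diag, 0.5)

    def test_star_normalization(self):
        net = WeightedNetwork(
            nodes=("C", "L1", "L2", "L3"),
            edges=(("C", "L1"), ("C", "L2"), ("C", "L3")),
            edge_weights=np.array([0.2, 0.3, 0.5]),
        )
        P = transition_probabilities(net)
        c = net.node_index("C")
        np.testing.assert_allclose(
            [P[c, net.node_index(f"L{i}")] for i in (1, 2, 3)], [0.2, 0.3, 0.5]
        )
        for i in (1, 2, 3):
            assert P[net.node_index(f"L{i}"), c] == 1.0

    def test_isolated_node_zero_row(self):
        net = WeightedNetwork(
            nodes=("A", "B", "Z"), edges=(("A", "B"),), edge_weights=np.array([0.7])
        )
        P = transition_probabilities(net)
        np.testing.assert_array_equal(P[net.node_index("Z")], 0.0)

    def test_row_stochastic_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            net = random_network(rng, 7, 12)
            P = transition_probabilities(net)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)


class TestAbsorbedLengthDistribution:
    def test_path_graph_geometric_halving(self, path_network):
        prob = AbsorbingWalkProblem(
            network=path_network, seed_set={"A", "C"}, start="A", l_max=50
        )
        pL, mass = absorbed_length_distribution(prob)
        assert pL[1] == pytest.approx(0.5, abs=1e-12)   # L = 2
        assert pL[3] == pytest.approx(0.25, abs=1e-12)  # L = 4
        assert pL[::2].sum() == 0.0                      # odd lengths impossible
        assert mass <= 1.0

    def test_one_step_absorption(self):
        net = WeightedNetwork(
            nodes=("A", "B"), edges=(("A", "B"),), edge_weights=np.array([0.9])
        )
        prob = AbsorbingWalkProblem(network=net, seed_set={"A", "B"}, start="A", l_max=10)
        pL, mass = absorbed_length_distribution(prob)
        assert pL[0] == 1.0 and mass == 1.0

    def test_disconnected_seed_has_zero_mass(self):
        net = WeightedNetwork(
            nodes=("A", "B", "C", "D"),
            edges=(("A", "B"), ("C", "D")),
            edge_weights=np.array([0.5, 0.5]),
        )
        prob = AbsorbingWalkProblem(network=net, seed_set={"A", "C"}, start="A", l_max=20)
        _, mass = absorbed_length_distribution(prob)
        assert mass == 0.0
        with pytest.raises(NegligibleAbsorption):
            expected_edge_passages(prob)

    def test_matches_walk_enumeration(self, cycle_network):
        prob = AbsorbingWalkProblem(
            network=cycle_network, seed_set={"A", "C"}, start="A", l_max=10
        )
        pL, _ = absorbed_length_distribution(prob)
        pL_oracle, _ = enumerate_absorbed_walks(cycle_network, {"A", "C"}, "A", 10)
        np.testing.assert_allclose(pL, pL_oracle, atol=1e-12)

    def test_mass_monotone_in_l_max(self, cycle_network):
        masses = [
            absorbed_length_distribution(
                AbsorbingWalkProblem(
                    network=cycle_network, seed_set={"A", "C"}, start="A", l_max=l
                )
            )[1]
            for l in (2, 5, 10, 30)
        ]
        assert all(a <= b + 1e-15 for a, b in zip(masses, masses[1:]))
        assert all(0.0 <= m <= 1.0 for m in masses)


class TestExpectedEdgePassages:
    def test_path_weighted_net_flow_is_one(self, path_network):
        prob = AbsorbingWalkProblem(
            network=path_network, seed_set={"A", "C"}, start="A", l_max=50
        )
        E = expected_edge_passages(prob, mode="weighted")
        i = {g: path_network.node_index(g) for g in "ABC"}
        assert E[i["A"], i["B"]] - E[i["B"], i["A"]] == pytest.approx(1.0, abs=1e-9)
        assert E[i["B"], i["C"]] - E[i["C"], i["B"]] == pytest.approx(1.0, abs=1e-9)

    def test_path_literal_net_flow_counts_feasible_lengths(self, path_network):
        prob = AbsorbingWalkProblem(
            network=path_network, seed_set={"A", "C"}, start="A", l_max=50
        )
        E = expected_edge_passages(prob, mode="literal")
        i = {g: path_network.node_index(g) for g in "ABC"}
        # 25 feasible even lengths in 1..50, each contributing net flow 1
        assert E[i["A"], i["B"]] - E[i["B"], i["A"]] == pytest.approx(25.0, abs=1e-9)

    @pytest.mark.parametrize("mode", ["weighted", "literal"])
    @pytest.mark.parametrize("graph_seed", [0, 1, 2])
    def test_matches_walk_enumeration(self, mode, graph_seed):
        rng = np.random.default_rng(100 + graph_seed)
        net = random_network(rng, 5, 7)
        seeds = set(rng.choice(net.nodes, size=2, replace=False))
        start = sorted(seeds)[0]
        prob = AbsorbingWalkProblem(network=net, seed_set=seeds, start=start, l_max=8)
        E = expected_edge_passages(prob, mode=mode)
        E_oracle = enumerated_passages(net, seeds, start, 8, mode)
        np.testing.assert_allclose(E, E_oracle, atol=1e-10)

    def test_cycle_matches_monte_carlo(self, cycle_network):
        prob = AbsorbingWalkProblem(
            network=cycle_network, seed_set={"A", "C"}, start="A", l_max=50
        )
        E = expected_edge_passages(prob, mode="weighted")
        sim = simulate_walks(prob, 100_000, seed=7)
        diff = np.abs(E - sim["mean"])
        tol = 3 * sim["se"] + 1e-3
        assert (diff <= tol).all()

    def test_invalid_mode_rejected(self, path_network):
        prob = AbsorbingWalkProblem(
            network=path_network, seed_set={"A", "C"}, start="A", l_max=10
        )
        with pytest.raises(ValueError, match="mode"):
            expected_edge_passages(prob, mode="bogus")


class TestEdgeRelevance:
    def test_path_graph_unit_relevance(self, path_network):
        rel = edge_relevance(path_network, {"A", "C"})
        assert rel[("A", "B")] == pytest.approx(1.0, abs=1e-9)
        assert rel[("B", "C")] == pytest.approx(1.0, abs=1e-9)

    def test_unreachable_component_zero_relevance(self):
        net = WeightedNetwork(
            nodes=("A", "B", "C", "X", "Y"),
            edges=(("A", "B"), ("B", "C"), ("X", "Y")),
            edge_weights=np.array([0.5, 0.5, 0.8]),
        )
        rel = edge_relevance(net, {"A", "C"})
        assert rel[("X", "Y")] == 0.0

    @pytest.mark.parametrize("graph_seed", [0, 1, 2, 3, 4])
    def test_matches_direct_form_oracle(self, graph_seed):
        rng = np.random.default_rng(200 + graph_seed)
        net = random_network(rng, 6, 8)
        seeds = set(rng.choice(net.nodes, size=3, replace=False))
        rel = edge_relevance(net, seeds, l_max=20)
        oracle = direct_form_edge_relevance(net, seeds, l_max=20)
        for e in net.edges:
            assert rel[e] == pytest.approx(oracle[e], abs=1e-9)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(33)
        net = random_network(rng, 6, 9)
        seeds = set(net.nodes[:2])
        rel = edge_relevance(net, seeds, l_max=15)
        # rename every node; values must follow the permutation untouched
        rename = {g: f"z_{g}" for g in net.nodes}
        renamed_nodes = tuple(sorted(rename[g] for g in net.nodes))
        remapped = sorted(
            (tuple(sorted((rename[a], rename[b]))), w)
            for (a, b), w in zip(net.edges, net.edge_weights)
        )
        net2 = WeightedNetwork(
            nodes=renamed_nodes,
            edges=tuple(e for e, _ in remapped),
            edge_weights=np.array([w for _, w in remapped]),
        )
        rel2 = edge_relevance(net2, {rename[s] for s in seeds}, l_max=15)
        for (a, b), v in rel.relevance.items():
            assert rel2[tuple(sorted((rename[a], rename[b])))] == pytest.approx(v, abs=1e-12)

    def test_skipped_start_renormalizes_remaining(self):
        # seed D sits in a separate component: its start is skipped, the
        # remaining two starts are reweighted to 1/2 each
        net = WeightedNetwork(
            nodes=("A", "B", "C", "D", "E"),
            edges=(("A", "B"), ("B", "C"), ("D", "E")),
            edge_weights=np.array([0.5, 0.5, 0.5]),
        )
        rel = edge_relevance(net, {"A", "C", "D"})
        assert rel.skipped_starts == ("D",)
        assert sum(rel.start_weights.values()) == pytest.approx(1.0)
        assert set(rel.start_weights) == {"A", "C"}

    def test_all_starts_skipped_raises(self):
        net = WeightedNetwork(
            nodes=("A", "B", "C", "D"),
            edges=(("A", "B"), ("C", "D")),
            edge_weights=np.array([0.5, 0.5]),
        )
        with pytest.raises(NegligibleAbsorption):
            edge_relevance(net, {"A", "C"})

    def test_small_seed_set_rejected(self, path_network):
        with pytest.raises(ValueError, match=">= 2"):
            edge_relevance(path_network, {"A"})


class TestSimulateWalks:
    def test_path_length_two_within_three_se(self, path_network):
        prob = AbsorbingWalkProblem(
            network=path_network, seed_set={"A", "C"}, start="A", l_max=50
        )
        sim = simulate_walks(prob, 100_000, seed=5)
        se = np.sqrt(0.5 * 0.5 / 100_000)
        assert abs(sim["pL"][1] - 0.5) <= 3 * se

    def test_zero_walks_rejected(self, path_network):
        prob = AbsorbingWalkProblem(
            network=path_network, seed_set={"A", "C"}, start="A", l_max=10
        )
        with pytest.raises(ValueError):
            simulate_walks(prob, 0, seed=1)

    def test_same_seed_reproducible(self, cycle_network):
        prob = AbsorbingWalkProblem(
            network=cycle_network, seed_set={"A", "C"}, start="A", l_max=30
        )
        s1 = simulate_walks(prob, 2000, seed=42)
        s2 = simulate_walks(prob, 2000, seed=42)
        np.testing.assert_array_equal(s1["mean"], s2["mean"])
        assert s1["n_absorbed"] == s2["n_absorbed"]
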