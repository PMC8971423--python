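import itertools
import math

import networkx as nx
import pytest

from entroloc import (
    ContactNetwork,
    InfectionSnapshot,
    adjacency_entropy,
    compute_entropy_table,
    contribution,
    core_convex_set,
    infected_subgraph,
    infection_degree,
    infection_intensity,
    intensity_entropy,
    neighborhood_entropy,
    slbne,
)
from conftest import random_infected_instance
from oracles import naive_core_set, naive_scores

SIG1 = 1 / (1 + math.exp(-1))  # sigmoid of degree 1

# Frozen hand-oracle values for the fully infected path a-b-c: xi from the
# degree-corrected infected fraction, eta/psi/AE over infected neighbors.
PATH_XI_LEAF = 0.7310585786300049
PATH_IE_LEAF = 0.33039540582319815
PATH_ETA_LEAF = 0.44039853898894116
PATH_ETA_CENTER = 1.4621171572600098
PATH_PSI_LEAF_TO_CENTER = 0.6839397205857212
PATH_PSI_CENTER_TO_LEAF = 1.1353352832366128
PATH_AE_LEAF = 0.37483926250069305
PATH_AE_CENTER = -0.4158015884929955
PATH_NE_LEAF = -0.9467423607920995
PATH_NE_CENTER = -1.0609622376346741


class TestInfectionIntensity:
    def test_all_neighbors_uninfected(self):
        net = ContactNetwork.from_edges([("a", "b"), ("a", "c")])
        snap = InfectionSnapshot(network=net, infected=frozenset({"a"}))
        assert infection_intensity("a", snap) == 0.0

    def test_degree_one_infected_neighbor(self):
        net = ContactNetwork.from_edges([("a", "b")])
        snap = InfectionSnapshot(network=net, infected=frozenset({"a", "b"}))
        assert infection_intensity("a", snap) == pytest.approx(SIG1, abs=1e-12)

    def test_degree_four_three_infected(self):
        net = ContactNetwork.from_edges([("a", x) for x in "bcde"])
        snap = InfectionSnapshot(network=net, infected=frozenset({"a", "b", "c", "d"}))
        assert infection_intensity("a", snap) == pytest.approx(
            0.75 / (1 + math.exp(-4)), abs=1e-12
        )

    def test_isolated_node_warns_and_returns_zero(self):
        net = ContactNetwork.from_edges([("a", "b")], nodes=["z"])
        snap = InfectionSnapshot(network=net, infected=frozenset({"z"}))
        with pytest.warns(UserWarning):
            assert infection_intensity("z", snap) == 0.0

    def test_monotone_in_infected_neighbor_count(self):
        """At fixed degree, xi never decreases as more neighbors are infected."""
        for deg in range(1, 21):
            leaves = [f"l{k}" for k in range(deg)]
            net = ContactNetwork.from_edges([("c", l) for l in leaves])
            prev = -1.0
            for n_inf in range(deg + 1):
                infected = frozenset(["c"] + leaves[:n_inf])
                snap = InfectionSnapshot(network=net, infected=infected)
                xi = infection_intensity("c", snap)
                assert xi >= prev
                prev = xi


class TestIntensityEntropy:
    @pytest.mark.parametrize(
        "xi,expected",
        [(0.0, 0.0), (0.5, 0.5), (PATH_XI_LEAF, PATH_IE_LEAF)],
    )
    def test_values(self, xi, expected):
        assert intensity_entropy(xi) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            intensity_entropy(bad)


class TestInfectionDegree:
    def test_three_path(self, three_path):
        _, snap = three_path
        assert infection_degree("a", snap) == pytest.approx(PATH_ETA_LEAF, abs=1e-12)
        assert infection_degree("b", snap) == pytest.approx(PATH_ETA_CENTER, abs=1e-12)

    def test_no_infected_neighbors(self):
        net = ContactNetwork.from_edges([("a", "b")])
        snap = InfectionSnapshot(network=net, infected=frozenset({"a"}))
        assert infection_degree("a", snap) == 0.0

    def test_star_center_with_infected_leaves(self, star_factory):
        net = star_factory(6)
        infected = frozenset(["c"] + [f"l{k}" for k in range(6)])
        snap = InfectionSnapshot(network=net, infected=infected)
        # each leaf has degree 1 and xi = sigmoid(1)
        assert infection_degree("c", snap) == pytest.approx(6 * SIG1, abs=1e-10)

    def test_degree_weights_use_full_graph_degree(self):
        # neighbor degrees 3, 2 -> weights 1/3, 1/2 even with uninfected mixed in
        net = ContactNetwork.from_edges(
            [("j", "x"), ("j", "y"), ("x", "u1"), ("x", "u2"), ("y", "u1")]
        )
        snap = InfectionSnapshot(network=net, infected=frozenset({"j", "x", "y"}))
        xi_x = infection_intensity("x", snap)
        xi_y = infection_intensity("y", snap)
        assert infection_degree("j", snap) == pytest.approx(
            xi_x / 3 + xi_y / 2, abs=1e-12
        )


class TestContribution:
    def test_only_infected_neighbor_cancels_to_reciprocal_intensity(self):
        net = ContactNetwork.from_edges([("i", "j"), ("j", "u")])
        snap = InfectionSnapshot(network=net, infected=frozenset({"i", "j"}))
        xi_i = infection_intensity("i", snap)
        assert contribution("i", "j", snap) == pytest.approx(1 / xi_i, abs=1e-10)

    def test_three_path_values(self, three_path):
        _, snap = three_path
        assert contribution("a", "b", snap) == pytest.approx(
            PATH_PSI_LEAF_TO_CENTER, abs=1e-12
        )
        assert contribution("b", "a", snap) == pytest.approx(
            PATH_PSI_CENTER_TO_LEAF, abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_contribution_sum_identity(self, seed):
        """sum over infected i in N(j) of psi_i(j) = (sum 1/|N(i)|) / eta_j."""
        net, snap = random_infected_instance(seed, n_max=30)
        for j in snap.infected:
            contributors = [
                i for i in snap.infected_neighbors(j)
            ]
            if not contributors:
                continue
            eta_j = infection_degree(j, snap)
            lhs = sum(contribution(i, j, snap) for i in contributors)
            rhs = sum(1 / net.degree(i) for i in contributors) / eta_j
            assert lhs == pytest.approx(rhs, abs=1e-9)


class TestAdjacencyEntropy:
    def test_no_infected_neighbors_is_zero(self):
        net = ContactNetwork.from_edges([("a", "b")])
        snap = InfectionSnapshot(network=net, infected=frozenset({"a"}))
        assert adjacency_entropy("a", snap) == 0.0

    def test_three_path_leaf_and_center(self, three_path):
        _, snap = three_path
        assert adjacency_entropy("a", snap) == pytest.approx(PATH_AE_LEAF, abs=1e-12)
        # psi > 1 at the center: negative entropy, not clamped
        assert adjacency_entropy("b", snap) == pytest.approx(PATH_AE_CENTER, abs=1e-12)


class TestNeighborhoodEntropy:
    def test_alpha_zero_reduces_to_adjacency_entropy(self, three_path):
        _, snap = three_path
        assert neighborhood_entropy("a", snap, alpha=0.0) == pytest.approx(
            adjacency_entropy("a", snap), abs=1e-12
        )

    def test_three_path_scores(self, three_path):
        _, snap = three_path
        assert neighborhood_entropy("a", snap) == pytest.approx(PATH_NE_LEAF, abs=1e-12)
        assert neighborhood_entropy("b", snap) == pytest.approx(PATH_NE_CENTER, abs=1e-12)


class TestCoreConvexSet:
    def test_three_path_leaves_are_core(self, three_path):
        _, snap = three_path
        table = compute_entropy_table(snap)
        assert core_convex_set(snap, table).members == {"a", "c"}

    def test_symmetric_cycle_falls_back_to_single_node(self):
        net = ContactNetwork.from_edges(
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")]
        )
        snap = InfectionSnapshot(network=net, infected=net.nodes)
        table = compute_entropy_table(snap)
        core = core_convex_set(snap, table)
        assert core.fallback_used
        assert core.members == {"a"}  # smallest id among the all-way tie

    def test_isolated_infected_node_is_core(self):
        net = ContactNetwork.from_edges([("a", "b")], nodes=["z"])
        snap = InfectionSnapshot(network=net, infected=frozenset({"z", "a", "b"}))
        table = compute_entropy_table(snap)
        assert "z" in core_convex_set(snap, table).members

    @pytest.mark.parametrize("seed", range(15))
    def test_strict_core_members_not_adjacent_in_infected_subgraph(self, seed):
        net, snap = random_infected_instance(seed)
        table = compute_entropy_table(snap)
        core = core_convex_set(snap, table)
        if core.fallback_used:
            return
        sub = infected_subgraph(snap)
        for u, v in itertools.combinations(sorted(core.members), 2):
            assert frozenset((u, v)) not in sub.edges


class TestPipelineAgainstNaiveOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_scores_and_core_match(self, seed):
        net, snap = random_infected_instance(seed)
        table = compute_entropy_table(snap)
        expected = naive_scores(net.graph, snap.infected)
        for i in snap.infected:
            xi, ie, eta, ae, ne = expected[i]
            assert table.xi(i) == pytest.approx(xi, abs=1e-9)
            assert table.ie(i) == pytest.approx(ie, abs=1e-9)
            assert table.eta(i) == pytest.approx(eta, abs=1e-9)
            assert table.ae(i) == pytest.approx(ae, abs=1e-9)
            assert table.ne(i) == pytest.approx(ne, abs=1e-9)
        assert core_convex_set(snap, table).members == naive_core_set(
            net.graph, snap.infected
        )


class TestSlbne:
    def test_single_infected_node(self):
        net = ContactNetwork.from_edges([("a", "b")])
        snap = InfectionSnapshot(network=net, infected=frozenset({"a"}))
        assert slbne(net, snap).predicted == {"a"}

    def test_three_path(self, three_path):
        net, snap = three_path
        result = slbne(net, snap)
        assert result.predicted == {"a", "c"}
        assert result.predicted == result.core_part

    def test_deterministic(self, three_path):
        net, snap = three_path
        assert slbne(net, snap).predicted == slbne(net, snap).predicted

    @pytest.mark.parametrize("seed", [3, 11, 27])
    def test_invariant_under_relabeling(self, seed):
        """Renaming every node permutes, but does not change, the prediction."""
        net, snap = random_infected_instance(seed, n_max=35)
        mapping = {v: f"x{v}" for v in net.nodes}
        relabeled = ContactNetwork(nx.relabel_nodes(net.graph, mapping))
        snap2 = InfectionSnapshot(
            network=relabeled,
            infected=frozenset(mapping[v] for v in snap.infected),
        )
        p1 = {mapping[v] for v in slbne(net, snap).predicted}
        assert p1 == set(slbne(relabeled, snap2).predicted)
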