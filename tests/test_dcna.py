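import networkx as nx
import numpy as np
import pytest

from dyncon.contacts import ContactMap
from dyncon.dcna import (build_consensus_network, community_delta,
                         difference_map, girvan_newman_partition,
                         hydrolysis_cycle_deltas, modularity, Partition)
from dyncon.synthetic import exhaustive_best_partition


def cmap_from(matrix, state="s"):
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    return ContactMap(state=state, residue_index=np.arange(n),
                      labels=[f"A:{2 * i + 1}" for i in range(n)],
                      matrix=m, cutoff=4.5, n_frames=100)


def maps_with_pair(ps):
    """Three 2-residue maps whose (0,1) probabilities are ``ps``."""
    out = []
    for k, p in enumerate(ps):
        m = np.array([[0.0, p], [p, 0.0]])
        out.append(cmap_from(m, state=f"s{k}"))
    return out


class TestConsensus:
    def test_edge_when_all_states_pass(self):
        cons = build_consensus_network(maps_with_pair([0.95, 0.92, 0.91]), 0.90)
        assert cons.graph.has_edge(0, 1)
        assert cons.graph[0][1]["weight"] == 1.0

    def test_edge_absent_if_one_state_fails(self):
        cons = build_consensus_network(maps_with_pair([0.95, 0.95, 0.80]), 0.90)
        assert not cons.graph.has_edge(0, 1)

    def test_threshold_at_boundary_is_inclusive(self):
        cons = build_consensus_network(maps_with_pair([0.90, 0.90, 0.90]), 0.90)
        assert cons.graph.has_edge(0, 1)

    def test_threshold_zero_is_nonzero_intersection(self):
        rng = np.random.default_rng(0)
        mats = []
        for _ in range(3):
            a = np.triu((rng.random((5, 5)) < 0.5) * rng.random((5, 5)), 1)
            mats.append(a + a.T)
        cons = build_consensus_network([cmap_from(m) for m in mats], 0.0)
        expected = {(i, j) for i in range(5) for j in range(i + 1, 5)}
        # p >= 0 holds everywhere, so threshold 0 keeps every pair
        assert set(map(tuple, map(sorted, cons.graph.edges))) == expected

    def test_subtraction_mode_tracks_reference_state(self):
        # stable in apo and barely changing elsewhere -> kept
        cons = build_consensus_network(maps_with_pair([0.95, 0.90, 0.92]),
                                       0.90, mode="subtraction")
        assert cons.graph.has_edge(0, 1)
        # large change vs apo -> dropped even though apo passes
        cons2 = build_consensus_network(maps_with_pair([0.95, 0.50, 0.92]),
                                        0.90, mode="subtraction")
        assert not cons2.graph.has_edge(0, 1)

    def test_single_state_rejected(self):
        with pytest.raises(ValueError):
            build_consensus_network(maps_with_pair([0.9])[:1])


class TestModularity:
    def test_barbell_hand_value(self):
        g = nx.barbell_graph(4, 0)
        cliques = [list(range(4)), list(range(4, 8))]
        assert modularity(g, cliques) == pytest.approx(12 / 13 - 0.5)

    def test_single_community_is_zero(self):
        g = nx.erdos_renyi_graph(8, 0.5, seed=1)
        assert modularity(g, [list(g.nodes)]) == pytest.approx(0.0)

    def test_singletons_negative(self):
        g = nx.path_graph(5)
        q = modularity(g, [[n] for n in g.nodes])
        assert q == pytest.approx(-sum((d / 8) ** 2 for _, d in g.degree))
        assert q < 0

    def test_agrees_with_networkx(self):
        g = nx.erdos_renyi_graph(10, 0.4, seed=3)
        parts = [[0, 1, 2, 3], [4, 5, 6], [7, 8, 9]]
        assert modularity(g, parts) == pytest.approx(
            nx.community.modularity(g, [set(p) for p in parts]))

    def test_edgeless_graph_is_zero(self):
        g = nx.empty_graph(4)
        assert modularity(g, [[n] for n in g.nodes]) == 0.0


class TestGirvanNewman:
    def test_two_cliques_with_bridge(self):
        g = nx.barbell_graph(4, 0)
        part = girvan_newman_partition(g)
        assert part.n_communities == 2
        assert part.communities() == [[0, 1, 2, 3], [4, 5, 6, 7]]
        assert part.modularity == pytest.approx(12 / 13 - 0.5)
        # exhaustive search confirms the clique split is globally optimal
        best, qstar = exhaustive_best_partition(g)
        assert part.modularity == pytest.approx(qstar)

    def test_single_clique_stays_whole(self):
        g = nx.complete_graph(5)
        part = girvan_newman_partition(g)
        assert part.n_communities == 1
        _, qstar = exhaustive_best_partition(g)
        assert part.modularity == pytest.approx(qstar)  # no split improves Q

    def test_components_are_never_merged(self):
        g = nx.Graph()
        for base in (0, 10, 20):
            nx.add_path(g, [base, base + 1, base + 2])
        part = girvan_newman_partition(g)
        assert part.n_communities >= 3
        for comm in part.communities():
            assert len({n // 10 for n in comm}) == 1

    def test_edgeless_network_singletons_with_warning(self):
        g = nx.empty_graph(3)
        with pytest.warns(UserWarning, match="edgeless"):
            part = girvan_newman_partition(g)
        assert part.n_communities == 3
        assert part.modularity == 0.0

    def test_trace_records_accepted_partitions(self):
        part = girvan_newman_partition(nx.barbell_graph(4, 0))
        assert part.trace[0] == pytest.approx(0.0)
        assert max(part.trace) == pytest.approx(part.modularity)


class TestDifferenceAndDelta:
    def test_difference_values(self):
        d = difference_map(cmap_from([[0, 0.9], [0.9, 0]]),
                           cmap_from([[0, 0.2], [0.2, 0]]))
        assert d[0, 1] == pytest.approx(0.7)

    def test_identical_maps_zero(self):
        m = cmap_from([[0, 0.4], [0.4, 0]])
        assert np.all(difference_map(m, m) == 0)

    def test_swapping_direction_negates(self):
        a = cmap_from(np.array([[0, 0.9], [0.9, 0]]))
        b = cmap_from(np.array([[0, 0.3], [0.3, 0]]))
        assert np.allclose(difference_map(a, b), -difference_map(b, a))

    def test_community_delta_example(self):
        # communities A = {0,1}, B = {2,3}; d02=+0.5, d03=-0.2, d12=+0.1
        d = np.zeros((4, 4))
        d[0, 2] = d[2, 0] = 0.5
        d[0, 3] = d[3, 0] = -0.2
        d[1, 2] = d[2, 1] = 0.1
        part = Partition(community_of={0: 0, 1: 0, 2: 1, 3: 1},
                         n_communities=2, modularity=0.0)
        dp, ids = community_delta(d, part, np.arange(4))
        assert dp[0, 1] == pytest.approx(0.4)
        assert dp[1, 0] == pytest.approx(0.4)  # unordered pairs, symmetric

    def test_zero_difference_all_zero(self):
        part = Partition(community_of={0: 0, 1: 0, 2: 1, 3: 1},
                         n_communities=2, modularity=0.0)
        dp, _ = community_delta(np.zeros((4, 4)), part, np.arange(4))
        assert np.all(dp == 0)

    def test_intra_community_pairs_not_counted(self):
        d = np.zeros((4, 4))
        d[0, 1] = d[1, 0] = 0.8  # same community: must not appear
        part = Partition(community_of={0: 0, 1: 0, 2: 1, 3: 1},
                         n_communities=2, modularity=0.0)
        dp, _ = community_delta(d, part, np.arange(4))
        assert np.all(dp == 0)


class TestHydrolysisCycle:
    def _random_maps(self, seed, n=8):
        rng = np.random.default_rng(seed)
        maps = {}
        for s in ("apo", "ATP", "ADP"):
            a = np.triu(rng.random((n, n)), 1)
            maps[s] = cmap_from(a + a.T, state=s)
        part = Partition(
            community_of={i: i % 3 for i in range(n)},
            n_communities=3, modularity=0.0)
        return maps, part

    def test_cycle_telescopes_to_zero(self):
        maps, part = self._random_maps(5)
        deltas = hydrolysis_cycle_deltas(maps, part)
        total = sum(d.delta_p for d in deltas)
        assert np.abs(total).max() < 1e-12

    def test_equal_maps_give_mutual_negatives(self):
        maps, part = self._random_maps(6)
        maps["ATP"] = cmap_from(maps["apo"].matrix, state="ATP")
        d1, d2, d3 = hydrolysis_cycle_deltas(maps, part)
        assert np.all(d1.delta_p == 0)          # apo->ATP with equal maps
        assert np.allclose(d2.delta_p, -d3.delta_p)

    def test_missing_state_rejected(self):
        maps, part = self._random_maps(7)
        del maps["ADP"]
        with pytest.raises(ValueError, match="ADP"):
            hydrolysis_cycle_deltas(maps, part)

    def test_direction_antisymmetry(self):
        maps, part = self._random_maps(8)
        fwd, _ = community_delta(
            difference_map(maps["ATP"], maps["apo"]), part,
            maps["apo"].residue_index)
        rev, _ = community_delta(
            difference_map(maps["apo"], maps["ATP"]), part,
            maps["apo"].residue_index)
        assert np.allclose(fwd, -rev)


class TestCycleClosureProperty:
    """Telescoping holds for arbitrary contact probabilities, not just
    the fixtures above."""

    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @given(arrays(np.float64, (3, 5, 5),
                  elements=st.floats(0.0, 1.0, allow_nan=False)))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_any_three_maps_telescope(self, raw):
        maps = {}
        for k, s in enumerate(("apo", "ATP", "ADP")):
            m = np.triu(raw[k], 1)
            maps[s] = cmap_from(m + m.T, state=s)
        part = Partition(community_of={i: i % 2 for i in range(5)},
                         n_communities=2, modularity=0.0)
        deltas = hydrolysis_cycle_deltas(maps, part)
        assert np.abs(sum(d.delta_p for d in deltas)).max() < 1e-12
        for d in deltas:
            assert np.allclose(d.delta_p, d.delta_p.T)


class TestPlantedBlockRecovery:
    def test_block_structured_graphs_recovered(self):
        """3 planted blocks of 10 nodes (intra 0.9, inter 0.05) are found."""
        rng_ok = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            g = nx.Graph()
            g.add_nodes_from(range(30))
            for i in range(30):
                for j in range(i + 1, 30):
                    p = 0.9 if i // 10 == j // 10 else 0.05
                    if rng.random() < p:
                        g.add_edge(i, j)
            part = girvan_newman_partition(g)
            want = [list(range(k, k + 10)) for k in (0, 10, 20)]
            if part.communities() == want:
                rng_ok += 1
        assert rng_ok / n_seeds >= 0.95
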