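"""System, node and edge measure panel against hand counts and brute-force
path-enumeration oracles."""

import math

import numpy as np
import pytest

from ctrlnet import (
    DirectedNetwork,
    InputConfiguration,
    OutputConfiguration,
    classify_config_nodes,
    controlling_matrix,
    driver_similarity,
    edge_measures,
    map_inputs,
    map_outputs,
    mean_relative_degree,
    node_measures,
    observing_matrix,
    reachability_matrices,
    system_measures,
)
from ctrlnet.characterization import edge_pair_counts
from ctrlnet.fixtures import cycle, erdos_renyi_directed, star
from ctrlnet.graph_core import generic_rank_oracle, StateSpaceModel

from conftest import (
    betweenness_by_path_enumeration,
    closeness_by_bfs,
    edge_betweenness_by_path_enumeration,
    random_nets,
)


def _configs(net):
    return map_inputs(net), map_outputs(net)


class TestSystemMeasures:
    def test_chain_panel(self, chain3):
        sm = system_measures(chain3, *_configs(chain3))
        assert sm.controllability == 1 and sm.observability == 1
        assert sm.n_nodes == 3 and sm.n_edges == 2
        assert sm.diameter == 2
        assert sm.density == pytest.approx(2 / 9)
        assert sm.percent_sym == 0.0
        assert sm.percent_loops == 0.0
        assert sm.relative_degree == 2

    def test_symmetric_pair_percentage(self):
        net = DirectedNetwork([1, 2, 3], [(1, 2), (2, 1), (1, 3)])
        sm = system_measures(net, *_configs(net))
        # 1 symmetric of 2 connected unordered pairs
        assert sm.percent_sym == pytest.approx(50.0)

    def test_self_loop_percentage(self):
        net = DirectedNetwork([1, 2], [(1, 1), (1, 2)])
        sm = system_measures(net, *_configs(net))
        assert sm.percent_loops == pytest.approx(50.0)

    def test_edge_count_decomposition_on_random_networks(self):
        """E = connected pairs + symmetric pairs + self-loops, always."""
        for net in random_nets(40, n_max=10, seed0=800):
            connected, symmetric, loops = edge_pair_counts(net)
            assert net.n_edges == connected + symmetric + loops

    def test_degree_statistics_on_cycle(self):
        net = cycle(4)
        sm = system_measures(net, *_configs(net))
        assert sm.degree_variance == 0.0          # all total degrees equal 2
        assert sm.freeman_centrality == 0.0
        # every edge joins degree-(1,1) endpoints: correlations undefined
        assert math.isnan(sm.pearson_in_in)

    def test_pearson_out_in_is_classical_assortativity_sign(self):
        # the hub (out-degree 3) feeds low in-degree leaves while the
        # low-out-degree node 5 feeds the high in-degree node 4 ->
        # disassortative out-in correlation over edges
        net = DirectedNetwork([1, 2, 3, 4, 5],
                              [(1, 2), (1, 3), (1, 4), (5, 4)])
        sm = system_measures(net, *_configs(net))
        assert sm.pearson_out_in < 0


class TestNodeMeasures:
    def test_chain_values(self, chain3):
        nm = node_measures(chain3, *_configs(chain3))
        assert nm.loc[1, "closeness"] == pytest.approx(2 / 3)
        assert nm.loc[2, "betweenness"] == pytest.approx(1.0)
        assert nm.loc[1, "control_centrality"] == 3
        assert nm.loc[1, "observe_centrality"] == 1
        assert nm.loc[3, "scott"] == pytest.approx(0.5)

    def test_cycle_pagerank_uniform(self, cycle3):
        nm = node_measures(cycle3)
        assert np.allclose(nm["pagerank"], 1 / 3, atol=1e-9)

    def test_pagerank_sums_to_one(self):
        for net in random_nets(15, n_max=12, seed0=900):
            nm = node_measures(net)
            assert nm["pagerank"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_neighbor_correlation_mean_out_neighbour_degree(self, star2):
        nm = node_measures(star2)
        # centre's two leaves each have total degree 1
        assert nm.loc[1, "neighbor_correlation"] == pytest.approx(1.0)
        assert nm.loc[2, "neighbor_correlation"] == 0.0  # out-degree 0

    def test_betweenness_and_closeness_match_path_enumeration(self):
        for seed in (0, 1, 2):
            net = erdos_renyi_directed(15, 0.15, seed=seed)
            nm = node_measures(net)
            betw = betweenness_by_path_enumeration(net)
            close = closeness_by_bfs(net)
            for v in net.labels:
                assert nm.loc[v, "betweenness"] == pytest.approx(betw[v], abs=1e-9)
                assert nm.loc[v, "closeness"] == pytest.approx(close[v], abs=1e-12)

    def test_control_centrality_bounds_generic_rank(self):
        """Reachable-set size upper-bounds the single-input generic rank."""
        for net in random_nets(20, n_max=8, seed0=1000):
            nm = node_measures(net)
            for v in sorted(net.labels)[:3]:
                B = np.zeros((net.n_nodes, 1), dtype=np.int8)
                B[net.index(v), 0] = 1
                model = StateSpaceModel(net.adjacency_matrix().T, B,
                                        np.ones((1, net.n_nodes), dtype=np.int8),
                                        labels=list(net.labels))
                assert nm.loc[v, "control_centrality"] >= \
                    generic_rank_oracle(model, seed=3)


class TestClassification:
    def test_star_source_and_external_dilation(self, star2):
        classes = classify_config_nodes(star2, {1, 2})
        assert classes[1] == "source"
        assert classes[2] == "external_dilation"

    def test_internal_dilation(self):
        net = DirectedNetwork(["a", "b", "c", "d"],
                              [("c", "a"), ("c", "b"), ("b", "d")])
        from ctrlnet import minimal_driver_nodes
        drivers = minimal_driver_nodes(net)
        assert drivers == {"b", "c"}
        classes = classify_config_nodes(net, drivers)
        assert classes["c"] == "source"
        assert classes["b"] == "internal_dilation"

    def test_cycle_fallback_driver_is_inaccessible(self, cycle3):
        assert classify_config_nodes(cycle3, {1}) == {1: "inaccessible"}

    def test_unknown_node_rejected(self, chain3):
        with pytest.raises(ValueError):
            classify_config_nodes(chain3, {42})


class TestControllingMatrix:
    def test_chain_driver_column(self, chain3):
        cfg = InputConfiguration({1}, {1: 0})
        mat = controlling_matrix(chain3, cfg)
        assert mat[1].tolist() == [0.0, 1.0, 2.0]
        assert mat[2].isna().all() and mat[3].isna().all()
        assert mean_relative_degree(mat) == pytest.approx(1.0)
        assert mat.min(axis=1).max() == 2

    def test_all_drivers_give_zero_mean(self, chain3):
        cfg = InputConfiguration({1, 2, 3}, {1: 0, 2: 1, 3: 2})
        assert mean_relative_degree(controlling_matrix(chain3, cfg)) == 0.0

    def test_observing_matrix_is_reverse_dual(self, chain3):
        cfg = OutputConfiguration({3}, {3: 0})
        mat = observing_matrix(chain3, cfg)
        assert mat[3].tolist() == [2.0, 1.0, 0.0]


class TestReachability:
    def test_chain_upper_triangular(self, chain3):
        rc, ro = reachability_matrices(chain3)
        assert rc.values.tolist() == [[True, True, True],
                                      [False, True, True],
                                      [False, False, True]]

    def test_cycle_all_true(self, cycle3):
        rc, _ = reachability_matrices(cycle3)
        assert rc.values.all()

    def test_observing_is_transpose_of_controlling(self):
        for net in random_nets(20, n_max=10, seed0=1100):
            rc, ro = reachability_matrices(net)
            assert (ro.values == rc.values.T).all()


class TestSimilarity:
    def test_single_driver(self, chain3):
        sim = driver_similarity(chain3, InputConfiguration({1}, {1: 0}))
        assert sim.shape == (1, 1) and sim.iloc[0, 0] == 1.0

    def test_star_drivers_disagree_everywhere(self, star2):
        sim = driver_similarity(star2, InputConfiguration({1, 2}, {1: 0, 2: 1}))
        assert sim.loc[1, 2] == 0.0

    def test_identical_rows_give_similarity_one(self):
        # two drivers with the same distance profile: twin sources feeding 3
        net = DirectedNetwork([1, 2, 3], [(1, 3), (2, 3)])
        sim = driver_similarity(net, InputConfiguration({1, 2}, {1: 0, 2: 1}))
        # d(1,.) = {1:0, 3:1}; d(2,.) = {2:0, 3:1}: agree only on node 3
        assert sim.loc[1, 2] == pytest.approx(1 / 3)
        twin = DirectedNetwork([1, 2], [(1, 2), (2, 1)])
        s2 = driver_similarity(twin, InputConfiguration({1, 2}, {1: 0, 2: 1}))
        assert s2.loc[1, 2] < 1.0  # distances swap, rows are not identical


class TestEdgeMeasures:
    def test_chain_edge_betweenness(self, chain3):
        em = edge_measures(chain3)
        assert em.table.loc[[(1, 2)], "betweenness"].item() == pytest.approx(2.0)

    def test_cycle_endpoint_similarity_is_one(self, cycle3):
        em = edge_measures(cycle3)
        assert (em.table["endpoint_similarity"] == 1.0).all()

    def test_edge_betweenness_matches_path_enumeration(self):
        net = erdos_renyi_directed(15, 0.15, seed=4)
        em = edge_measures(net)
        oracle = edge_betweenness_by_path_enumeration(net)
        for e, val in oracle.items():
            assert em.table.loc[[e], "betweenness"].item() == pytest.approx(val, abs=1e-9)

    def test_edge_similarity_diagonal_and_symmetry(self, chain3):
        em = edge_measures(chain3)
        sim = em.edge_similarity
        assert np.allclose(np.diag(sim.values), 1.0)
        assert np.allclose(sim.values, sim.values.T)
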