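import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import normalized_mutual_info_score

import oracles
from restconn import (
    Partition,
    ThresholdedNetwork,
    classify_hubs,
    consensus_partition,
    fixture_graph,
    louvain,
    modularity_q,
    module_summary,
    normalized_participation_coefficient,
    participation_coefficient,
    within_module_zscore,
)
from restconn.community import agreement_matrix, within_module_strength
from restconn.types import ValidationError, relabel_contiguous


class TestLouvain:
    def test_two_cliques_recovered_with_half_q(self):
        net = fixture_graph("two_cliques", 4)
        part = louvain(net, seed=0)
        assert part.n_modules == 2
        assert part.q == pytest.approx(0.5)

    def test_planted_partition_recovery_median_nmi(self):
        net = fixture_graph("planted_partition", 60, 3, 0.9, 0.02, seed=8)
        truth = np.repeat([1, 2, 3], 20)
        nmis = [
            normalized_mutual_info_score(truth, louvain(net, seed=s).labels)
            for s in range(20)
        ]
        assert np.median(nmis) == pytest.approx(1.0)

    def test_returned_q_is_self_consistent(self, rng):
        adj = oracles.random_weighted_graph(20, 0.3, rng)
        net = ThresholdedNetwork(adj)
        part = louvain(net, seed=3)
        assert part.q == pytest.approx(modularity_q(net, part), abs=1e-12)

    def test_empty_graph_errors(self):
        with pytest.raises(ValidationError):
            louvain(np.zeros((0, 0)))


class TestConsensus:
    def test_deterministic_structure_agrees_immediately(self):
        net = fixture_graph("two_cliques", 4)
        part, agree = consensus_partition(net, n_runs=20, seed=1)
        assert part.n_modules == 2
        assert np.array_equal(np.unique(agree), [0.0, 1.0])

    def test_planted_five_module_recovery(self):
        net = fixture_graph("planted_partition", 90, 5, 0.8, 0.05, seed=5)
        truth = np.repeat(np.arange(5), 18)
        part, _ = consensus_partition(net, n_runs=100, seed=2)
        assert part.n_modules == 5
        assert normalized_mutual_info_score(truth, part.labels) >= 0.95

    def test_idempotence(self):
        net = fixture_graph("planted_partition", 60, 3, 0.8, 0.05, seed=6)
        part1, _ = consensus_partition(net, n_runs=50, seed=3)
        # re-running consensus on a graph whose structure the first pass
        # resolved must reproduce the same partition
        part2, _ = consensus_partition(net, n_runs=50, seed=4)
        assert normalized_mutual_info_score(part1.labels, part2.labels) == pytest.approx(1.0)

    def test_seed_determinism(self):
        net = fixture_graph("planted_partition", 60, 3, 0.7, 0.1, seed=7)
        a, _ = consensus_partition(net, n_runs=30, seed=9)
        b, _ = consensus_partition(net, n_runs=30, seed=9)
        assert np.array_equal(a.labels, b.labels)


class TestWithinModuleZscore:
    def test_equal_degrees_give_zero(self):
        net = fixture_graph("clique", 4)
        part = Partition(np.ones(4, dtype=int))
        assert np.allclose(within_module_zscore(net, part), 0.0)

    def test_three_node_module_known_values(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 1.0
        adj[0, 2] = adj[2, 0] = 1.0
        net = ThresholdedNetwork(adj, mode="binary")
        wmz = within_module_zscore(net, Partition(np.array([1, 1, 1])))
        assert wmz == pytest.approx([1.1547, -0.5774, -0.5774], abs=1e-4)

    def test_zero_mean_within_each_module(self, rng):
        adj = oracles.random_weighted_graph(20, 0.4, rng)
        net = ThresholdedNetwork(adj)
        part = Partition(relabel_contiguous(rng.integers(0, 3, 20)))
        wmz = within_module_zscore(net, part)
        for s in range(1, part.n_modules + 1):
            assert wmz[part.labels == s].mean() == pytest.approx(0.0, abs=1e-12)


class TestParticipationCoefficient:
    def test_closed_form_splits(self):
        # all edges inside own module
        net = fixture_graph("clique", 4)
        assert np.allclose(
            participation_coefficient(net, Partition(np.ones(4, dtype=int))), 0.0
        )
        # equal split across 2 modules
        adj = np.zeros((4, 4))
        adj[0, 1] = adj[1, 0] = 1.0
        adj[0, 2] = adj[2, 0] = 1.0
        net = ThresholdedNetwork(adj, mode="binary")
        pc = participation_coefficient(net, Partition(np.array([1, 1, 2, 2])))
        assert pc[0] == pytest.approx(0.5)
        # equal split across 4 modules
        net = fixture_graph("star", 5)
        pc = participation_coefficient(net, Partition(np.array([1, 1, 2, 3, 4])))
        assert pc[0] == pytest.approx(0.75)

    def test_upper_bound_one_minus_inverse_m(self, rng):
        adj = oracles.random_weighted_graph(24, 0.4, rng)
        net = ThresholdedNetwork(adj)
        part = Partition(relabel_contiguous(rng.integers(0, 4, 24)))
        pc = participation_coefficient(net, part)
        assert np.all(pc <= 1 - 1 / part.n_modules + 1e-12)


@pytest.fixture(scope="module")
def hub_graph():
    """Planted-partition graph with degree-heterogeneous hubs."""
    net = fixture_graph("planted_partition", 60, 3, 0.6, 0.05, seed=12)
    adj = net.adjacency.copy()
    for hub in (0, 20, 40):  # densify hubs inside their own module
        block = slice(20 * (hub // 20), 20 * (hub // 20) + 20)
        adj[hub, block] = 1.0
        adj[block, hub] = 1.0
    np.fill_diagonal(adj, 0.0)
    return ThresholdedNetwork(adj, mode="binary")


class TestNormalizedPC:

    def test_deterministic_and_bounded(self, hub_graph):
        part = Partition(np.repeat([1, 2, 3], 20))
        a = normalized_participation_coefficient(hub_graph, part, n_null=50, seed=5)
        b = normalized_participation_coefficient(hub_graph, part, n_null=50, seed=5)
        assert np.array_equal(a, b)
        assert np.all((a >= 0) & (a <= 1))

    def test_reduces_within_strength_dependence(self, hub_graph):
        part = Partition(np.repeat([1, 2, 3], 20))
        pc = participation_coefficient(hub_graph, part)
        pc_norm = normalized_participation_coefficient(
            hub_graph, part, n_null=100, seed=8
        )
        k_within = within_module_strength(hub_graph, part)
        corr_raw = abs(np.corrcoef(pc, k_within)[0, 1])
        corr_norm = abs(np.corrcoef(pc_norm, k_within)[0, 1])
        assert corr_norm < corr_raw

    def test_swap_free_network_falls_back_to_pc(self):
        net = fixture_graph("clique", 5)
        part = Partition(np.array([1, 1, 1, 2, 2]))
        pc_norm = normalized_participation_coefficient(net, part, n_null=10, seed=0)
        assert np.allclose(pc_norm, participation_coefficient(net, part))
        assert net.flags.get("pc_norm_fallback")


class TestHubClassification:
    @pytest.mark.parametrize(
        "wmz, pc_norm, role",
        [
            (1.5, 0.7, "connector hub"),
            (1.5, 0.3, "provincial hub"),
            (0.2, 0.7, "connector non-hub"),
            (0.2, 0.3, "provincial non-hub"),
            # strict inequalities at the boundaries
            (1.0, 0.7, "connector non-hub"),
            (1.5, 0.5, "provincial hub"),
            (1.0, 0.5, "provincial non-hub"),
        ],
    )
    def test_quadrant_rule(self, wmz, pc_norm, role):
        table = classify_hubs(np.array([wmz]), np.array([pc_norm]))
        assert table["role"].iloc[0] == role


class TestModuleSummary:
    def test_single_module_no_hubs(self):
        part = Partition(np.ones(5, dtype=int))
        hubs = classify_hubs(np.zeros(5), np.zeros(5), part)
        report = module_summary(part, hubs)
        assert len(report) == 1
        assert report["n_connector_hubs"].iloc[0] == 0
        assert report["n_provincial_hubs"].iloc[0] == 0

    def test_node_counts_sum_to_n(self, rng):
        part = Partition(relabel_contiguous(rng.integers(0, 4, 40)))
        hubs = classify_hubs(rng.standard_normal(40), rng.random(40), part)
        report = module_summary(part, hubs)
        assert report["n_nodes"].sum() == 40

    def test_hemisphere_prefixed_lists(self):
        part = Partition(np.array([1, 1, 1, 1]))
        hubs = classify_hubs(
            np.array([2.0, 2.0, 0.0, 2.0]), np.array([0.7, 0.2, 0.5, 0.8]), part
        )
        parcels = pd.DataFrame({
            "node_id": [1, 2, 3, 4],
            "label": list("abcd"),
            "hemisphere": ["L", "L", "R", "R"],
            "functional_network": ["x"] * 4,
        })
        report = module_summary(part, hubs, parcels)
        assert report["connector_hubs"].iloc[0] == "L 1 R 4"
        assert report["provincial_hubs"].iloc[0] == "L 2"


def test_agreement_matrix_properties():
    runs = [np.array([1, 1, 2, 2]), np.array([1, 1, 1, 2]), np.array([2, 2, 1, 1])]
    agree = agreement_matrix(runs)
    assert np.allclose(agree, agree.T)
    assert np.all(np.diag(agree) == 1.0)
    assert agree[0, 1] == pytest.approx(1.0)
    assert agree[1, 2] == pytest.approx(1 / 3)
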