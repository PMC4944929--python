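"""Map-equation codelength, greedy search, and structural decompositions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import graph_from_edges, random_connected_graph
from oracles import brute_modularity, contingency_ari
from synaptoflow.communities import (
    Partition,
    cnm_agglomerative,
    codelength,
    girvan_newman,
    infomap_partition,
    modularity_Q,
    module_flow_table,
    nontrivial_modules,
    participation_coefficients,
    partition_similarity,
    spectral_partition,
    stationary_flow,
    summarize_flow,
)


def single_module(g):
    return Partition(g.node_ids, np.ones(g.n_nodes, dtype=int))


class TestStationaryFlow:
    def test_regular_graph_uniform(self, cycle4):
        flow = stationary_flow(cycle4)
        np.testing.assert_allclose(flow.p, 0.25)

    def test_star_strength_proportional(self):
        g = graph_from_edges(5, [(0, i, 2.0) for i in range(1, 5)])
        flow = stationary_flow(g)
        assert flow.p[0] == pytest.approx(0.5)
        np.testing.assert_allclose(flow.p[1:], 0.125)

    def test_matches_simulated_walk(self):
        rng = np.random.default_rng(3)
        g = random_connected_graph(rng, 12)
        flow = stationary_flow(g)
        # Monte-Carlo oracle: simulate a long weighted random walk
        steps = 1_000_000
        visits = np.zeros(g.n_nodes)
        node = 0
        probs = [g.weights[i] / g.weights[i].sum() for i in range(g.n_nodes)]
        choices = rng.random(steps)
        for s in range(steps):
            cum = np.cumsum(probs[node])
            node = int(np.searchsorted(cum, choices[s] * cum[-1]))
            visits[node] += 1
        np.testing.assert_allclose(visits / steps, flow.p, atol=1e-3)

    def test_all_zero_graph_rejected(self):
        g = graph_from_edges(3, [])
        with pytest.raises(ValueError):
            stationary_flow(g)


class TestCodelength:
    def test_cycle_single_module_is_node_entropy(self, cycle4):
        assert codelength(cycle4, single_module(cycle4)) == pytest.approx(2.0)

    def test_two_dyads_closed_forms(self, two_dyads):
        split = Partition(two_dyads.node_ids, np.array([1, 1, 2, 2]))
        assert codelength(two_dyads, split) == pytest.approx(1.0)
        assert codelength(two_dyads, single_module(two_dyads)) == pytest.approx(2.0)

    def test_invariant_under_module_relabeling(self):
        rng = np.random.default_rng(9)
        g = random_connected_graph(rng, 10)
        labels = rng.integers(1, 4, 10)
        l1 = codelength(g, Partition(g.node_ids, labels))
        remap = {1: 7, 2: 3, 3: 11}
        l2 = codelength(
            g, Partition(g.node_ids, np.array([remap[l] for l in labels]))
        )
        assert l1 == pytest.approx(l2)

    def test_missing_node_rejected(self, cycle4):
        part = Partition(np.array([1, 2, 3]), np.array([1, 1, 1]))
        with pytest.raises(KeyError):
            codelength(cycle4, part)


class TestInfomapPartition:
    def test_planted_cliques_recovered(self, two_cliques_bridge):
        part, flow = infomap_partition(two_cliques_bridge, seed=1, trials=5)
        assert part.n_modules == 2
        labels = part.labels_for(two_cliques_bridge.node_ids)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert flow.codelength < codelength(
            two_cliques_bridge, single_module(two_cliques_bridge)
        )

    def test_reproducible_given_seed(self):
        g = random_connected_graph(np.random.default_rng(4), 30)
        p1, f1 = infomap_partition(g, seed=99, trials=5)
        p2, f2 = infomap_partition(g, seed=99, trials=5)
        assert (p1.labels == p2.labels).all()
        assert f1.codelength == f2.codelength

    def test_isolated_nodes_become_singletons(self):
        g = graph_from_edges(5, [(0, 1), (1, 2)])  # nodes 4,5 isolated
        part, flow = infomap_partition(g, seed=0, trials=2)
        labels = part.labels_for(np.array([4, 5]))
        assert labels[0] != labels[1]
        counts = np.bincount(part.labels)
        assert counts[labels[0]] == 1 and counts[labels[1]] == 1
        assert flow.p_of(4) == 0.0

    def test_modules_sorted_by_flow(self, default_sample):
        from synaptoflow.ingest import (aggregate_links,
                                        drop_uncataloged_contacts,
                                        filter_contacts)

        table, _ = drop_uncataloged_contacts(default_sample.contacts,
                                             default_sample.catalog)
        g = aggregate_links(filter_contacts(table, 0.16), 0.16,
                            node_ids=default_sample.catalog.ids)
        part, flow = infomap_partition(g, seed=2, trials=3)
        flows = [flow.module_flow[m]
                 for m in sorted(flow.module_flow)]
        assert all(a >= b - 1e-12 for a, b in zip(flows, flows[1:]))

    def test_flow_summary_bookkeeping(self, two_cliques_bridge):
        part, flow = infomap_partition(two_cliques_bridge, seed=0, trials=3)
        assert sum(flow.module_flow.values()) == pytest.approx(1.0)
        for m, q in flow.module_exit.items():
            assert q >= 0
        assert flow.total_exit == pytest.approx(sum(flow.module_exit.values()))


class TestModularityQ:
    def test_single_module_is_zero(self, two_cliques_bridge):
        assert modularity_Q(
            two_cliques_bridge, single_module(two_cliques_bridge)
        ) == pytest.approx(0.0)

    def test_disjoint_equal_cliques_split_gives_half(self):
        edges = [(a, b) for a in range(4) for b in range(a + 1, 4)]
        edges += [(a + 4, b + 4) for a, b in edges]
        g = graph_from_edges(8, edges)
        part = Partition(g.node_ids, np.array([1] * 4 + [2] * 4))
        assert modularity_Q(g, part) == pytest.approx(0.5)

    def test_matches_double_sum_oracle(self):
        rng = np.random.default_rng(13)
        g = random_connected_graph(rng, 20)
        labels = rng.integers(1, 5, 20)
        part = Partition(g.node_ids, labels)
        assert modularity_Q(g, part) == pytest.approx(
            brute_modularity(g.weights, labels)
        )


class TestStructuralMethods:
    def test_divisive_cuts_bridge_first(self, two_triangles_bridge):
        part = girvan_newman(two_triangles_bridge, target_modules=2)
        labels = part.labels_for(two_triangles_bridge.node_ids)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_agglomerative_matches_on_planted_graph(self, two_triangles_bridge):
        part = cnm_agglomerative(two_triangles_bridge)
        ref = girvan_newman(two_triangles_bridge, target_modules=2)
        assert partition_similarity(part, ref) == pytest.approx(1.0)
        assert modularity_Q(two_triangles_bridge, part) > 0

    @pytest.mark.parametrize("basis", ["laplacian", "modularity_matrix"])
    def test_spectral_recovers_planted_cliques(self, two_cliques_bridge, basis):
        part, scan = spectral_partition(two_cliques_bridge, k=2, basis=basis)
        labels = part.labels_for(two_cliques_bridge.node_ids)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1

    def test_spectral_scan_reports_max_q(self, small_params):
        from synaptoflow.ingest import (aggregate_links,
                                        drop_uncataloged_contacts,
                                        filter_contacts)
        from synaptoflow.synthetic import generate_sample

        sample = generate_sample(small_params, seed=3)
        table, _ = drop_uncataloged_contacts(sample.contacts, sample.catalog)
        g = aggregate_links(filter_contacts(table, 0.16), 0.16,
                            node_ids=sample.catalog.ids)
        part, scan = spectral_partition(g, k_range=(2, 8), seed=0)
        best = scan.loc[scan["Q"].idxmax()]
        assert modularity_Q(g, part) == pytest.approx(best["Q"])


class TestParticipation:
    def test_all_weight_inside_own_module_is_zero(self, two_dyads):
        part = Partition(two_dyads.node_ids, np.array([1, 1, 2, 2]))
        np.testing.assert_allclose(
            participation_coefficients(two_dyads, part), 0.0
        )

    def test_equal_split_across_two_modules_is_half(self):
        g = graph_from_edges(3, [(0, 1), (0, 2)])
        part = Partition(g.node_ids, np.array([1, 1, 2]))
        p = participation_coefficients(g, part)
        assert p[0] == pytest.approx(0.5)


class TestModuleFlowTable:
    def test_equal_cliques_split_flow(self):
        edges = [(a, b) for a in range(3) for b in range(a + 1, 3)]
        edges += [(a + 3, b + 3) for a, b in edges]
        g = graph_from_edges(6, edges)
        part = Partition(g.node_ids, np.array([1, 1, 1, 2, 2, 2]))
        flow = summarize_flow(g, part)
        table = module_flow_table(flow, part)
        np.testing.assert_allclose(table["total_flow"], 0.5)
        assert list(table["n_members"]) == [3, 3]

    def test_flow_recomputes_from_node_visit_rates(self, default_sample):
        from synaptoflow.ingest import (aggregate_links,
                                        drop_uncataloged_contacts,
                                        filter_contacts)

        table, _ = drop_uncataloged_contacts(default_sample.contacts,
                                             default_sample.catalog)
        g = aggregate_links(filter_contacts(table, 0.16), 0.16,
                            node_ids=default_sample.catalog.ids)
        part, flow = infomap_partition(g, seed=5, trials=3)
        tab = module_flow_table(flow, part)
        labels = part.labels_for(flow.node_ids)
        for _, row in tab.head(5).iterrows():
            members = labels == _module_of(tab, row)
            assert row["total_flow"] == pytest.approx(
                flow.p[members].sum()
            )

    def test_nontrivial_module_rule(self, two_dyads):
        part = Partition(two_dyads.node_ids, np.array([1, 1, 2, 2]))
        flow = summarize_flow(two_dyads, part)
        # both modules carry 50% flow: far above the 1% flow cut
        assert nontrivial_modules(flow, part) == [1, 2]


def _module_of(tab, row):
    return int(row["module"])


class TestPartitionSimilarity:
    def test_identical_partitions(self, cycle4):
        p = Partition(cycle4.node_ids, np.array([1, 1, 2, 2]))
        assert partition_similarity(p, p) == pytest.approx(1.0)

    def test_one_module_vs_singletons_is_chance(self):
        ids = np.arange(1, 5)
        p1 = Partition(ids, np.ones(4, dtype=int))
        p2 = Partition(ids, np.arange(1, 5))
        assert partition_similarity(p1, p2) == pytest.approx(0.0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_matches_contingency_formula(self, seed):
        rng = np.random.default_rng(seed)
        ids = np.arange(1, 31)
        l1 = rng.integers(1, 5, 30)
        l2 = rng.integers(1, 5, 30)
        got = partition_similarity(Partition(ids, l1), Partition(ids, l2))
        assert got == pytest.approx(contingency_ari(l1, l2))

    def test_mismatched_node_sets_rejected(self):
        p1 = Partition(np.array([1, 2]), np.array([1, 1]))
        p2 = Partition(np.array([1, 3]), np.array([1, 1]))
        with pytest.raises(ValueError):
            partition_similarity(p1, p2)


def test_merging_disconnected_modules_never_reduces_codelength():
    """Joining two modules with no inter-module weight cannot shorten the code."""
    rng = np.random.default_rng(21)
    for _ in range(10):
        g1 = random_connected_graph(rng, 5)
        g2 = random_connected_graph(rng, 5)
        w = np.zeros((10, 10))
        w[:5, :5] = g1.weights
        w[5:, 5:] = g2.weights
        from synaptoflow.ingest import WeightedGraph

        g = WeightedGraph(node_ids=np.arange(1, 11), weights=w)
        split = Partition(g.node_ids, np.array([1] * 5 + [2] * 5))
        merged = Partition(g.node_ids, np.ones(10, dtype=int))
        assert codelength(g, merged) >= codelength(g, split) - 1e-12


def test_infomap_cross_check_against_igraph(two_cliques_bridge, small_params):
    """Independent implementation agreement on planted structure."""
    igraph = pytest.importorskip("igraph")
    from synaptoflow.ingest import (aggregate_links,
                                    drop_uncataloged_contacts,
                                    filter_contacts)
    from synaptoflow.synthetic import generate_sample

    sample = generate_sample(small_params, seed=8)
    table, _ = drop_uncataloged_contacts(sample.contacts, sample.catalog)
    g = aggregate_links(filter_contacts(table, 0.16), 0.16,
                        node_ids=sample.catalog.ids)
    part, _ = infomap_partition(g, seed=1, trials=5)

    linked = g.strength() > 0
    sub = g.weights[np.ix_(linked, linked)]
    iu, ju = np.triu_indices(sub.shape[0], 1)
    nz = sub[iu, ju] > 0
    ig = igraph.Graph(
        n=sub.shape[0],
        edges=list(zip(iu[nz].tolist(), ju[nz].tolist())),
        edge_attrs={"weight": sub[iu, ju][nz].tolist()},
    )
    ref = ig.community_infomap(edge_weights="weight", trials=5)
    ours = part.labels_for(g.node_ids[linked])
    assert contingency_ari(ours, ref.membership) > 0.8
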