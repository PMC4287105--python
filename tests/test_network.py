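import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from maturix.network import (
    RelevanceNetwork,
    centralities,
    correlation_matrix,
    fastgreedy_communities,
    graph_from_adjacency,
    hub_report,
    largest_connected_component,
    modularity,
    threshold_adjacency,
)
from maturix.simulate import SimulationConfig, simulate_design, simulate_expression

from _oracles import (
    betweenness_by_path_enumeration,
    connected_components_unionfind,
    exhaustive_max_modularity,
    modularity_direct,
)


def clique_bridge_graph(rng) -> nx.Graph:
    """Random near-clique communities joined by at most one bridge edge —
    the shape of a hard-thresholded correlation network."""
    k = int(rng.integers(2, 4))
    sizes = [int(rng.integers(3, 5)) for _ in range(k)]
    while sum(sizes) > 9:
        sizes[int(np.argmax(sizes))] -= 1
    G = nx.Graph()
    start = 0
    blocks = []
    for s in sizes:
        nodes = list(range(start, start + s))
        G.add_nodes_from(nodes)
        G.add_edges_from((u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:])
        blocks.append(nodes)
        start += s
    for a, b in zip(blocks, blocks[1:]):
        if rng.random() < 0.7:
            G.add_edge(int(rng.choice(a)), int(rng.choice(b)))
    return G


class TestCorrelation:
    def test_duplicated_gene_has_unit_correlation(self):
        rng = np.random.default_rng(60)
        x = rng.normal(0, 1, 20)
        S = correlation_matrix(pd.DataFrame({"a": x, "b": x, "c": rng.normal(0, 1, 20)}))
        assert S.loc["a", "b"] == pytest.approx(1.0)

    def test_negated_gene_has_minus_one(self):
        rng = np.random.default_rng(61)
        x = rng.normal(0, 1, 15)
        S = correlation_matrix(pd.DataFrame({"a": x, "b": -x}))
        assert S.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(62)
        X = rng.normal(0, 1, (12, 5))
        S = correlation_matrix(X).to_numpy()
        C = X - X.mean(axis=0)
        cov = C.T @ C / (len(X) - 1)
        sd = np.sqrt(np.diag(cov))
        np.testing.assert_allclose(S, cov / np.outer(sd, sd), atol=1e-12)

    def test_zero_variance_gene_excluded_with_warning(self):
        rng = np.random.default_rng(63)
        df = pd.DataFrame({"a": rng.normal(0, 1, 10), "flat": np.ones(10)})
        with pytest.warns(UserWarning, match="zero-variance"):
            S = correlation_matrix(df)
        assert list(S.columns) == ["a"]


class TestThreshold:
    def test_negative_correlation_above_threshold_is_edge(self):
        S = np.array([[1.0, -0.99], [-0.99, 1.0]])
        assert threshold_adjacency(S, 0.98)[0, 1] == 1

    def test_boundary_is_strict(self):
        S = np.array([[1.0, 0.98], [0.98, 1.0]])
        assert threshold_adjacency(S, 0.98)[0, 1] == 0

    def test_diagonal_never_edges(self):
        S = np.eye(3)
        assert threshold_adjacency(S, 0.5).sum() == 0

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_adjacency(np.eye(2), 1.5)

    def test_edge_count_monotone_in_threshold(self):
        rng = np.random.default_rng(64)
        S = correlation_matrix(rng.normal(0, 1, (12, 25)))
        counts = [threshold_adjacency(S, r0).to_numpy().sum()
                  for r0 in (0.1, 0.3, 0.5, 0.7, 0.9, 0.99)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_high_threshold_on_noise_gives_near_empty_graph(self):
        rng = np.random.default_rng(65)
        S = correlation_matrix(rng.normal(0, 1, (30, 40)))
        A = threshold_adjacency(S, 0.999)
        assert A.to_numpy().sum() <= 2


class TestComponents:
    def test_tie_broken_by_smallest_member(self):
        G = nx.Graph()
        G.add_edges_from([("d", "e"), ("e", "f"), ("d", "f")])  # triangle 1
        G.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])  # triangle 2
        G.add_node("z")
        lcc = largest_connected_component(G)
        assert set(lcc.nodes) == {"a", "b", "c"}

    def test_path_beats_pair(self):
        G = nx.path_graph(5)
        G.add_edge(10, 11)
        assert set(largest_connected_component(G).nodes) == set(range(5))

    def test_matches_unionfind_oracle(self):
        rng = np.random.default_rng(66)
        for _ in range(100):
            G = nx.gnp_random_graph(int(rng.integers(4, 15)), float(rng.uniform(0.05, 0.4)),
                                    seed=int(rng.integers(1e9)))
            comps = connected_components_unionfind(list(G.edges), list(G.nodes))
            biggest = max(len(c) for c in comps)
            assert largest_connected_component(G).number_of_nodes() == biggest

    def test_empty_graph(self):
        assert largest_connected_component(nx.Graph()).number_of_nodes() == 0


class TestFastGreedy:
    def test_single_clique_one_community_zero_q(self):
        G = nx.complete_graph(6)
        partition, q = fastgreedy_communities(G)
        assert len(partition) == 1 and q == pytest.approx(0.0)

    def test_two_cliques_one_bridge_recovered(self):
        G = nx.complete_graph(5)
        H = nx.relabel_nodes(nx.complete_graph(5), {i: i + 5 for i in range(5)})
        G = nx.compose(G, H)
        G.add_edge(0, 5)
        partition, q = fastgreedy_communities(G)
        assert sorted(map(sorted, partition)) == [list(range(5)), list(range(5, 10))]
        best_q, _ = exhaustive_max_modularity(list(G.edges), list(G.nodes))
        assert q == pytest.approx(best_q, abs=1e-12)

    def test_matches_exhaustive_optimum_on_clique_bridge_suite(self):
        """On graphs with the structure the 0.98-threshold network produces
        (near-cliques, sparse bridges) the greedy partition attains the
        exhaustive-search maximum modularity."""
        rng = np.random.default_rng(67)
        for _ in range(25):
            G = clique_bridge_graph(rng)
            partition, q = fastgreedy_communities(G)
            best_q, _ = exhaustive_max_modularity(list(G.edges), list(G.nodes))
            assert q == pytest.approx(best_q, abs=1e-9)

    def test_never_exceeds_exhaustive_optimum(self):
        rng = np.random.default_rng(68)
        for _ in range(20):
            G = nx.gnp_random_graph(int(rng.integers(4, 9)), float(rng.uniform(0.2, 0.7)),
                                    seed=int(rng.integers(1e9)))
            if G.number_of_edges() == 0:
                continue
            partition, q = fastgreedy_communities(G)
            assert q == pytest.approx(modularity(G, partition), abs=1e-12)
            best_q, _ = exhaustive_max_modularity(list(G.edges), list(G.nodes))
            assert q <= best_q + 1e-9

    def test_agrees_with_networkx_cnm_on_structured_graphs(self):
        from networkx.algorithms.community import greedy_modularity_communities
        from networkx.algorithms.community import modularity as nx_modularity

        rng = np.random.default_rng(69)
        for _ in range(10):
            G = clique_bridge_graph(rng)
            _, q = fastgreedy_communities(G)
            q_nx = nx_modularity(G, greedy_modularity_communities(G))
            assert q == pytest.approx(q_nx, abs=1e-9)

    def test_edgeless_graph_gives_singletons(self):
        G = nx.empty_graph(4)
        partition, q = fastgreedy_communities(G)
        assert len(partition) == 4 and q == 0.0

    def test_modularity_value_matches_direct_count(self):
        rng = np.random.default_rng(70)
        G = clique_bridge_graph(rng)
        partition, q = fastgreedy_communities(G)
        assert q == pytest.approx(modularity_direct(list(G.edges), partition), abs=1e-12)


class TestCentralities:
    def test_path_graph(self):
        G = nx.path_graph(["a", "b", "c"])
        tab = centralities(G)
        assert tab.loc["b", "degree"] == 2
        assert tab.loc["b", "betweenness"] == pytest.approx(1.0)

    def test_star_center(self):
        G = nx.star_graph(3)  # center 0, three leaves
        tab = centralities(G)
        assert tab.loc[0, "betweenness"] == pytest.approx(3.0)  # C(3,2) pairs

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(71)
        for _ in range(50):
            G = nx.gnp_random_graph(int(rng.integers(4, 13)), float(rng.uniform(0.2, 0.6)),
                                    seed=int(rng.integers(1e9)))
            tab = centralities(G)
            oracle = betweenness_by_path_enumeration(list(G.edges), list(G.nodes))
            for v in G.nodes:
                assert tab.loc[v, "betweenness"] == pytest.approx(oracle[v], abs=1e-9)
                assert tab.loc[v, "degree"] == G.degree(v)


class TestHubReport:
    def test_clique_ties_broken_lexicographically(self):
        G = nx.complete_graph(["c", "a", "b"])
        tab = hub_report(G)
        assert list(tab.index) == ["a", "b", "c"]
        assert len(tab) == G.number_of_nodes()

    def test_planted_hub_has_top_degree(self):
        """The latent-factor parent gene keeps every edge to its children
        and tops the degree ranking in most replicates."""
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=100 + seed,
                                   n_genes={"null": 0, "network_block_1": 20})
            design = simulate_design(cfg)
            expr, truth = simulate_expression(cfg, design)
            net = RelevanceNetwork(threshold=0.98).fit(expr.X)
            hub_probe = truth.index[truth["role"] == "hub"][0]
            hits += int(net.hub_table_.index[0] == hub_probe)
        assert hits >= 9

    def test_report_has_community_and_rank_columns(self):
        G = nx.complete_graph(4)
        partition, _ = fastgreedy_communities(G)
        tab = hub_report(G, partition)
        assert {"degree", "betweenness", "community", "degree_rank",
                "betweenness_rank"} <= set(tab.columns)


class TestRelevanceNetworkEstimator:
    def test_planted_four_blocks_recovered(self):
        cfg = SimulationConfig(
            seed=110,
            n_genes={"null": 0, "network_block_1": 20, "network_block_2": 20,
                     "network_block_3": 20, "network_block_4": 20},
        )
        design = simulate_design(cfg)
        expr, truth = simulate_expression(cfg, design)
        net = RelevanceNetwork(threshold=0.98, community_scope="full").fit(expr.X)
        label_of = {}
        for ci, comm in enumerate(net.communities_):
            for v in comm:
                label_of[v] = ci
        true_labels = [truth.at[p, "block"] for p in truth.index]
        pred_labels = [label_of[p] for p in truth.index]
        assert adjusted_rand_score(true_labels, pred_labels) >= 0.9

    def test_invariant_to_sample_and_gene_order(self):
        rng = np.random.default_rng(72)
        X = pd.DataFrame(rng.normal(0, 1, (20, 8)),
                         columns=[f"g{i}" for i in range(8)])
        X.iloc[:, 1] = X.iloc[:, 0] + rng.normal(0, 0.01, 20)
        net1 = RelevanceNetwork(threshold=0.9).fit(X)
        shuffled = X.sample(frac=1, axis=0, random_state=1).sample(frac=1, axis=1,
                                                                   random_state=2)
        net2 = RelevanceNetwork(threshold=0.9).fit(shuffled)
        assert set(map(frozenset, net1.graph_.edges)) == set(map(frozenset, net2.graph_.edges))

    def test_edge_list_carries_correlations(self):
        rng = np.random.default_rng(73)
        x = rng.normal(0, 1, 25)
        X = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.01, 25),
                          "c": rng.normal(0, 1, 25)})
        net = RelevanceNetwork(threshold=0.9).fit(X)
        edges = net.edge_list()
        assert len(edges) == 1
        assert edges.iloc[0]["r"] > 0.99
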