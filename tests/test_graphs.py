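"""Synolitic graph construction, sparsification and topology features.

Centralities and the minimum-connected threshold are checked against
independent brute-force oracles (BFS all-pairs shortest paths; exhaustive
threshold sweep; bottleneck of a maximum spanning tree).
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from synolitic.cohort import FeatureTable, SyntheticSpec, generate_cohort
from synolitic.errors import ConfigurationError, StructuralError
from synolitic.graphs import (
    PatientGraph,
    PairwiseModelBank,
    SparsifierConfig,
    attach_node_topology,
    build_fold_graphs,
    build_patient_graph,
    build_patient_graphs,
    edge_weight,
    fit_pairwise_bank,
    sparsify_min_connected,
    sparsify_top_p,
)
from synolitic.preprocess import zscore_apply, zscore_fit

from conftest import random_patient_graph


# --------------------------------------------------------------------------
# independent brute-force oracles
# --------------------------------------------------------------------------
def bfs_shortest_paths(n, edges):
    """All-pairs hop distances and shortest-path counts, by BFS enumeration."""
    adj = {k: [] for k in range(n)}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    dist = np.full((n, n), np.inf)
    counts = np.zeros((n, n))
    for s in range(n):
        dist[s, s] = 0
        counts[s, s] = 1
        frontier = [s]
        d = 0
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if dist[s, w] == np.inf and w != s:
                        if w not in nxt:
                            nxt.append(w)
                        counts[s, w] += counts[s, u]
                    elif dist[s, w] == d + 1:
                        counts[s, w] += counts[s, u]
            d += 1
            for w in nxt:
                dist[s, w] = d
            frontier = nxt
    return dist, counts


def brute_force_centralities(g: PatientGraph):
    n = g.n_nodes
    edges = [tuple(e) for e in g.edge_index]
    dist, _ = bfs_shortest_paths(n, edges)
    degree = np.zeros(n)
    strength = np.zeros(n)
    for (u, v), w in zip(edges, g.edge_weight):
        degree[u] += 1
        degree[v] += 1
        strength[u] += w
        strength[v] += w
    degree_c = degree / (n - 1)
    # Wasserman–Faust closeness over the reachable set
    closeness = np.zeros(n)
    for k in range(n):
        reach = [j for j in range(n) if j != k and np.isfinite(dist[k, j])]
        if reach:
            total = sum(dist[k, j] for j in reach)
            closeness[k] = (len(reach) / total) * (len(reach) / (n - 1))
    # betweenness by explicit enumeration of all shortest paths
    betweenness = np.zeros(n)
    adj = {k: [] for k in range(n)}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)

    def all_shortest_paths(s, t):
        if not np.isfinite(dist[s, t]):
            return []
        paths = [[s]]
        for _ in range(int(dist[s, t])):
            paths = [
                p + [w]
                for p in paths
                for w in adj[p[-1]]
                if dist[s, w] == len(p) and dist[w, t] == dist[s, t] - len(p)
            ]
        return [p for p in paths if p[-1] == t]

    for s, t in itertools.combinations(range(n), 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for node in range(n):
            if node in (s, t):
                continue
            through = sum(1 for p in paths if node in p)
            betweenness[node] += through / len(paths)
    betweenness /= (n - 1) * (n - 2) / 2
    return degree_c, strength, closeness, betweenness


def sweep_min_connected_threshold(g: PatientGraph):
    """Exhaustive sweep: largest weight level keeping the graph connected."""
    best = None
    for t in sorted(set(g.edge_weight)):
        keep = [tuple(e) for e, w in zip(g.edge_index, g.edge_weight) if w >= t]
        nxg = nx.Graph(keep)
        nxg.add_nodes_from(range(g.n_nodes))
        if nx.is_connected(nxg):
            best = t
    return best


# --------------------------------------------------------------------------
def _std_tables(seed=0):
    spec = SyntheticSpec(n_patients=80, prevalence=0.3, n_features=8,
                         block_structure=(), marginal_effects=((0, 1.0),),
                         seed=seed)
    table, _ = generate_cohort(spec)
    params = zscore_fit(table, np.arange(80))
    return zscore_apply(table, params)


class TestEdgeWeight:
    @pytest.mark.parametrize("p,w", [(0.5, 0.0), (1.0, 1.0), (0.0, 1.0), (0.9, 0.8)])
    def test_values(self, p, w):
        assert edge_weight(p) == pytest.approx(w)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            edge_weight(1.2)
        with pytest.raises(ConfigurationError):
            edge_weight(-0.1)

    def test_vectorized_bounds(self):
        p = np.linspace(0, 1, 101)
        w = edge_weight(p)
        assert w.min() >= 0 and w.max() <= 1


class TestPairwiseBank:
    @pytest.mark.parametrize("n,expected", [(5, 10), (8, 28)])
    def test_pair_count(self, n, expected):
        table = _std_tables()
        bank = fit_pairwise_bank(table, table.feature_names[:n])
        assert bank.n_pairs == expected

    def test_label_copy_pair_saturates(self):
        rng = np.random.default_rng(0)
        y = np.tile([0, 1], 40)
        values = np.column_stack([y.astype(float), rng.standard_normal(80)])
        t = FeatureTable([f"P{i}" for i in range(80)], ["copy", "noise"], values, y)
        bank = fit_pairwise_bank(t, ["copy", "noise"])
        probs = bank.predict_proba_matrix(values)
        acc = np.mean((probs[:, 0] > 0.5) == y)
        # finite L2 (C = 1) bounds the coefficients, so saturation is
        # "toward" the extremes rather than exact
        assert acc == 1.0
        assert probs[y == 1, 0].min() > 0.85
        assert probs[y == 0, 0].max() < 0.15

    def test_too_few_features_rejected(self):
        table = _std_tables()
        with pytest.raises(ConfigurationError):
            fit_pairwise_bank(table, table.feature_names[:1])


class TestBuildPatientGraph:
    def test_complete_symmetric_bounded(self):
        table = _std_tables()
        bank = fit_pairwise_bank(table, table.feature_names)
        g = build_patient_graph(bank, table.values[0], "P0")
        assert g.n_edges == 28
        assert g.edge_weight.min() >= 0 and g.edge_weight.max() <= 1
        assert not np.any(g.edge_index[:, 0] == g.edge_index[:, 1])

    def test_identical_patients_identical_graphs(self):
        table = _std_tables()
        bank = fit_pairwise_bank(table, table.feature_names)
        g1 = build_patient_graph(bank, table.values[3])
        g2 = build_patient_graph(bank, table.values[3].copy())
        np.testing.assert_array_equal(g1.edge_weight, g2.edge_weight)

    def test_hand_set_model_closed_form(self):
        # beta = (2, 0), intercept 0, f_i = 1 -> p = sigmoid(2), w = 2p - 1
        bank = PairwiseModelBank(
            selected=["a", "b"],
            pair_index=np.array([[0, 1]]),
            coef=np.array([[2.0, 0.0]]),
            intercept=np.array([0.0]),
        )
        g = build_patient_graph(bank, np.array([1.0, 5.0]))
        p = 1 / (1 + np.exp(-2.0))
        assert g.edge_weight[0] == pytest.approx(2 * abs(p - 0.5))
        assert g.edge_weight[0] == pytest.approx(0.76159, abs=1e-4)

    def test_batch_matches_single(self):
        table = _std_tables()
        bank = fit_pairwise_bank(table, table.feature_names)
        batch = build_patient_graphs(bank, table)
        single = build_patient_graph(bank, table.values[7])
        np.testing.assert_allclose(batch[7].edge_weight, single.edge_weight,
                                   rtol=1e-12)

    def test_feature_mismatch_rejected(self):
        table = _std_tables()
        bank = fit_pairwise_bank(table, table.feature_names[:4])
        with pytest.raises(StructuralError):
            build_patient_graph(bank, table.values[0])


class TestTopP:
    def test_identity_at_p1(self):
        g = random_patient_graph(np.random.default_rng(0), 8)
        out = sparsify_top_p(g, 1.0)
        assert out.n_edges == g.n_edges

    def test_ceiling_edge_count(self):
        g = random_patient_graph(np.random.default_rng(1), 6, edge_prob=2.0)
        assert g.n_edges == 15
        assert sparsify_top_p(g, 0.2).n_edges == 3
        assert sparsify_top_p(g, 0.01).n_edges == 1

    def test_keeps_highest_weights(self):
        g = random_patient_graph(np.random.default_rng(2), 5, edge_prob=2.0)
        out = sparsify_top_p(g, 0.2)
        kept = set(out.edge_weight)
        assert kept == set(sorted(g.edge_weight)[-2:])

    def test_nesting_and_idempotence(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            g = random_patient_graph(rng, 7, edge_prob=2.0)
            e02 = {tuple(e) for e in sparsify_top_p(g, 0.2).edge_index}
            e08 = {tuple(e) for e in sparsify_top_p(g, 0.8).edge_index}
            assert e02 <= e08 <= {tuple(e) for e in g.edge_index}
            again = sparsify_top_p(sparsify_top_p(g, 0.5), 0.5)
            assert again.n_edges == sparsify_top_p(g, 0.5).n_edges

    def test_tie_break_by_endpoint_names(self):
        values = np.zeros(4)
        g = PatientGraph(
            "t", ["a", "b", "c", "d"], values,
            np.array([[0, 1], [2, 3], [0, 2]]),
            np.array([0.9, 0.9, 0.3]),
            values.reshape(-1, 1),
        )
        out = sparsify_top_p(g, 1 / 6)  # budget: 1 edge of the K4 total
        # tie between (a,b) and (c,d) at 0.9 resolved lexicographically
        assert [tuple(e) for e in out.edge_index] == [(0, 1)]


class TestMinConnected:
    def test_triangle_example(self):
        values = np.zeros(3)
        g = PatientGraph("t", ["a", "b", "c"], values,
                         np.array([[0, 1], [1, 2], [0, 2]]),
                         np.array([0.9, 0.5, 0.2]), values.reshape(-1, 1))
        out = sparsify_min_connected(g)
        assert sorted(out.edge_weight) == [0.5, 0.9]

    def test_uniform_weights_unchanged(self):
        g = random_patient_graph(np.random.default_rng(4), 6, edge_prob=2.0)
        g.edge_weight[:] = 0.7
        out = sparsify_min_connected(g)
        assert out.n_edges == g.n_edges

    def test_matches_sweep_and_mst_bottleneck(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            g = random_patient_graph(rng, n, edge_prob=2.0)
            out = sparsify_min_connected(g)
            t_star = out.edge_weight.min()
            assert t_star == pytest.approx(sweep_min_connected_threshold(g))
            nxg = g.to_networkx()
            mst = nx.maximum_spanning_tree(nxg, weight="weight")
            bottleneck = min(d["weight"] for _, _, d in mst.edges(data=True))
            assert t_star == pytest.approx(bottleneck)
            # result is connected; any strictly higher threshold is not
            assert nx.is_connected(out.to_networkx())
            assert out.n_edges >= n - 1

    def test_disconnected_input_rejected(self):
        values = np.zeros(4)
        g = PatientGraph("t", ["a", "b", "c", "d"], values,
                         np.array([[0, 1]]), np.array([0.5]),
                         values.reshape(-1, 1))
        with pytest.raises(StructuralError):
            sparsify_min_connected(g)


class TestTopology:
    def test_path_graph_closed_form(self):
        values = np.array([0.1, 0.2, 0.3])
        g = PatientGraph("t", ["a", "b", "c"], values,
                         np.array([[0, 1], [1, 2]]), np.array([1.0, 1.0]),
                         values.reshape(-1, 1))
        out = attach_node_topology(g)
        feats = out.node_features
        np.testing.assert_allclose(feats[:, 0], values)
        np.testing.assert_allclose(feats[:, 1], [0.5, 1.0, 0.5])  # degree
        np.testing.assert_allclose(feats[:, 2], [1.0, 2.0, 1.0])  # strength
        np.testing.assert_allclose(feats[:, 3], [2 / 3, 1.0, 2 / 3])  # closeness
        np.testing.assert_allclose(feats[:, 4], [0.0, 1.0, 0.0])  # betweenness

    def test_complete_graph_degenerate_centralities(self):
        g = random_patient_graph(np.random.default_rng(6), 7, edge_prob=2.0)
        out = attach_node_topology(g)
        np.testing.assert_allclose(out.node_features[:, 1], 1.0)
        np.testing.assert_allclose(out.node_features[:, 4], 0.0, atol=1e-12)
        np.testing.assert_allclose(out.node_features[:, 3], 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            g = random_patient_graph(rng, n, edge_prob=rng.uniform(0.3, 1.0))
            out = attach_node_topology(g)
            deg, stren, clo, btw = brute_force_centralities(g)
            np.testing.assert_allclose(out.node_features[:, 1], deg, atol=1e-9)
            np.testing.assert_allclose(out.node_features[:, 2], stren, atol=1e-9)
            np.testing.assert_allclose(out.node_features[:, 3], clo, atol=1e-9)
            np.testing.assert_allclose(out.node_features[:, 4], btw, atol=1e-9)


class TestFoldGraphs:
    def test_label_blindness_of_test_graphs(self):
        spec = SyntheticSpec(n_patients=60, prevalence=0.3, n_features=8,
                             block_structure=(), marginal_effects=((0, 1.0),),
                             seed=1)
        table, _ = generate_cohort(spec)
        train, test = table.subset_rows(range(40)), table.subset_rows(range(40, 60))
        _, g1, _ = build_fold_graphs(train, test, 6, SparsifierConfig("top_p", 0.8),
                                     seed=0)
        test_flipped = test.copy()
        test_flipped.labels = 1 - test_flipped.labels
        _, g2, _ = build_fold_graphs(train, test_flipped, 6,
                                     SparsifierConfig("top_p", 0.8), seed=0)
        for a, b in zip(g1, g2):
            np.testing.assert_array_equal(a.edge_weight, b.edge_weight)
            np.testing.assert_array_equal(a.node_features, b.node_features)
            assert a.label is None and b.label is None

    def test_identical_rows_identical_graphs(self):
        spec = SyntheticSpec(n_patients=50, prevalence=0.3, n_features=6,
                             block_structure=(), seed=2)
        table, _ = generate_cohort(spec)
        tr_g, te_g, _ = build_fold_graphs(table, table, 5,
                                          SparsifierConfig("none"), seed=0)
        for a, b in zip(tr_g, te_g):
            np.testing.assert_array_equal(a.edge_weight, b.edge_weight)

    def test_planted_signal_raises_edge_weights(self):
        noise_spec = SyntheticSpec(n_patients=200, prevalence=0.3, n_features=6,
                                   block_structure=(), seed=3)
        signal_spec = SyntheticSpec(
            n_patients=200, prevalence=0.3, n_features=6, block_structure=(),
            marginal_effects=tuple((j, 1.5) for j in range(3)), seed=3,
        )
        means = []
        for spec in (noise_spec, signal_spec):
            table, _ = generate_cohort(spec)
            tr_g, _, _ = build_fold_graphs(table, table.subset_rows([0]), 6,
                                           SparsifierConfig("none"), seed=0)
            means.append(np.mean([g.edge_weight.mean() for g in tr_g]))
        assert means[1] > means[0] + 0.05
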