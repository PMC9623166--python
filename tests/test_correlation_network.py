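import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rhizocore.community_table import RelativeAbundanceTable
from rhizocore.correlation_network import (
    CorrelationResult,
    centralities,
    detect_modules,
    filter_edges,
    network_density,
    select_keystones,
    spearman_matrix,
    spearman_xy,
)

from conftest import spearman_oracle


def _rel_from_matrix(x):
    x = np.asarray(x, dtype=float)
    props = x / x.sum(axis=1, keepdims=True)
    return RelativeAbundanceTable(
        props,
        [f"S{i}" for i in range(x.shape[0])],
        [f"O{j}" for j in range(x.shape[1])],
    )


class TestSpearmanXY:
    def test_monotone_increasing(self):
        x = np.array([1, 3, 5, 7, 9, 11])
        rho, p = spearman_xy(x, x**3)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 720)  # 2 of 6! permutations tie the extreme

    def test_reversed_ranks(self):
        x = np.arange(6, dtype=float)
        rho, _ = spearman_xy(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_constant_column(self):
        rho, p = spearman_xy(np.ones(6), np.arange(6))
        assert (rho, p) == (0.0, 1.0)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match=">= 4"):
            spearman_xy(np.arange(3), np.arange(3))

    def test_rho_matches_oracle_with_ties(self, rng):
        x = np.array([1.0, 2.0, 2.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 2.0, 6.0, 5.0, 7.0])
        rho, _ = spearman_xy(x, y)
        assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_exact_p_matches_full_enumeration_n7(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        rho, p = spearman_xy(x, y)
        # independent oracle: enumerate all 7! permutations from scratch
        rho_obs = spearman_oracle(x, y)
        count = 0
        total = 0
        for perm in itertools.permutations(range(7)):
            total += 1
            if abs(spearman_oracle(x, y[list(perm)])) >= abs(rho_obs) - 1e-12:
                count += 1
        assert rho == pytest.approx(rho_obs, abs=1e-12)
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        rho1, p1 = spearman_xy(x, y)
        rho2, p2 = spearman_xy(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestSpearmanMatrix:
    def test_matrix_agrees_with_pairwise(self, rng):
        x = rng.integers(1, 100, size=(12, 6))
        rel = _rel_from_matrix(x)
        res = spearman_matrix(rel)
        df = rel.to_frame()
        for i in range(6):
            for j in range(i + 1, 6):
                rho, p = spearman_xy(df.iloc[:, i], df.iloc[:, j])
                assert res.rho[i, j] == pytest.approx(rho, abs=1e-10)
                assert res.p[i, j] == pytest.approx(p, abs=1e-10)

    def test_diagonal_and_symmetry(self, rng):
        res = spearman_matrix(_rel_from_matrix(rng.integers(1, 50, size=(10, 5))))
        np.testing.assert_allclose(np.diag(res.rho), 1.0)
        np.testing.assert_allclose(res.rho, res.rho.T)
        np.testing.assert_allclose(res.p, res.p.T)

    def test_restriction(self, rng):
        rel = _rel_from_matrix(rng.integers(1, 50, size=(10, 5)))
        res = spearman_matrix(rel, otu_ids=["O3", "O1"])
        assert res.otu_ids == ["O3", "O1"]


class TestFilterEdges:
    def _corr(self, rho, p, ids):
        return CorrelationResult(otu_ids=ids, rho=rho, p=p, n_samples=18)

    def test_threshold_rules(self):
        ids = ["A", "B", "C"]
        rho = np.array([[1, 0.85, 0.75], [0.85, 1, -0.9], [0.75, -0.9, 1]])
        p = np.array([[0, 0.005, 0.001], [0.005, 0, 0.002], [0.001, 0.002, 0]])
        net = filter_edges(self._corr(rho, p, ids))
        assert net.has_edge("A", "B") and net["A"]["B"]["sign"] == "positive"
        assert not net.has_edge("A", "C")  # fails r_min
        assert net.has_edge("B", "C") and net["B"]["C"]["sign"] == "negative"

    def test_isolates_retained(self):
        ids = ["A", "B", "C"]
        rho = np.eye(3)
        p = np.ones((3, 3))
        net = filter_edges(self._corr(rho, p, ids))
        assert set(net.nodes) == set(ids) and net.number_of_edges() == 0

    def test_brute_force_scan_30_nodes(self, rng):
        k = 30
        rho = rng.uniform(-1, 1, size=(k, k))
        rho = (rho + rho.T) / 2
        np.fill_diagonal(rho, 1.0)
        p = rng.uniform(0, 0.05, size=(k, k))
        p = (p + p.T) / 2
        np.fill_diagonal(p, 0.0)
        ids = [f"N{i}" for i in range(k)]
        net = filter_edges(self._corr(rho, p, ids), r_min=0.8, p_max=0.01)
        expected = set()
        for i in range(k):  # independent double loop
            for j in range(i + 1, k):
                if abs(rho[i, j]) >= 0.8 and p[i, j] <= 0.01:
                    expected.add(frozenset((ids[i], ids[j])))
        assert {frozenset(e) for e in net.edges} == expected

    def test_no_filter_gives_complete_graph(self, rng):
        rel = _rel_from_matrix(rng.integers(1, 50, size=(10, 6)))
        res = spearman_matrix(rel)
        net = filter_edges(res, r_min=1e-9, p_max=1.0)
        assert net.number_of_edges() == 6 * 5 // 2


class TestDensity:
    def test_complete_graph(self):
        assert network_density(nx.complete_graph(4)) == 1.0

    def test_path_graph(self):
        assert network_density(nx.path_graph(3)) == pytest.approx(2 / 3)

    def test_counting_oracle(self, rng):
        g = nx.gnp_random_graph(12, 0.4, seed=5)
        assert network_density(g) == pytest.approx(g.number_of_edges() / 66)

    def test_positive_only(self):
        g = nx.Graph()
        g.add_edge("a", "b", sign="positive")
        g.add_edge("b", "c", sign="negative")
        assert network_density(g, positive_only=True) == pytest.approx(2 * 1 / (3 * 2))

    def test_too_few_nodes(self):
        with pytest.raises(ValueError):
            network_density(nx.Graph([("a", "b")]), node_subset=["a"])


class TestDetectModules:
    def test_two_disjoint_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        part = detect_modules(g, seed=0)
        sizes = part.sizes()
        assert sorted(sizes.values()) == [6, 6]
        assert part.main_modules == [1, 2]
        assert part.modularity == pytest.approx(0.5)
        # never merges disjoint components
        comp_modules = [
            {part.module_of_node[n] for n in comp} for comp in nx.connected_components(g)
        ]
        assert all(len(mods) == 1 for mods in comp_modules)
        assert comp_modules[0] != comp_modules[1]

    def test_single_clique(self):
        part = detect_modules(nx.complete_graph(8), seed=0)
        assert len(part.sizes()) == 1

    def test_min_size_excludes_small_modules(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(3))
        part = detect_modules(g, seed=0, min_size=5)
        assert part.main_modules == [1]
        assert len(part.sizes()) == 2

    def test_edgeless_errors(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        with pytest.raises(ValueError, match="edgeless"):
            detect_modules(g, seed=0)

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(3)
        g = nx.Graph()
        truth = {}
        for b in range(3):
            for i in range(15):
                node = f"B{b}_{i}"
                g.add_node(node)
                truth[node] = b
        nodes = list(g.nodes)
        for i, u in enumerate(nodes):
            for v in nodes[i + 1 :]:
                prob = 0.9 if truth[u] == truth[v] else 0.02
                if rng.random() < prob:
                    g.add_edge(u, v)
        part = detect_modules(g, seed=0)
        from sklearn.metrics import adjusted_rand_score

        labels_true = [truth[n] for n in nodes]
        labels_pred = [part.module_of_node[n] for n in nodes]
        assert adjusted_rand_score(labels_true, labels_pred) >= 0.9

    def test_deterministic_under_seed(self):
        g = nx.gnp_random_graph(40, 0.15, seed=9)
        g.remove_nodes_from(list(nx.isolates(g)))
        p1 = detect_modules(g, seed=4)
        p2 = detect_modules(g, seed=4)
        assert p1.module_of_node == p2.module_of_node


def bfs_centrality_oracle(g):
    """All-pairs BFS: degree, Wasserman-Faust closeness, normalized betweenness."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    degree = {v: g.degree(v) for v in nodes}
    # shortest path lengths and counts via BFS per source
    dist = {}
    sigma = {}
    preds = {}
    for s in nodes:
        d = {s: 0}
        sig = {v: 0 for v in nodes}
        sig[s] = 1
        pred = {v: [] for v in nodes}
        queue = [s]
        while queue:
            u = queue.pop(0)
            for w in g[u]:
                if w not in d:
                    d[w] = d[u] + 1
                    queue.append(w)
                if d.get(w) == d[u] + 1:
                    sig[w] += sig[u]
                    pred[w].append(u)
        dist[s] = d
        sigma[s] = sig
        preds[s] = pred
    closeness = {}
    for v in nodes:
        reach = [u for u in nodes if u != v and u in dist[v]]
        if not reach:
            closeness[v] = 0.0
            continue
        total = sum(dist[v][u] for u in reach)
        nc = len(reach) + 1
        closeness[v] = ((nc - 1) / (n - 1)) * ((nc - 1) / total)
    betweenness = {v: 0.0 for v in nodes}
    for s in nodes:
        for t in nodes:
            if s >= t or t not in dist[s]:
                continue
            # count shortest s-t paths through each interior node
            for v in nodes:
                if v in (s, t) or v not in dist[s] or v not in dist[t]:
                    continue
                if dist[s][v] + dist[t][v] == dist[s][t]:
                    betweenness[v] += sigma[s][v] * sigma[t][v] / sigma[s][t]
    scale = (n - 1) * (n - 2) / 2
    for v in nodes:
        betweenness[v] /= scale
    return degree, closeness, betweenness


class TestCentralities:
    def test_three_node_path(self):
        cent = centralities(nx.path_graph(["A", "B", "C"]))
        assert cent.loc["B", "degree"] == 2
        assert cent.loc["B", "closeness"] == pytest.approx(1.0)
        assert cent.loc["B", "betweenness"] == pytest.approx(1.0)

    def test_star_graph(self):
        g = nx.star_graph(5)  # hub 0, 5 leaves
        cent = centralities(g)
        assert cent.loc[0, "betweenness"] == pytest.approx(1.0)
        assert all(cent.loc[leaf, "betweenness"] == 0 for leaf in range(1, 6))

    @pytest.mark.parametrize("graph_seed", range(10))
    def test_matches_bfs_oracle(self, graph_seed):
        g = nx.gnp_random_graph(10, 0.35, seed=graph_seed)
        cent = centralities(g)
        deg, clo, bet = bfs_centrality_oracle(g)
        for v in g.nodes:
            assert cent.loc[v, "degree"] == deg[v]
            assert cent.loc[v, "closeness"] == pytest.approx(clo[v], abs=1e-10)
            assert cent.loc[v, "betweenness"] == pytest.approx(bet[v], abs=1e-10)

    def test_leaf_in_tree_has_zero_betweenness(self):
        g = nx.random_labeled_tree(12, seed=2)
        cent = centralities(g)
        for v in g.nodes:
            if g.degree(v) == 1:
                assert cent.loc[v, "betweenness"] == 0


class TestSelectKeystones:
    def test_dominant_node_scores_three(self):
        cent = pd.DataFrame(
            {
                "degree": [9, 4, 3, 2],
                "closeness": [0.9, 0.5, 0.4, 0.3],
                "betweenness": [0.0, 0.2, 0.5, 0.9],
            },
            index=["hub", "n1", "n2", "n3"],
        )
        ks = select_keystones(cent, k=1)
        assert ks.nodes == ["hub"]
        assert ks.scores[0] == 3.0  # rank 1 on all three criteria

    def test_k_equals_n_returns_all(self):
        cent = centralities(nx.path_graph(4))
        ks = select_keystones(cent, k=4)
        assert len(ks.nodes) == 4

    def test_k_exceeding_n_warns(self):
        cent = centralities(nx.path_graph(4))
        with pytest.warns(UserWarning, match="exceeds"):
            ks = select_keystones(cent, k=10)
        assert len(ks.nodes) == 4

    def test_exhaustive_composite_sort_25_nodes(self):
        from scipy.stats import rankdata

        g = nx.gnp_random_graph(25, 0.25, seed=8)
        cent = centralities(g)
        ks = select_keystones(cent, k=10)
        # independent full enumeration
        score = {}
        d = cent["degree"].to_numpy()
        c = cent["closeness"].to_numpy()
        b = cent["betweenness"].to_numpy()
        rd, rc, rb = rankdata(-d), rankdata(-c), rankdata(b)
        for i, node in enumerate(cent.index):
            score[str(node)] = rd[i] + rc[i] + rb[i]
        expected = sorted(score, key=lambda v: (score[v], v))[:10]
        assert ks.nodes == expected

    def test_relabeling_invariance(self):
        g = nx.gnp_random_graph(15, 0.3, seed=1)
        mapping = {v: f"X{v:02d}" for v in g.nodes}
        ks1 = select_keystones(centralities(g), k=5)
        ks2 = select_keystones(centralities(nx.relabel_nodes(g, mapping)), k=5)
        assert [mapping[int(v)] for v in ks1.nodes] == ks2.nodes
        assert ks1.scores == ks2.scores
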