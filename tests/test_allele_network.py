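import itertools

import numpy as np
import pandas as pd
import pytest

from kelpshift import allele_network as an
from kelpshift.popgen import AlleleFrequencyTable


def _freq_table(cells):
    rows = [
        {"site": s, "locus": l, "allele": a, "count": c}
        for (s, l), alleles in cells.items()
        for a, c in alleles.items()
    ]
    loci = sorted({l for _, l in cells})
    return AlleleFrequencyTable(pd.DataFrame(rows), loci)


def _clique_blocks(sizes, within=0.9, between=0.1):
    """Block similarity matrix: constant within-block and between-block weights."""
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    sim = np.where(labels[:, None] == labels[None, :], within, between)
    np.fill_diagonal(sim, 1.0)
    names = [f"s{i}" for i in range(n)]
    return pd.DataFrame(sim, index=names, columns=names), labels


def exhaustive_best_partition(adj):
    """Brute-force modularity optimum over all set partitions (n <= 8)."""
    n = adj.shape[0]

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1 :]
            yield [[first]] + part

    best = -np.inf
    for part in partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for c, block in enumerate(part):
            labels[block] = c
        best = max(best, an.modularity_q(adj, labels))
    return best


class TestSimilarity:
    def test_identical_allele_sets_give_one(self):
        cells = {("A", "L1"): {1: 5, 2: 5}, ("B", "L1"): {1: 9, 2: 1}}
        sim = an.shared_allele_similarity(_freq_table(cells))
        assert sim.loc["A", "B"] == pytest.approx(1.0)

    def test_disjoint_allele_sets_give_zero(self):
        cells = {("A", "L1"): {1: 5, 2: 5}, ("B", "L1"): {3: 5, 4: 5}}
        sim = an.shared_allele_similarity(_freq_table(cells))
        assert sim.loc["A", "B"] == pytest.approx(0.0)

    def test_jaccard_matches_set_arithmetic(self):
        # union {1,2,3}, intersection {1,2} at the only shared locus -> 2/3
        cells = {("A", "L1"): {1: 4, 2: 6}, ("B", "L1"): {1: 2, 2: 2, 3: 8}}
        sim = an.shared_allele_similarity(_freq_table(cells))
        assert sim.loc["A", "B"] == pytest.approx(2.0 / 3.0)

    def test_pair_without_common_locus_warns_nan(self):
        cells = {("A", "L1"): {1: 4}, ("B", "L2"): {1: 4}}
        with pytest.warns(UserWarning, match="no typed locus"):
            sim = an.shared_allele_similarity(_freq_table(cells))
        assert np.isnan(sim.loc["A", "B"])


class TestLeadingEigenvector:
    def test_two_disconnected_cliques_q_half(self):
        sim, truth = _clique_blocks([4, 4], within=1.0, between=0.0)
        adj = sim.to_numpy().copy()
        np.fill_diagonal(adj, 0.0)
        labels, q = an.leading_eigenvector(adj)
        assert q == pytest.approx(0.5)
        assert len(np.unique(labels)) == 2
        assert (pd.Series(labels).groupby(truth).nunique() == 1).all()

    def test_single_clique_q_zero(self):
        adj = np.ones((5, 5)) - np.eye(5)
        labels, q = an.leading_eigenvector(adj)
        assert q == pytest.approx(0.0)
        assert len(np.unique(labels)) == 1

    def test_within_002_of_exhaustive_optimum_on_small_graphs(self):
        rng = np.random.default_rng(3)
        fixtures = []
        for n in (5, 6, 7, 8):
            a = rng.random((n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            a[a < 0.4] = 0.0  # sparsify
            fixtures.append(a)
        sim, _ = _clique_blocks([4, 4], within=0.9, between=0.05)
        a = sim.to_numpy().copy()
        np.fill_diagonal(a, 0.0)
        fixtures.append(a)
        for adj in fixtures:
            _, q = an.leading_eigenvector(adj)
            assert q >= exhaustive_best_partition(adj) - 0.02

    def test_node_order_invariance(self):
        sim, _ = _clique_blocks([3, 5], within=0.8, between=0.1)
        adj = sim.to_numpy().copy()
        np.fill_diagonal(adj, 0.0)
        labels, q = an.leading_eigenvector(adj)
        rng = np.random.default_rng(1)
        perm = rng.permutation(adj.shape[0])
        labels_p, q_p = an.leading_eigenvector(adj[np.ix_(perm, perm)])
        assert q_p == pytest.approx(q, abs=1e-12)
        # partitions agree up to relabeling
        mapping = {}
        for a, b in zip(labels[perm], labels_p):
            mapping.setdefault(a, b)
            assert mapping[a] == b


class TestPercolation:
    def test_planted_clusters_recovered_and_between_edges_removed(self):
        sim, truth = _clique_blocks([5, 5], within=0.85, between=0.2)
        net = an.percolate(sim)
        assert net.threshold > 0.2  # between-cluster edges dropped
        between = net.adjacency[np.ix_(truth == 0, truth == 1)]
        assert np.all(between == 0)
        assert net.n_communities == 2
        assert (pd.Series(net.communities).groupby(truth).nunique() == 1).all()

    def test_uniform_weights_single_community(self):
        sim, _ = _clique_blocks([6], within=0.7)
        with pytest.warns(UserWarning, match="degenerate"):
            net = an.percolate(sim)
        assert net.n_communities == 1
        assert net.modularity == pytest.approx(0.0)

    def test_threshold_scan_matches_exhaustive_scan(self):
        rng = np.random.default_rng(8)
        a = rng.random((5, 5))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        sim = pd.DataFrame(a, index=list("abcde"), columns=list("abcde"))
        net = an.percolate(sim)
        adj0 = a.copy()
        np.fill_diagonal(adj0, 0.0)
        best_q, best_t = -np.inf, None
        for t in np.unique(adj0[np.triu_indices(5, 1)]):
            adj_t = np.where(adj0 >= t, adj0, 0.0)
            _, q = an.leading_eigenvector(adj_t)
            if q > best_q + 1e-12:
                best_q, best_t = q, t
        assert net.threshold == pytest.approx(best_t)
        assert net.modularity == pytest.approx(best_q)

    def test_percolation_never_adds_edges(self, freqs):
        sim = an.shared_allele_similarity(freqs)
        net = an.percolate(sim)
        full = sim.to_numpy().copy()
        np.fill_diagonal(full, 0.0)
        assert (net.adjacency > 0).sum() <= (full > 0).sum()
        # deterministic scan
        net2 = an.percolate(sim)
        assert net2.threshold == net.threshold
        np.testing.assert_array_equal(net2.communities, net.communities)


class TestPermutationTest:
    def test_planted_structure_highly_significant(self):
        sim, _ = _clique_blocks([8, 8], within=0.9, between=0.1)
        net = an.percolate(sim)
        p = an.modularity_permutation_test(net, n_perm=10_000, seed=0)
        assert p <= 0.001

    def test_null_weights_rarely_significant(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = rng.random((12, 12))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            labels = np.repeat([0, 1], 6)  # arbitrary planted labels
            net = an.SiteNetwork(
                sites=[f"s{i}" for i in range(12)],
                adjacency=a,
                threshold=0.0,
                communities=labels,
                modularity=an.modularity_q(a, labels),
            )
            if an.modularity_permutation_test(net, n_perm=199, seed=seed) > 0.05:
                hits += 1
        assert hits >= 90

    def test_preconditions_and_degenerate_cases(self):
        sim, _ = _clique_blocks([4, 4])
        net = an.percolate(sim)
        with pytest.raises(ValueError):
            an.modularity_permutation_test(net, n_perm=0)
        one = an.SiteNetwork(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]), 0.0, np.zeros(2, int), 0.0)
        assert an.modularity_permutation_test(one, n_perm=10) == 1.0


class TestCentrality:
    def test_star_center_is_maximal(self):
        n = 6
        adj = np.zeros((n, n))
        adj[0, 1:] = adj[1:, 0] = 1.0
        cent = an.eigenvector_centrality(adj)
        assert cent[0] == pytest.approx(1.0)
        assert (cent[1:] < 1.0).all()

    def test_complete_graph_ties_leave_hub_set_empty(self):
        sim, _ = _clique_blocks([6], within=0.7)
        adj = sim.to_numpy().copy()
        np.fill_diagonal(adj, 0.0)
        net = an.SiteNetwork([f"s{i}" for i in range(6)], adj, 0.0, np.zeros(6, int), 0.0)
        cent, hubs = an.centrality_hubs(net)
        np.testing.assert_allclose(cent, 1.0, atol=1e-8)
        assert hubs == []

    def test_bridge_node_is_a_hub(self):
        # two 4-cliques joined only through a bridge node
        n = 9
        adj = np.zeros((n, n))
        for block in (range(4), range(4, 8)):
            for i, j in itertools.combinations(block, 2):
                adj[i, j] = adj[j, i] = 1.0
        bridge = 8
        for j in range(8):
            adj[bridge, j] = adj[j, bridge] = 0.8
        net = an.SiteNetwork([f"s{i}" for i in range(n)], adj, 0.0, np.zeros(n, int), 0.0)
        _, hubs = an.centrality_hubs(net)
        assert "s8" in hubs

    def test_matches_networkx_cross_check(self):
        import networkx as nx

        rng = np.random.default_rng(5)
        a = rng.random((7, 7))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        cent = an.eigenvector_centrality(a)
        g = nx.from_numpy_array(a)
        ref = nx.eigenvector_centrality_numpy(g, weight="weight")
        ref = np.array([ref[i] for i in range(7)])
        np.testing.assert_allclose(cent, ref / ref.max(), atol=1e-6)
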