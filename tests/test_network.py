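"""Co-expression network: thresholding, topology, power law, walktrap, enrichment."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybridase import network as hn


def net_of(graph: nx.Graph) -> hn.AlleleNetwork:
    return hn.AlleleNetwork(graph=graph, r_min=0.98, p_max=0.05)


def set_partitions(items):
    """All set partitions of ``items`` (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [partition[i] | {first}] + partition[i + 1:]
        yield partition + [{first}]


def brute_force_best_modularity(g: nx.Graph) -> float:
    """Exhaustive maximum modularity over all partitions (<= 8 nodes)."""
    return max(
        nx.algorithms.community.modularity(g, parts)
        for parts in set_partitions(list(g.nodes))
    )


class TestBuildNetwork:
    def test_identical_profiles_connected(self):
        prof = pd.DataFrame([np.arange(8.0), np.arange(8.0)], index=["a", "b"])
        net = hn.build_network(prof)
        assert net.graph.has_edge("a", "b")
        assert net.graph["a"]["b"]["r"] == pytest.approx(1.0)

    def test_anticorrelated_profiles_not_connected(self):
        prof = pd.DataFrame([np.arange(8.0), -np.arange(8.0), np.arange(8.0)],
                            index=["a", "b", "c"])
        net = hn.build_network(prof)
        assert not net.graph.has_edge("a", "b")

    def test_r_threshold_is_binding_at_8_cells(self):
        # at n=8 and r just under 0.98 the parametric p is ~2e-5 << 0.05,
        # so the correlation threshold, not the p threshold, decides edges
        t = 0.98 * math.sqrt(6 / (1 - 0.98**2))
        p = 2 * stats.t.sf(t, df=6)
        assert p == pytest.approx(1.97e-5, rel=0.01)
        rng = np.random.default_rng(0)
        base = rng.normal(size=8)
        near = base + rng.normal(0, 0.12, 8)
        prof = pd.DataFrame([base, near], index=["a", "b"])
        r = np.corrcoef(prof)[0, 1]
        net = hn.build_network(prof)
        assert net.graph.has_edge("a", "b") == (r >= 0.98)

    def test_constant_profile_excluded_with_warning(self):
        prof = pd.DataFrame([np.arange(8.0), np.zeros(8)], index=["a", "b"])
        with pytest.warns(RuntimeWarning, match="constant"):
            net = hn.build_network(prof)
        assert "b" not in net.graph

    def test_monotone_in_r_min(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=8)
        prof = pd.DataFrame(
            [base + rng.normal(0, s, 8) for s in (0.01, 0.05, 0.1, 0.5, 1.0)],
            index=list("abcde"),
        )
        loose = hn.build_network(prof, r_min=0.9)
        tight = hn.build_network(prof, r_min=0.99)
        assert set(tight.graph.edges) <= set(loose.graph.edges)


class TestTopology:
    def test_path_graph_average_path_length(self):
        rep = hn.topology_stats(net_of(nx.path_graph(list("abc"))), power_law=False)
        assert rep.average_path_length == pytest.approx(4 / 3)

    def test_complete_graph(self):
        rep = hn.topology_stats(net_of(nx.complete_graph(5)), power_law=False)
        assert rep.average_path_length == pytest.approx(1.0)
        assert rep.degree_min == rep.degree_max == 4

    def test_disconnected_pairs_excluded(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        rep = hn.topology_stats(net_of(g), power_law=False)
        assert rep.average_path_length == pytest.approx(1.0)


class TestPowerLaw:
    def test_exponent_recovery(self):
        draws = hn.sample_power_law(1000, 2.43, seed=2)
        fit = hn.fit_power_law(draws, n_bootstrap=10, seed=0)
        assert abs(fit["gamma"] - 2.43) < 0.3

    @pytest.mark.parametrize("gamma", [2.0, 3.0])
    def test_recovery_across_exponents(self, gamma):
        draws = hn.sample_power_law(2000, gamma, seed=3)
        assert abs(hn._mle_gamma(draws, 1) - gamma) < 0.2

    def test_higher_x_min_fits_the_tail(self):
        draws = hn.sample_power_law(3000, 2.43, seed=9)
        fit = hn.fit_power_law(draws[draws >= 2], x_min=2, n_bootstrap=5, seed=0)
        assert abs(fit["gamma"] - 2.43) < 0.3

    def test_poisson_degrees_fit_worse_than_power_law(self):
        rng = np.random.default_rng(4)
        worse = 0
        reps = 50
        for _ in range(reps):
            pl = hn.sample_power_law(300, 2.43, seed=rng)
            po = rng.poisson(8, 300) + 1
            ks_pl = hn._ks_stat(pl, hn._mle_gamma(pl, 1), 1)
            ks_po = hn._ks_stat(po, hn._mle_gamma(po, 1), 1)
            worse += ks_po > ks_pl
        assert worse / reps >= 0.9

    def test_degenerate_degrees_rejected(self):
        with pytest.raises(ValueError):
            hn.fit_power_law(np.full(100, 3))


class TestWalktrap:
    def test_two_triangles(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g})
        labels = hn.walktrap(net_of(g))
        assert len(set(labels.values())) == 2
        assert labels["n0"] == labels["n1"] == labels["n2"]
        assert labels["n3"] == labels["n4"] == labels["n5"]

    def test_complete_graph_single_community(self):
        labels = hn.walktrap(net_of(nx.complete_graph(6)))
        assert len(set(labels.values())) == 1

    def test_near_optimal_modularity_on_small_graphs(self):
        fixtures = [
            nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]),
            nx.path_graph(7),
            nx.cycle_graph(8),
            nx.barbell_graph(3, 1),
            nx.star_graph(6),
        ]
        for g in fixtures:
            g = nx.relabel_nodes(g, {v: f"v{v}" for v in g})
            labels = hn.walktrap(net_of(g))
            parts = {}
            for v, l in labels.items():
                parts.setdefault(l, set()).add(v)
            q = nx.algorithms.community.modularity(g, parts.values())
            q_best = brute_force_best_modularity(g)
            assert q >= 0.9 * q_best - 1e-9

    def test_node_order_invariance(self):
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(12, 0.3, seed=7)
        g = nx.relabel_nodes(g, {v: f"x{v}" for v in g})
        l1 = hn.walktrap(net_of(g))
        shuffled = nx.Graph()
        edges = list(g.edges)
        rng.shuffle(edges)
        shuffled.add_edges_from(edges)
        l2 = hn.walktrap(net_of(shuffled))
        parts1 = frozenset(frozenset(v for v in l1 if l1[v] == c) for c in set(l1.values()))
        parts2 = frozenset(frozenset(v for v in l2 if l2[v] == c) for c in set(l2.values()))
        assert parts1 == parts2

    def test_planted_two_block_profiles_recovered(self):
        rng = np.random.default_rng(6)
        sig_a, sig_b = rng.normal(size=8), rng.normal(size=8)
        rows, names = [], []
        for i in range(10):
            rows.append(sig_a + rng.normal(0, 0.01, 8))
            names.append(f"scg{i:04d}")
        for i in range(10):
            rows.append(sig_b + rng.normal(0, 0.01, 8))
            names.append(f"sug{i:04d}")
        net = hn.build_network(pd.DataFrame(rows, index=names), r_min=0.98)
        labels = hn.walktrap(net)
        blocks = {frozenset(v for v in labels if labels[v] == c) for c in set(labels.values())}
        assert blocks == {
            frozenset(names[:10]) & set(labels), frozenset(names[10:]) & set(labels)
        } or blocks == {frozenset(names[:10]), frozenset(names[10:])}


class TestComposition:
    def test_pure_cluster_flagged(self):
        g = nx.Graph()
        for i in range(9):
            g.add_edge(f"sug{i}", f"sug{i+1}")
        for i in range(9):
            g.add_edge(f"scg{i}", f"scg{i+1}")
        net = net_of(g)
        hn.walktrap(net)
        comp = hn.cluster_composition(net)
        pure_su = comp[comp.prop_su == 1.0]
        assert len(pure_su) >= 1
        assert pure_su.flagged.all()

    def test_balanced_cluster_not_flagged(self):
        g = nx.complete_graph(10)
        g = nx.relabel_nodes(g, {i: (f"scg{i}" if i < 5 else f"sug{i}") for i in g})
        net = net_of(g)
        hn.walktrap(net)
        comp = hn.cluster_composition(net)
        assert not comp.flagged.any()
        assert (comp.binom_p > 0.05).all()


class TestEnrichment:
    def test_exact_term_astronomically_small(self):
        universe = {f"g{i}" for i in range(1000)}
        term = {f"g{i}" for i in range(20)}
        res = hn.enrichment(term, {"T": term}, universe)
        assert res.loc[0, "p_value"] < 1e-30

    def test_random_clusters_rarely_enriched(self):
        rng = np.random.default_rng(8)
        universe = [f"g{i}" for i in range(500)]
        annotation = {
            f"T{j}": set(rng.choice(universe, 25, replace=False)) for j in range(30)
        }
        hits = 0
        for _ in range(100):
            cluster = set(rng.choice(universe, 20, replace=False))
            res = hn.enrichment(cluster, annotation, set(universe))
            if len(res) and res.p_adj.min() <= 0.05:
                hits += 1
        assert hits <= 10

    def test_empty_cluster_no_rows(self):
        res = hn.enrichment(set(), {"T": {"a"}}, {"a", "b"})
        assert len(res) == 0
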