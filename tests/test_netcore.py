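import math

import networkx as nx
import numpy as np
import pytest

from targetspread import (
    EdgeListFormatError,
    Network,
    ParameterError,
    bfs_distances,
    generate_ba,
    generate_gn,
    generate_ws,
    load_edge_list,
    network_stats,
    write_edge_list,
)

from _oracles import floyd_warshall


class TestEdgeListIO:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "g.txt"
        p.write_text("a b\nb c\n")
        net = load_edge_list(p)
        assert net.n == 3
        assert sorted((net.labels[i], net.labels[j]) for i, j in net.edges()) == [
            ("a", "b"),
            ("b", "c"),
        ]

    def test_self_loops_and_duplicates_dropped(self, tmp_path):
        p = tmp_path / "g.txt"
        p.write_text("a a\na b\na b\n")
        net = load_edge_list(p)
        assert net.n == 2
        assert net.n_edges == 1

    def test_comments_blanks_and_extra_tokens(self, tmp_path):
        p = tmp_path / "g.txt"
        p.write_text("# header\n\na b 3.5 extra\nb c 1\n")
        net = load_edge_list(p)
        assert net.n == 3 and net.n_edges == 2

    def test_single_token_line_reports_line_number(self, tmp_path):
        p = tmp_path / "g.txt"
        p.write_text("a b\nc\n")
        with pytest.raises(EdgeListFormatError, match=":2:"):
            load_edge_list(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(OSError):
            load_edge_list(tmp_path / "nope.txt")

    def test_netsci_shaped_input(self, tmp_path):
        # 379 labels, 914 distinct edges, like the collaboration network
        rng = np.random.default_rng(5)
        edges = set()
        while len(edges) < 914:
            i, j = rng.integers(379, size=2)
            if i != j:
                edges.add((min(i, j), max(i, j)))
        # force every label to appear
        lines = [f"n{i} n{j}" for i, j in edges]
        p = tmp_path / "netsci_shaped.txt"
        p.write_text("\n".join(lines) + "\n")
        net = load_edge_list(p)
        assert net.n_edges == 914

    def test_round_trip(self, tmp_path, rng):
        net = generate_ba(40, 2, rng)
        p = tmp_path / "rt.txt"
        write_edge_list(net, p)
        net2 = load_edge_list(p)

        def label_edges(n):
            return {frozenset((n.labels[i], n.labels[j])) for i, j in n.edges()}

        assert label_edges(net) == label_edges(net2)
        assert set(net.labels) == set(net2.labels)

    def test_gml_labels_only(self, tmp_path):
        from targetspread import load_gml

        p = tmp_path / "g.gml"
        p.write_text(
            'graph [\n  node [ id 0 label "a" ]\n  node [ id 1 label "b" ]\n'
            "  edge [ source 0 target 1 weight 2.5 ]\n]\n"
        )
        net = load_gml(p)
        assert net.n == 2 and net.n_edges == 1 and "a" in net and "b" in net

    def test_first_appearance_fixes_indexing(self, tmp_path):
        p = tmp_path / "g.txt"
        p.write_text("x y\na x\n")
        net = load_edge_list(p)
        assert net.labels == ["x", "y", "a"]


class TestGenerators:
    def test_ba_shape_and_connectivity(self, rng):
        net = generate_ba(500, 2, rng)
        assert net.n == 500
        assert abs(net.degrees.mean() - 4.0) < 0.1
        assert nx.is_connected(net.to_networkx())

    def test_ba_minimal_tree(self, rng):
        net = generate_ba(3, 1, rng)
        assert net.n == 3 and net.n_edges == 2

    def test_ba_param_error(self, rng):
        with pytest.raises(ParameterError):
            generate_ba(3, 3, rng)

    def test_ws_mean_degree_exact(self, rng):
        net = generate_ws(500, 4, 0.1, rng)
        assert net.n == 500
        assert net.n_edges == 1000  # rewiring preserves edge count

    def test_ws_p0_is_deterministic_ring(self):
        a = generate_ws(10, 4, 0.0, np.random.default_rng(1))
        b = generate_ws(10, 4, 0.0, np.random.default_rng(99))
        assert set(a.edges()) == set(b.edges())
        assert np.all(a.degrees == 4)

    def test_ws_p1_preserves_edge_count(self, rng):
        assert generate_ws(100, 4, 1.0, rng).n_edges == 200

    def test_ws_param_errors(self, rng):
        with pytest.raises(ParameterError):
            generate_ws(10, 3, 0.1, rng)
        with pytest.raises(ParameterError):
            generate_ws(10, 4, 1.5, rng)

    def test_ba_heavier_tailed_than_ws(self):
        # same mean degree, BA max degree should dominate over seeds
        ba_max, ws_max = [], []
        for s in range(50):
            ba_max.append(generate_ba(200, 2, np.random.default_rng(s)).degrees.max())
            ws_max.append(
                generate_ws(200, 4, 0.1, np.random.default_rng(s)).degrees.max()
            )
        assert np.mean(ba_max) > np.mean(ws_max) + 5

    def test_generators_seed_reproducible(self):
        for gen in (
            lambda r: generate_ba(60, 2, r),
            lambda r: generate_ws(60, 4, 0.3, r),
            lambda r: generate_gn(3, 10, 4.0, 0.8, r),
        ):
            a = gen(np.random.default_rng(7))
            b = gen(np.random.default_rng(7))
            assert set(a.edges()) == set(b.edges())

    def test_generators_simple_undirected(self, rng):
        for net in (
            generate_ba(80, 3, rng),
            generate_ws(80, 6, 0.5, rng),
            generate_gn(4, 20, 8.0, 0.7, rng),
        ):
            g = net.to_networkx()
            assert not any(i == j for i, j in g.edges())
            for i, nbrs in enumerate(net.adj):
                for j in nbrs:
                    assert i in net.adj[j]

    def test_gn_fully_assortative_is_disconnected(self, rng):
        net = generate_gn(4, 32, 16.0, 1.0, rng)
        comps = list(nx.connected_components(net.to_networkx()))
        assert len(comps) >= 4
        # no edge crosses the planted partition
        for i, j in net.edges():
            assert net.community[i] == net.community[j]

    def test_gn_mean_degree(self):
        # averaged over draws: one draw of 128 nodes fluctuates by ~0.5
        means = [
            generate_gn(4, 32, 16.0, 0.5, np.random.default_rng(s)).degrees.mean()
            for s in range(10)
        ]
        assert abs(np.mean(means) - 16.0) / 16.0 < 0.05
        net = generate_gn(4, 32, 16.0, 0.5, np.random.default_rng(0))
        crossing = sum(net.community[i] != net.community[j] for i, j in net.edges())
        assert crossing > 0

    def test_gn_modularity_increases_with_frac_in(self, rng):
        part = [set(range(10)), set(range(10, 20))]
        strong = generate_gn(2, 10, 4.0, 0.9, np.random.default_rng(3))
        weak = generate_gn(2, 10, 4.0, 0.5, np.random.default_rng(3))
        q_strong = nx.algorithms.community.modularity(strong.to_networkx(), part)
        q_weak = nx.algorithms.community.modularity(weak.to_networkx(), part)
        assert q_strong > q_weak

    def test_gn_infeasible_degree(self, rng):
        with pytest.raises(ParameterError):
            generate_gn(2, 3, 10.0, 1.0, rng)


class TestBFS:
    def test_path_single_source(self, path5):
        d = bfs_distances(path5, ["t"])
        assert d.tolist() == [0, 1, 2, 3, 4]

    def test_min_over_sources(self, path5):
        d = bfs_distances(path5, ["t", "d"])
        assert d.tolist() == [0, 1, 2, 1, 0]

    def test_unreachable_is_inf(self):
        net = Network.from_label_pairs([("a", "b"), ("c", "d")])
        d = bfs_distances(net, ["a"])
        assert d[net.index_of("c")] == math.inf
        assert d[net.index_of("d")] == math.inf

    def test_unknown_source(self, path5):
        with pytest.raises(KeyError):
            bfs_distances(path5, ["zz"])

    def test_empty_sources(self, path5):
        with pytest.raises(ParameterError):
            bfs_distances(path5, [])

    @pytest.mark.parametrize("seed", range(8))
    def test_against_floyd_warshall(self, seed):
        net = Network.from_networkx(nx.gnp_random_graph(25, 0.12, seed=seed))
        d_all = floyd_warshall(net)
        rng = np.random.default_rng(seed)
        sources = rng.choice(25, size=3, replace=False)
        expect = d_all[sources].min(axis=0)
        got = bfs_distances(net, sources.tolist())
        assert np.array_equal(got, expect)


class TestNetworkStats:
    def test_four_regular(self):
        net = generate_ws(20, 4, 0.0, np.random.default_rng(0))
        st = network_stats(net)
        assert st.lambda_c == pytest.approx(1 / 3)

    def test_path3_hand_values(self):
        net = Network.from_label_pairs([("a", "b"), ("b", "c")])
        st = network_stats(net)
        assert st.mean_degree == pytest.approx(4 / 3)
        assert st.second_moment == pytest.approx(2.0)
        assert st.diameter == 2

    def test_star_hand_values(self, star5):
        st = network_stats(star5)
        assert st.diameter == 2
        assert st.mean_degree == pytest.approx(8 / 5)
        assert st.second_moment == pytest.approx(4.0)
        assert st.lambda_c == pytest.approx((8 / 5) / (4 - 8 / 5))

    def test_degenerate_lambda_c_is_inf_not_error(self):
        net = Network.from_label_pairs([("a", "b")])  # perfect matching
        st = network_stats(net)
        assert st.lambda_c == math.inf

    def test_diameter_on_largest_component(self):
        net = Network.from_label_pairs([("a", "b"), ("b", "c"), ("x", "y")])
        assert network_stats(net).diameter == 2
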