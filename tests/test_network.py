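import itertools

import numpy as np
import pytest

from comodnet.network import (
    Edge,
    Network,
    binarize_sample_strings,
    clustering_coefficient_profile,
    degree_distribution,
    extract_network,
    order_edges,
    read_network,
    write_network,
)
from comodnet.pairwise import ClusterResult, PairResult


def _pair(a, b, rhos, strings=None, skipped=()):
    clusters = []
    for k, r in enumerate(rhos):
        clusters.append(
            ClusterResult(
                index=k,
                size=40,
                rho=r,
                sample_string=(strings[k] if strings else "1" * 6),
                reason="below range" if k in skipped else None,
            )
        )
    return PairResult(gene_a=a, gene_b=b, clusters=clusters)


def _edge(a, b, k, rho, s):
    return Edge(gene_a=a, gene_b=b, cluster_index=k, rho=rho, sample_string=s)


class TestExtract:
    def test_threshold_and_perfect_correlation_rules(self):
        results = [
            _pair("A", "B", [0.95]),
            _pair("A", "C", [0.9]),
            _pair("B", "C", [0.5]),
            _pair("C", "D", [1.0]),
            _pair("D", "E", [-0.92]),
        ]
        net = extract_network(results, 0.86)
        assert len(net.edges) == 3
        rhos = sorted(e.rho for e in net.edges)
        assert rhos == pytest.approx([-0.92, 0.9, 0.95])

    def test_impossible_tau_gives_empty_network(self):
        net = extract_network([_pair("A", "B", [0.99])], 1.01)
        assert net.edges == [] and net.nodes == set()

    def test_skipped_clusters_never_become_edges(self):
        net = extract_network([_pair("A", "B", [0.99], skipped={0})], 0.5)
        assert net.edges == []

    def test_monotone_in_tau(self):
        rng = np.random.default_rng(0)
        results = [
            _pair(f"G{i}", f"G{j}", [float(rng.uniform(-1, 1))])
            for i, j in itertools.combinations(range(8), 2)
        ]
        keys = lambda net: {(e.gene_a, e.gene_b, e.cluster_index)
                            for e in net.edges}
        lo = keys(extract_network(results, 0.3))
        hi = keys(extract_network(results, 0.7))
        assert hi <= lo

    def test_multi_edges_preserved_with_distinct_strings(self):
        res = _pair("A", "B", [0.9, -0.88], strings=["110000", "001100"])
        net = extract_network([res], 0.86)
        assert len(net.edges) == 2
        assert {e.sample_string for e in net.edges} == {"110000", "001100"}
        assert {e.cluster_index for e in net.edges} == {0, 1}

    def test_endpoints_canonically_ordered(self):
        net = extract_network([_pair("Z", "A", [0.9])], 0.5)
        assert net.edges[0].pair == ("A", "Z")


class TestBinarize:
    def test_stated_digit_rule(self):
        net = Network(edges=[_edge("A", "B", 0, 0.9, "109681")])
        np.testing.assert_array_equal(
            binarize_sample_strings(net), [[1, 0, 0, 0, 0, 1]]
        )

    def test_all_nine_string_gives_zero_row(self):
        net = Network(edges=[_edge("A", "B", 0, 0.9, "999999")])
        assert binarize_sample_strings(net).sum() == 0

    def test_column_sums_count_edge_participation(self):
        net = Network(
            edges=[
                _edge("A", "B", 0, 0.9, "1100"),
                _edge("A", "C", 0, 0.9, "1010"),
                _edge("B", "C", 0, 0.9, "1001"),
            ]
        )
        mat = binarize_sample_strings(net)
        np.testing.assert_array_equal(mat.sum(axis=0), [3, 1, 1, 1])


class TestOrderEdges:
    def test_identical_rows_adjacent(self):
        mat = np.array([[1, 1, 0, 0], [0, 0, 1, 1], [1, 1, 0, 0]])
        order = list(order_edges(mat))
        assert abs(order.index(0) - order.index(2)) == 1

    def test_orthogonal_blocks_stay_contiguous(self):
        rng = np.random.default_rng(1)
        a = np.zeros((5, 10), dtype=int)
        a[:, :5] = rng.integers(0, 2, (5, 5)) | np.eye(5, dtype=int)[:, :5]
        b = np.zeros((5, 10), dtype=int)
        b[:, 5:] = 1
        mat = np.vstack([a, b])
        order = list(order_edges(mat))
        first_half = {order.index(k) for k in range(5)}
        assert first_half in ({0, 1, 2, 3, 4}, {5, 6, 7, 8, 9})

    def test_permutation_is_bijection(self):
        rng = np.random.default_rng(2)
        mat = rng.integers(0, 2, (12, 7))
        order = order_edges(mat)
        assert sorted(order) == list(range(12))

    def test_single_edge_identity(self):
        assert list(order_edges(np.array([[1, 0]]))) == [0]


class TestGraphStatistics:
    def test_triangle_graph(self):
        net = Network(
            edges=[
                _edge("A", "B", 0, 0.9, "1"),
                _edge("A", "C", 0, 0.9, "1"),
                _edge("B", "C", 0, 0.9, "1"),
            ]
        )
        assert degree_distribution(net) == {2: 3}
        assert clustering_coefficient_profile(net) == [(2, 1.0)]

    def test_star_hub_has_zero_clustering(self):
        net = Network(
            edges=[_edge("H", f"L{k}", 0, 0.9, "1") for k in range(4)]
        )
        assert degree_distribution(net) == {1: 4, 4: 1}
        profile = dict(clustering_coefficient_profile(net))
        assert profile[4] == 0.0

    def test_clustering_matches_brute_force_triangle_count(self):
        rng = np.random.default_rng(3)
        nodes = [f"N{k}" for k in range(20)]
        edges = [
            _edge(*sorted((nodes[i], nodes[j])), 0, 0.9, "1")
            for i in range(20)
            for j in range(i + 1, 20)
            if rng.random() < 0.25
        ]
        net = Network(edges=edges)
        adj = {n: set() for n in nodes}
        for e in edges:
            adj[e.gene_a].add(e.gene_b)
            adj[e.gene_b].add(e.gene_a)
        # brute-force local clustering: triangles / possible pairs
        expected: dict[str, float] = {}
        for n in nodes:
            nb = sorted(adj[n])
            k = len(nb)
            if k < 2:
                expected[n] = 0.0
                continue
            tri = sum(
                1
                for x in range(k)
                for y in range(x + 1, k)
                if nb[y] in adj[nb[x]]
            )
            expected[n] = tri / (k * (k - 1) / 2)
        profile = dict(clustering_coefficient_profile(net))
        by_degree: dict[int, list[float]] = {}
        for n in nodes:
            if adj[n]:
                by_degree.setdefault(len(adj[n]), []).append(expected[n])
        for d, vals in by_degree.items():
            assert profile[d] == pytest.approx(float(np.mean(vals)), abs=1e-12)

    def test_empty_network_empty_outputs(self):
        net = Network()
        assert degree_distribution(net) == {}
        assert clustering_coefficient_profile(net) == []


class TestNetworkIO:
    def test_round_trip(self, tmp_path):
        net = Network(
            edges=[
                _edge("A", "B", 0, 0.912345, "1109"),
                _edge("A", "B", 1, -0.87, "0016"),
            ],
            threshold=0.85,
            sample_ids=["S1", "S2", "S3", "S4"],
        )
        p = tmp_path / "net.tsv"
        write_network(net, p)
        back = read_network(p)
        assert back.threshold == pytest.approx(0.85)
        assert back.sample_ids == net.sample_ids
        assert len(back.edges) == 2
        for a, b in zip(back.edges, net.edges):
            assert a.pair == b.pair
            assert a.cluster_index == b.cluster_index
            assert a.sample_string == b.sample_string
            assert a.rho == pytest.approx(b.rho, rel=1e-9)

    def test_heatmap_renders(self, tmp_path):
        net = Network(
            edges=[
                _edge("A", "B", 0, 0.9, "1100"),
                _edge("A", "C", 0, 0.9, "0011"),
            ],
            sample_ids=["S1", "S2", "S3", "S4"],
        )
        from comodnet.network import plot_sample_heatmap

        out = tmp_path / "heat.png"
        plot_sample_heatmap(
            net, out, sample_groups={"S1": "X", "S2": "X", "S3": "Y", "S4": "Y"}
        )
        assert out.stat().st_size > 0
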