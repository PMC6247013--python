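from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

import kmernet as kn
from kmernet.af_distance import DistanceRecord, EdgeList
from kmernet.errors import TaxonomyError
from kmernet.networks import INetwork, stats_tsv

from .oracles import brute_clique_stats


def edge_list(pairs_with_s, isolates=None, mode="whole"):
    records = [
        DistanceRecord(a, b, mode, 0.0, 0.0, 10.0 - s, s) for a, b, s in pairs_with_s
    ]
    if isolates is None:
        isolates = sorted({x for a, b, _ in pairs_with_s for x in (a, b)})
    return EdgeList(mode=mode, k=25, strand_policy="both", transform="linear",
                    isolates=list(isolates), records=records)


def graph_net(edges, nodes=None, t=0.0):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for a, b in edges:
        g.add_edge(a, b, S=5.0)
    return INetwork(t=t, graph=g)


class TestBuildINetwork:
    def test_threshold_keeps_geq(self):
        el = edge_list([("a", "b", 3.0), ("a", "c", 5.0), ("b", "c", 4.0)])
        net = kn.build_inetwork(el, 4.0)
        assert set(map(frozenset, net.graph.edges)) == {
            frozenset({"a", "c"}), frozenset({"b", "c"})
        }
        strict = kn.build_inetwork(el, 4.0, strict_threshold=True)
        assert set(map(frozenset, strict.graph.edges)) == {frozenset({"a", "c"})}

    def test_singletons_kept_as_nodes(self):
        el = edge_list([("a", "b", 3.0)], isolates=["a", "b", "lonely"])
        net = kn.build_inetwork(el, 0.0)
        assert net.x == 3 and net.y == 1
        assert kn.nonsingleton_count(net) == 2

    def test_above_max_s_empty(self):
        el = edge_list([("a", "b", 3.0), ("b", "c", 5.0)])
        net = kn.build_inetwork(el, 6.0)
        assert net.y == 0 and kn.nonsingleton_count(net) == 0


class TestDensity:
    def test_fig_worked_examples(self):
        """A 4-node network at 0, 3 and 6 edges has D = 0.0, 0.5, 1.0."""
        nodes = list("abcd")
        all_edges = list(itertools.combinations(nodes, 2))
        for n_edges, expected in [(0, 0.0), (3, 0.5), (6, 1.0)]:
            net = graph_net(all_edges[:n_edges], nodes=nodes)
            assert kn.density(net) == pytest.approx(expected)

    def test_complete_graph(self):
        net = graph_net(itertools.combinations(range(5), 2))
        assert kn.density(net) == 1.0

    def test_undefined_below_two_nodes(self):
        with pytest.raises(ValueError):
            kn.density(graph_net([], nodes=["a"]))


class TestCliqueStats:
    def test_triangle(self):
        z, n = kn.clique_stats(graph_net([(0, 1), (1, 2), (0, 2)]))
        assert (z, n) == (3, 1)

    def test_path_has_no_clique(self):
        z, n = kn.clique_stats(graph_net([(0, 1), (1, 2), (2, 3)]))
        assert (z, n) == (2, 0)

    def test_k4_plus_pendant(self):
        edges = list(itertools.combinations(range(4), 2)) + [(3, 4)]
        z, n = kn.clique_stats(graph_net(edges))
        assert (z, n) == (4, 1)

    def test_empty_and_edgeless(self):
        assert kn.clique_stats(graph_net([], nodes=[])) == (0, 0)
        assert kn.clique_stats(graph_net([], nodes=["a", "b"])) == (1, 0)

    def test_budget_exhaustion_reports_unavailable(self):
        edges = list(itertools.combinations(range(8), 2))
        z, n = kn.clique_stats(graph_net(edges), budget=0)
        assert z == 8 and n is None

    def test_matches_brute_force_on_random_graphs(self):
        """Bron–Kerbosch pivoting agrees with all-subsets enumeration."""
        rng = np.random.default_rng(2024)
        for _ in range(60):
            n_nodes = int(rng.integers(1, 11))
            nodes = list(range(n_nodes))
            edges = {
                (a, b)
                for a, b in itertools.combinations(nodes, 2)
                if rng.random() < rng.uniform(0.1, 0.9)
            }
            net = graph_net(edges, nodes=nodes)
            assert kn.clique_stats(net) == brute_clique_stats(nodes, edges)


class TestThresholdSweep:
    def test_monotone_and_nested(self):
        rng = np.random.default_rng(5)
        pairs = [
            (f"i{a}", f"i{b}", float(rng.uniform(0, 10)))
            for a, b in itertools.combinations(range(12), 2)
            if rng.random() < 0.6
        ]
        el = edge_list(pairs, isolates=[f"i{j}" for j in range(12)])
        stats = kn.threshold_sweep(el, list(range(10)))
        for lo, hi in zip(stats, stats[1:]):
            assert hi.c <= lo.c and hi.D <= lo.D and hi.z <= lo.z

    def test_single_and_duplicate_t(self):
        el = edge_list([("a", "b", 5.0)])
        assert len(kn.threshold_sweep(el, [5.0])) == 1
        with pytest.warns(UserWarning, match="duplicate"):
            out = kn.threshold_sweep(el, [5.0, 5.0])
        assert len(out) == 1

    def test_stats_tsv_format(self, tmp_path):
        el = edge_list([("a", "b", 5.0), ("b", "c", 2.0)])
        stats = kn.threshold_sweep(el, [0, 3])
        path = tmp_path / "stats.tsv"
        stats_tsv(stats, str(path))
        lines = path.read_text().splitlines()
        assert lines[0] == "threshold\tc\tD\tz\tn"
        assert len(lines) == 3


TAX = {
    **{f"a{i}": "PhylumA" for i in range(12)},
    **{f"b{i}": "PhylumB" for i in range(12)},
    **{f"c{i}": "PhylumC" for i in range(3)},
}


class TestPNetwork:
    def test_cross_edge_counts(self):
        el = edge_list(
            [("a0", "b0", 5.0), ("a1", "b0", 5.0), ("a0", "a1", 5.0)],
            isolates=list(TAX),
        )
        inet = kn.build_inetwork(el, 0.0)
        pnet = kn.build_pnetwork(inet, TAX)
        assert pnet.graph["PhylumA"]["PhylumB"]["g"] == 2
        assert pnet.graph.nodes["PhylumA"]["internal_pairs"] == 1
        assert pnet.graph.nodes["PhylumA"]["N"] == 12
        assert not pnet.graph.has_edge("PhylumA", "PhylumC")

    def test_within_only_edges_give_no_p_edges(self):
        el = edge_list([("a0", "a1", 5.0), ("a1", "a2", 5.0)], isolates=list(TAX))
        pnet = kn.build_pnetwork(kn.build_inetwork(el, 0.0), TAX)
        assert pnet.graph.number_of_edges() == 0
        assert pnet.graph.nodes["PhylumA"]["internal_pairs"] == 2

    def test_hand_enumerated_three_phyla(self):
        pairs = (
            [(f"a{i}", f"b{i}", 5.0) for i in range(4)]
            + [(f"a{i}", f"c{i % 3}", 5.0) for i in range(6)]
        )
        el = edge_list(pairs, isolates=list(TAX))
        pnet = kn.build_pnetwork(kn.build_inetwork(el, 0.0), TAX)
        assert pnet.graph["PhylumA"]["PhylumB"]["g"] == 4
        assert pnet.graph["PhylumA"]["PhylumC"]["g"] == 6

    def test_edge_sum_matches_inetwork(self, three_clade):
        genomes, _, _, edges = three_clade
        tax = {g.isolate_id: g.taxonomy for g in genomes}
        inet = kn.build_inetwork(edges, 0.0)
        pnet = kn.build_pnetwork(inet, tax)
        total = sum(d["g"] for _, _, d in pnet.graph.edges(data=True)) + sum(
            d["internal_pairs"] for _, d in pnet.graph.nodes(data=True)
        )
        assert total == inet.y

    def test_missing_taxonomy_listed(self):
        el = edge_list([("a0", "zz", 5.0)])
        with pytest.raises(TaxonomyError, match="zz"):
            kn.build_pnetwork(kn.build_inetwork(el, 0.0), TAX)

    def test_proteobacteria_split_into_classes(self):
        tax = {
            "x": kn.Taxonomy("G", "G s", "Proteobacteria", "Gammaproteobacteria"),
            "y": kn.Taxonomy("G", "G s", "Proteobacteria", "Betaproteobacteria"),
            "z": kn.Taxonomy("F", "F s", "Firmicutes"),
        }
        el = edge_list([("x", "y", 5.0), ("x", "z", 5.0)])
        pnet = kn.build_pnetwork(kn.build_inetwork(el, 0.0), tax)
        assert set(pnet.graph.nodes) == {
            "Gammaproteobacteria", "Betaproteobacteria", "Firmicutes"
        }


class TestConnectedness:
    def test_ratio_and_threshold_rule(self):
        pairs = [(f"a{i}", f"b{j}", 5.0) for i in range(10) for j in range(5)]
        pairs += [("a0", "c0", 5.0)]  # PhylumC has only 3 isolates
        el = edge_list(pairs, isolates=list(TAX))
        inet = kn.build_inetwork(el, 0.0)
        mat = kn.connectedness(inet, TAX, min_genomes=10)
        assert list(mat.index) == ["PhylumA", "PhylumB"]  # C excluded (< 10)
        assert mat.loc["PhylumA", "PhylumB"] == pytest.approx(50 / 144)
        assert mat.loc["PhylumB", "PhylumA"] == mat.loc["PhylumA", "PhylumB"]

    def test_full_connection_gives_one(self):
        pairs = [(f"a{i}", f"b{j}", 5.0) for i in range(12) for j in range(12)]
        el = edge_list(pairs, isolates=list(TAX))
        mat = kn.connectedness(kn.build_inetwork(el, 0.0), TAX, min_genomes=10)
        assert mat.loc["PhylumA", "PhylumB"] == 1.0

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        pairs = [
            (f"a{i}", f"b{j}", 5.0)
            for i in range(12) for j in range(12) if rng.random() < 0.3
        ]
        el = edge_list(pairs, isolates=list(TAX))
        mat = kn.connectedness(kn.build_inetwork(el, 0.0), TAX, min_genomes=10)
        relabel = {iso: f"X_{iso}" for iso in TAX}
        el2 = edge_list(
            [(relabel[a], relabel[b], s) for a, b, s in pairs],
            isolates=[relabel[i] for i in TAX],
        )
        tax2 = {relabel[i]: ph for i, ph in TAX.items()}
        mat2 = kn.connectedness(kn.build_inetwork(el2, 0.0), tax2, min_genomes=10)
        assert np.allclose(mat.values, mat2.values)


class TestJsonExport:
    def test_triangle_roundtrip(self, tmp_path):
        el = edge_list([("a", "b", 5.0), ("b", "c", 6.0), ("a", "c", 7.0)])
        net = kn.build_inetwork(el, 0.0)
        path = str(tmp_path / "net.json")
        kn.export_json(net, path)
        nodes, links = kn.import_json(path)
        assert len(nodes) == 3 and len(links) == 3
        assert {(l["source"], l["target"]) for l in links} == {
            ("a", "b"), ("a", "c"), ("b", "c")
        }
        assert all(isinstance(l["S"], float) for l in links)

    def test_empty_network(self, tmp_path):
        el = edge_list([], isolates=["a", "b"])
        path = str(tmp_path / "empty.json")
        kn.export_json(kn.build_inetwork(el, 0.0), path)
        nodes, links = kn.import_json(path)
        assert len(nodes) == 2 and links == []

    def test_pnetwork_links_carry_g(self, tmp_path):
        el = edge_list([("a0", "b0", 5.0)], isolates=list(TAX))
        pnet = kn.build_pnetwork(kn.build_inetwork(el, 0.0), TAX)
        path = str(tmp_path / "p.json")
        kn.export_json(pnet, path)
        nodes, links = kn.import_json(path)
        assert links[0]["g"] == 1
        sizes = {n["id"]: n["size"] for n in nodes}
        assert sizes["PhylumA"] == 12
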