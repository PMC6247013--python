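"""Threshold-filtered similarity networks and their topology statistics.

Two graph depictions are built from an edge list:

* the I-network — nodes are genome isolates (singletons retained), an edge
  means the pair's similarity S meets the threshold t;
* the P-network — nodes are phyla (with Proteobacteria split into classes),
  an edge between two phyla is weighted by g, the number of cross-phylum
  isolate pairs connected in the I-network at the same t.

The reported statistics follow the usual network-characteristics
definitions: c (nonsingleton node count), D = y / (x(x−1)/2) (density),
z (size of the largest clique), n (number of maximal cliques on ≥3 nodes),
and, per phylum pair, the connectedness C_ab = g / (N_a · N_b) restricted to
phyla with at least ``min_genomes`` isolates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .af_distance import EdgeList
from .errors import TaxonomyError

#: Default cap on enumerated maximal cliques before n is reported unavailable.
DEFAULT_CLIQUE_BUDGET = 5_000_000


@dataclass
class INetwork:
    t: float
    graph: nx.Graph  # nodes: isolate ids; edge attr "S"

    @property
    def x(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def y(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class PNetwork:
    t: float
    graph: nx.Graph  # nodes: phyla, attrs N + internal_pairs; edge attr "g"


@dataclass
class NetworkStats:
    """One row of a threshold sweep: t, c, D, z, n (n None if unavailable)."""

    t: float
    x: int
    y: int
    c: int
    D: float
    z: int
    n: int | None

    @property
    def e(self) -> int:
        return self.x * (self.x - 1) // 2


def build_inetwork(edges: EdgeList, t: float, strict_threshold: bool = False) -> INetwork:
    """Keep edges with S ≥ t (S > t when ``strict_threshold``); all isolates
    remain as nodes, so singletons are preserved."""
    if t < 0:
        raise ValueError("threshold t must be >= 0")
    g = nx.Graph()
    g.add_nodes_from(edges.isolates)
    for r in edges.records:
        keep = r.S > t if strict_threshold else r.S >= t
        if keep:
            g.add_edge(r.isolate_a, r.isolate_b, S=r.S)
    return INetwork(t=t, graph=g)


def density(net: INetwork) -> float:
    """D = y / e with e = x(x−1)/2 possible edges; undefined for x < 2."""
    x = net.x
    if x < 2:
        raise ValueError(f"density undefined for a network with {x} node(s)")
    return net.y / (x * (x - 1) / 2)


def nonsingleton_count(net: INetwork) -> int:
    """c = number of nodes with one or more edges."""
    return sum(1 for _, deg in net.graph.degree() if deg >= 1)


def clique_stats(
    net: INetwork, budget: int = DEFAULT_CLIQUE_BUDGET
) -> tuple[int, int | None]:
    """(z, n): largest clique size, and number of maximal cliques on ≥3 nodes.

    Maximal cliques are enumerated with Bron–Kerbosch (pivoting, via
    networkx); if more than ``budget`` maximal cliques are produced the count
    n is reported as None ("not available"), mirroring how the count becomes
    impractical on very dense graphs.  z is computed by exact branch-and-bound
    search and is always available.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        return 0, 0
    clique, size = nx.max_weight_clique(g, weight=None)
    z = int(size)
    n = 0
    for i, members in enumerate(nx.find_cliques(g)):
        if i >= budget:
            return z, None
        if len(members) >= 3:
            n += 1
    return z, n


def network_stats(net: INetwork, budget: int = DEFAULT_CLIQUE_BUDGET) -> NetworkStats:
    z, n = clique_stats(net, budget=budget)
    return NetworkStats(
        t=net.t,
        x=net.x,
        y=net.y,
        c=nonsingleton_count(net),
        D=density(net) if net.x >= 2 else 0.0,
        z=z,
        n=n,
    )


def threshold_sweep(
    edges: EdgeList,
    t_values: Sequence[float],
    strict_threshold: bool = False,
    budget: int = DEFAULT_CLIQUE_BUDGET,
) -> list[NetworkStats]:
    """One NetworkStats row per threshold, ascending; duplicates dropped."""
    unique = sorted(set(t_values))
    if len(unique) != len(t_values):
        warnings.warn("duplicate threshold values were deduplicated")
    out = []
    for t in unique:
        net = build_inetwork(edges, t, strict_threshold=strict_threshold)
        out.append(network_stats(net, budget=budget))
    return out


def stats_tsv(stats: Sequence[NetworkStats], path: str) -> None:
    """Write the sweep as a TSV shaped like the network-characteristics
    tables: Threshold, c, D, z, n."""
    with open(path, "w") as fh:
        fh.write("threshold\tc\tD\tz\tn\n")
        for s in stats:
            n = "NA" if s.n is None else s.n
            fh.write(f"{s.t:g}\t{s.c}\t{s.D:.6g}\t{s.z}\t{n}\n")


def _phylum_of(
    isolates: Sequence[str], taxonomy: Mapping[str, object]
) -> dict[str, str]:
    missing = [i for i in isolates if i not in taxonomy]
    if missing:
        raise TaxonomyError(f"isolates without taxonomy: {missing}")
    out = {}
    for i in isolates:
        tax = taxonomy[i]
        out[i] = tax.effective_phylum if hasattr(tax, "effective_phylum") else str(tax)
    return out


def build_pnetwork(inet: INetwork, taxonomy: Mapping[str, object]) -> PNetwork:
    """Aggregate the I-network per phylum.

    Edge attribute g counts I-network edges with one endpoint in each
    phylum; within-phylum edge counts are kept as node metadata
    (``internal_pairs``) rather than self-loops.
    """
    phylum = _phylum_of(list(inet.graph.nodes), taxonomy)
    p = nx.Graph()
    for iso, ph in phylum.items():
        if ph not in p:
            p.add_node(ph, N=0, internal_pairs=0)
        p.nodes[ph]["N"] += 1
    for a, b in inet.graph.edges:
        pa, pb = phylum[a], phylum[b]
        if pa == pb:
            p.nodes[pa]["internal_pairs"] += 1
        else:
            if p.has_edge(pa, pb):
                p[pa][pb]["g"] += 1
            else:
                p.add_edge(pa, pb, g=1)
    return PNetwork(t=inet.t, graph=p)


def connectedness(
    inet: INetwork,
    taxonomy: Mapping[str, object],
    min_genomes: int = 10,
) -> pd.DataFrame:
    """Symmetric matrix of C_ab = g / (N_a · N_b) over qualifying phyla.

    g counts unordered cross-phylum isolate pairs joined by an edge at this
    t; phyla with fewer than ``min_genomes`` isolates are excluded to avoid
    sampling bias.  The diagonal is the within-phylum analogue
    g_aa / (N_a (N_a − 1) / 2).
    """
    phylum = _phylum_of(list(inet.graph.nodes), taxonomy)
    sizes: dict[str, int] = {}
    for ph in phylum.values():
        sizes[ph] = sizes.get(ph, 0) + 1
    qualifying = sorted(ph for ph, n in sizes.items() if n >= min_genomes)
    if len(qualifying) < 2:
        warnings.warn("fewer than two phyla meet the minimum genome count")
    g_counts: dict[tuple[str, str], int] = {}
    for a, b in inet.graph.edges:
        pa, pb = sorted((phylum[a], phylum[b]))
        g_counts[(pa, pb)] = g_counts.get((pa, pb), 0) + 1
    mat = pd.DataFrame(0.0, index=qualifying, columns=qualifying)
    for a in qualifying:
        for b in qualifying:
            g = g_counts.get(tuple(sorted((a, b))), 0)
            G = sizes[a] * sizes[b] if a != b else sizes[a] * (sizes[a] - 1) // 2
            mat.loc[a, b] = g / G if G > 0 else 0.0
    return mat


def export_json(
    net: INetwork | PNetwork,
    path: str,
    taxonomy: Mapping[str, object] | None = None,
) -> None:
    """Serialize a network as D3-force-layout JSON: {"nodes": [...],
    "links": [...]} with sorted keys."""
    if isinstance(net, INetwork):
        phylum = (
            _phylum_of(list(net.graph.nodes), taxonomy) if taxonomy is not None else {}
        )
        nodes = [
            {"id": v, "phylum": phylum.get(v, ""), "size": 1}
            for v in sorted(net.graph.nodes)
        ]
        links = [
            {"source": a, "target": b, "S": net.graph[a][b]["S"]}
            for a, b in sorted(net.graph.edges, key=lambda e: tuple(sorted(e)))
        ]
    else:
        nodes = [
            {"id": v, "phylum": v, "size": net.graph.nodes[v]["N"]}
            for v in sorted(net.graph.nodes)
        ]
        links = [
            {"source": a, "target": b, "g": net.graph[a][b]["g"]}
            for a, b in sorted(net.graph.edges, key=lambda e: tuple(sorted(e)))
        ]
    with open(path, "w") as fh:
        json.dump({"links": links, "nodes": nodes, "t": net.t}, fh, sort_keys=True, indent=1)


def import_json(path: str) -> tuple[list[dict], list[dict]]:
    """Read back an exported network JSON; returns (nodes, links)."""
    with open(path) as fh:
        obj = json.load(fh)
    return obj["nodes"], obj["links"]
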