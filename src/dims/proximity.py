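"""Network proximity measures on an interaction network.

Four quantities over two node sets A and B of an undirected, unweighted
interaction network:

separation (closest measure)
    s_ab = d_AB - (d_AA + d_BB) / 2, where d_AB averages, over every
    member of either set, the distance to the nearest member of the other
    set, and d_AA / d_BB average each member's distance to its nearest
    other member of the same set. s_ab < 0 means the two target
    neighbourhoods overlap/complement each other; s_ab >= 0 means they are
    topologically separated.

module shortest distance
    the mean of all pairwise distances d(a, b), a in A, b in B, i.e. the
    pair sum normalized by |A| x |B| (disconnected pairs are skipped and
    counted).

flow centrality
    FC_{A,B}(v) = (1 / |A||B|) * sum over pairs (a, b) of
    sigma_ab(v) / sigma_ab, the fraction of a-b shortest paths through v.
    Both the normalized value and the raw pair sum are reported.

gene total distance
    sum of distances from one gene to every member of A u B (a per-gene
    proximity score used for driver ranking).

All distances are breadth-first (unweighted); computations are restricted
to the largest connected component by default, and genes absent from the
network are dropped with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd


@dataclass
class SeparationResult:
    s_ab: float
    d_ab: float
    d_aa: float
    d_bb: float
    n_mapped_a: int
    n_mapped_b: int
    n_dropped: int


@dataclass
class ModuleDistanceResult:
    d_shortest: float
    pairs_used: int
    pairs_skipped: int


@dataclass
class FlowCentralityResult:
    table: pd.DataFrame  # index: candidate node; fc_raw, fc_norm, pairs_used
    n_pairs_total: int

    def fc_raw(self, node) -> float:
        return float(self.table.loc[node, "fc_raw"])

    def fc_norm(self, node) -> float:
        return float(self.table.loc[node, "fc_norm"])


class InteractionNetwork:
    """Simple undirected graph over gene ids, optionally restricted to its
    largest connected component (the default, so distances are defined)."""

    def __init__(self, graph: nx.Graph, largest_component: bool = True):
        g = nx.Graph(graph)  # collapses multi-edges
        g.remove_edges_from(nx.selfloop_edges(g))
        if largest_component and g.number_of_nodes() and not nx.is_connected(g):
            keep = max(nx.connected_components(g), key=len)
            dropped = g.number_of_nodes() - len(keep)
            warnings.warn(
                f"restricting to largest connected component "
                f"({dropped} nodes dropped)"
            )
            g = g.subgraph(keep).copy()
        self.graph = g

    @classmethod
    def from_edges(cls, edges, **kwargs) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_edges_from(edges)
        return cls(g, **kwargs)

    def __contains__(self, node) -> bool:
        return node in self.graph

    def map_genes(self, genes, label: str = "gene set") -> list:
        """Intersect a gene set with the network, warning about drop-outs."""
        genes = list(dict.fromkeys(genes))
        mapped = [g for g in genes if g in self.graph]
        missing = [g for g in genes if g not in self.graph]
        if missing:
            warnings.warn(
                f"{label}: {len(missing)} genes absent from the network: "
                f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
            )
        return mapped


def _as_network(net) -> InteractionNetwork:
    if isinstance(net, InteractionNetwork):
        return net
    return InteractionNetwork(net)


def _distances_from(graph: nx.Graph, sources) -> dict:
    return {s: nx.single_source_shortest_path_length(graph, s) for s in sources}


def _closest(dist_row: dict, targets, exclude=None) -> float | None:
    best = None
    for t in targets:
        if t == exclude:
            continue
        d = dist_row.get(t)
        if d is not None and (best is None or d < best):
            best = d
    return best


def separation(net, a_genes, b_genes) -> SeparationResult:
    """Closest-measure separation s_ab of two gene sets."""
    net = _as_network(net)
    a = net.map_genes(a_genes, "set A")
    b = net.map_genes(b_genes, "set B")
    n_dropped = (len(set(a_genes)) - len(a)) + (len(set(b_genes)) - len(b))
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            "each set must map to >= 2 network nodes "
            f"(got {len(a)} and {len(b)}); d_AA/d_BB would be undefined"
        )
    dist = _distances_from(net.graph, set(a) | set(b))

    cross = []
    for x in a:
        d = _closest(dist[x], b)
        if d is not None:
            cross.append(d)
    for y in b:
        d = _closest(dist[y], a)
        if d is not None:
            cross.append(d)
    if not cross:
        raise ValueError("sets A and B are not connected in the network")

    within_a = [d for x in a if (d := _closest(dist[x], a, exclude=x)) is not None]
    within_b = [d for y in b if (d := _closest(dist[y], b, exclude=y)) is not None]
    if not within_a or not within_b:
        raise ValueError("within-set distances undefined (disconnected set members)")

    d_ab = sum(cross) / len(cross)
    d_aa = sum(within_a) / len(within_a)
    d_bb = sum(within_b) / len(within_b)
    return SeparationResult(
        s_ab=d_ab - (d_aa + d_bb) / 2.0,
        d_ab=d_ab,
        d_aa=d_aa,
        d_bb=d_bb,
        n_mapped_a=len(a),
        n_mapped_b=len(b),
        n_dropped=n_dropped,
    )


def module_shortest_distance(net, a_genes, b_genes) -> ModuleDistanceResult:
    """Mean pairwise distance between two modules, normalized by |A| x |B|."""
    net = _as_network(net)
    a = net.map_genes(a_genes, "set A")
    b = net.map_genes(b_genes, "set B")
    if not a or not b:
        raise ValueError("both sets must map to the network")
    dist = _distances_from(net.graph, set(a))
    total, used, skipped = 0.0, 0, 0
    for x in a:
        row = dist[x]
        for y in b:
            d = row.get(y)
            if d is None:
                skipped += 1
            else:
                total += d
                used += 1
    if used == 0:
        raise ValueError("all A-B pairs are disconnected")
    return ModuleDistanceResult(
        d_shortest=total / used, pairs_used=used, pairs_skipped=skipped
    )


def _bfs_path_counts(graph: nx.Graph, source) -> tuple[dict, dict]:
    """BFS distances and shortest-path counts sigma from one source."""
    dist = {source: 0}
    sigma = {source: 1.0}
    queue = [source]
    while queue:
        nxt = []
        for u in queue:
            du = dist[u]
            su = sigma[u]
            for w in graph[u]:
                if w not in dist:
                    dist[w] = du + 1
                    sigma[w] = su
                    nxt.append(w)
                elif dist[w] == du + 1:
                    sigma[w] += su
        queue = nxt
    return dist, sigma


def flow_centrality(net, a_genes, b_genes, candidates=None) -> FlowCentralityResult:
    """Fraction of A-B shortest paths through each candidate node.

    For each candidate v, pairs (a, b) with v in {a, b}, a == b, or a
    disconnected from b are skipped; fc_norm divides fc_raw by the number
    of usable pairs for that candidate.
    """
    net = _as_network(net)
    a = net.map_genes(a_genes, "set A")
    b = net.map_genes(b_genes, "set B")
    if not a or not b:
        raise ValueError("both sets must map to the network")
    if candidates is None:
        cand = list(net.graph.nodes())
    else:
        cand = net.map_genes(candidates, "candidates")
    if not cand:
        raise ValueError("empty candidate set")

    sources = set(a) | set(b)
    bfs = {s: _bfs_path_counts(net.graph, s) for s in sources}
    pairs = []
    for x in a:
        dist_x, _ = bfs[x]
        for y in b:
            if x != y and y in dist_x:
                pairs.append((x, y, dist_x[y]))

    fc_raw = {v: 0.0 for v in cand}
    pairs_used = {v: 0 for v in cand}
    cand_set = set(cand)
    for x, y, dxy in pairs:
        dist_x, sig_x = bfs[x]
        dist_y, sig_y = bfs[y]
        sigma_ab = sig_x[y]
        for v in cand_set:
            if v == x or v == y:
                continue
            pairs_used[v] += 1
            dxv = dist_x.get(v)
            if dxv is None:
                continue
            dyv = dist_y.get(v)
            if dyv is None or dxv + dyv != dxy:
                continue
            fc_raw[v] += sig_x[v] * sig_y[v] / sigma_ab

    table = pd.DataFrame(
        {
            "fc_raw": [fc_raw[v] for v in cand],
            "pairs_used": [pairs_used[v] for v in cand],
        },
        index=pd.Index(cand, name="gene"),
    )
    table["fc_norm"] = table.fc_raw / table.pairs_used.where(table.pairs_used > 0, 1)
    return FlowCentralityResult(table=table, n_pairs_total=len(pairs))


def gene_total_distance(net, gene, a_genes, b_genes) -> tuple[float, int]:
    """Summed distance from ``gene`` to every reachable member of A u B
    (the gene itself excluded). Returns (total, n_reachable)."""
    net = _as_network(net)
    if gene not in net.graph:
        raise ValueError(f"{gene!r} not in the network")
    targets = (set(net.map_genes(a_genes, "set A"))
               | set(net.map_genes(b_genes, "set B"))) - {gene}
    dist = nx.single_source_shortest_path_length(net.graph, gene)
    reachable = [dist[t] for t in targets if t in dist]
    if not reachable:
        raise ValueError(f"{gene!r} cannot reach any member of A u B")
    return float(sum(reachable)), len(reachable)
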