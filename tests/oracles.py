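"""Independent brute-force oracles for the network proximity measures.

These deliberately use the most literal (slow) formulations — dictionary
all-pairs shortest paths and explicit enumeration of every shortest path —
so they share no code path with the package implementations they check.
"""

from __future__ import annotations

import numpy as np
import networkx as nx


def bf_separation(graph: nx.Graph, a, b):
    """Closest-measure separation by literal evaluation of the definition."""
    spl = dict(nx.all_pairs_shortest_path_length(graph))

    def closest(x, targets, exclude=None):
        ds = [spl[x][t] for t in targets if t != exclude and t in spl[x]]
        return min(ds) if ds else None

    cross = [closest(x, b) for x in a] + [closest(y, a) for y in b]
    cross = [d for d in cross if d is not None]
    waa = [d for x in a if (d := closest(x, a, exclude=x)) is not None]
    wbb = [d for y in b if (d := closest(y, b, exclude=y)) is not None]
    d_ab = sum(cross) / len(cross)
    d_aa = sum(waa) / len(waa)
    d_bb = sum(wbb) / len(wbb)
    return d_ab - (d_aa + d_bb) / 2.0, d_ab, d_aa, d_bb


def bf_module_distance(graph: nx.Graph, a, b):
    spl = dict(nx.all_pairs_shortest_path_length(graph))
    ds = [spl[x][y] for x in a for y in b if y in spl[x]]
    return sum(ds) / len(ds)


def bf_flow_centrality(graph: nx.Graph, a, b, v):
    """sigma_ab(v)/sigma_ab summed over usable pairs, by enumerating every
    shortest path; returns (raw sum, usable pair count)."""
    raw, used = 0.0, 0
    for x in a:
        for y in b:
            if x == y or v in (x, y):
                continue
            if not nx.has_path(graph, x, y):
                continue
            paths = list(nx.all_shortest_paths(graph, x, y))
            used += 1
            through = sum(1 for p in paths if v in p[1:-1])
            raw += through / len(paths)
    return raw, used


def bf_gene_total_distance(graph: nx.Graph, v, a, b):
    targets = (set(a) | set(b)) - {v}
    total, n = 0, 0
    for t in targets:
        if nx.has_path(graph, v, t):
            total += nx.shortest_path_length(graph, v, t)
            n += 1
    return float(total), n


def bf_tom(adjacency: np.ndarray) -> np.ndarray:
    """Literal element-wise evaluation of the topological overlap formula."""
    a = adjacency.copy().astype(float)
    n = a.shape[0]
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom
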