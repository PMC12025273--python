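"""Driver-gene ranking from network proximity indices.

Candidates are scored twice against the two target modules A and B: by
total shortest-path distance to the members of A u B (smaller = closer to
both programmes) and by flow centrality (larger = more of the A-B shortest
paths pass through the gene). The drivers are the union of the top-k lists
of the two rankings; genes in both lists are the "common" drivers. Ties are
broken by score and then lexicographic gene id, so the output is
deterministic and independent of input ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from dims.proximity import InteractionNetwork, _as_network, flow_centrality


@dataclass
class DriverRanking:
    table: pd.DataFrame
    top_k_distance: list[str]
    top_k_fc: list[str]
    drivers: set[str]
    common: set[str]
    k: int

    def as_frame(self) -> pd.DataFrame:
        return self.table


def rank_drivers(
    net,
    a_genes,
    b_genes,
    candidates=None,
    k: int = 10,
    fc_column: str = "fc_raw",
) -> DriverRanking:
    """Rank candidate genes by total shortest distance (ascending) and flow
    centrality (descending); select the top-k of each.

    ``candidates`` defaults to every network node — drivers such as bridge
    genes need not belong to A or B. ``fc_column`` picks which flow
    centrality ("fc_raw" or "fc_norm") drives the ranking; both are
    reported.
    """
    if fc_column not in ("fc_raw", "fc_norm"):
        raise ValueError("fc_column must be 'fc_raw' or 'fc_norm'")
    net = _as_network(net)
    a = net.map_genes(a_genes, "set A")
    b = net.map_genes(b_genes, "set B")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each target set must map to >= 2 network nodes")
    fc = flow_centrality(net, a, b, candidates=candidates)
    cand = list(fc.table.index)
    if k > len(cand):
        warnings.warn(f"k={k} exceeds {len(cand)} candidates; clamping")
        k = len(cand)

    # total distance to A u B via one BFS per target, accumulated per node
    targets = sorted(set(a) | set(b))
    total = {v: 0.0 for v in cand}
    n_reach = {v: 0 for v in cand}
    for t in targets:
        dist = nx.single_source_shortest_path_length(net.graph, t)
        for v in cand:
            if v == t:
                continue
            d = dist.get(v)
            if d is not None:
                total[v] += d
                n_reach[v] += 1

    table = fc.table.copy()
    table["shortest_distance"] = [
        total[v] if n_reach[v] else np.inf for v in cand
    ]
    table["n_reachable_targets"] = [n_reach[v] for v in cand]

    by_dist = sorted(cand, key=lambda v: (table.loc[v, "shortest_distance"], v))
    by_fc = sorted(cand, key=lambda v: (-table.loc[v, fc_column], v))
    top_dist = by_dist[:k]
    top_fc = by_fc[:k]
    drivers = set(top_dist) | set(top_fc)
    common = set(top_dist) & set(top_fc)

    table["rank_distance"] = [by_dist.index(v) + 1 for v in cand]
    table["rank_fc"] = [by_fc.index(v) + 1 for v in cand]
    table["in_top_distance"] = [v in set(top_dist) for v in cand]
    table["in_top_fc"] = [v in set(top_fc) for v in cand]
    table["driver"] = [v in drivers for v in cand]
    table["common"] = [v in common for v in cand]
    table = table[
        [
            "shortest_distance",
            "n_reachable_targets",
            "fc_raw",
            "fc_norm",
            "pairs_used",
            "rank_distance",
            "rank_fc",
            "in_top_distance",
            "in_top_fc",
            "driver",
            "common",
        ]
    ].sort_values(["rank_fc"])
    return DriverRanking(
        table=table,
        top_k_distance=top_dist,
        top_k_fc=top_fc,
        drivers=drivers,
        common=common,
        k=k,
    )
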