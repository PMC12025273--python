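"""Plain-text readers and writers for the formats the pipeline exchanges.

Expression matrices are TSV with gene ids in the first column and sample ids
in the header; interaction networks are two-column edge lists (TSV) or SIF;
gene sets are one-id-per-line text or GMT.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate gene ids in {path}")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a sample -> group TSV with columns (sample, group)."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_group_map(groups: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(groups), "group": list(groups.values())}
    ).to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read an undirected edge list: two-column TSV or SIF (a REL b)."""
    graph = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            if len(parts) >= 3:  # SIF: source relation target [target ...]
                src, targets = parts[0], parts[2:]
            elif len(parts) == 2:
                src, targets = parts[0], parts[1:]
            else:
                continue
            for tgt in targets:
                if src != tgt:
                    graph.add_edge(src, tgt)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(graph.edges()):
            fh.write(f"{u}\t{v}\n")


def read_gene_set(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_set(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT annotation file: term <tab> description <tab> gene..."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = {g for g in parts[2:] if g}
    return terms


def write_gmt(terms: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(terms):
            genes = "\t".join(sorted(terms[term]))
            fh.write(f"{term}\tna\t{genes}\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
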