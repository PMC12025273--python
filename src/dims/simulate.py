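"""Synthetic expression and interaction-network generator with known truth.

The generator emulates a four-arm drug-combination study (sham, two single
drugs, their combination) measured on a log2-scale expression platform, plus
a scale-free interaction network carrying planted target sets and bridge
nodes, so that every downstream stage — module detection, preservation
Zsummary, DEG screening, separation, driver ranking — can be validated
against planted ground truth.

Expression model
----------------
Each module m is a one-factor Gaussian block: for member gene j in group g,

    x_js = baseline_j + noise_sd * (r_mg * e_ms + sqrt(1 - r_mg^2) * eps_js)
           + delta_g(j)

with e_ms (the module's latent factor) and eps_js independent standard
normal draws. The implied within-module correlation is r_mg^2, so the
loading r controls co-expression strength analytically. A module named in
``disruption_map[g]`` has its loading replaced by ``r_disrupted`` (default
0) in that group only: membership labels stay meaningful, the co-expression
simply vanishes there. Unassigned genes are pure noise. Differential
expression is an additive log2 mean shift delta on the named genes.

Network model
-------------
A Barabasi-Albert (or configuration-model) scaffold with two planted target
sets wired as spokes of community hubs. In ``separated`` mode the sets live
in two different scale-free communities joined only through planted bridge
nodes, so every cross-set shortest path traverses a bridge and the
separation s_ab is positive by construction. In ``overlapping`` mode both
sets hang off one hub and share a stated fraction of nodes, which makes
s_ab = -2 * shared_fraction (negative by construction). Bridge nodes exist
only in separated mode.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from dims import io

GROUPS = ("sham", "drugA", "drugB", "combo")

# Default study design: modules 1 and 2 are intact only under drugA and
# drugB respectively (each drug induces its own co-expression programme),
# module 3 is intact only under the combination (the planted synergy
# module), modules 4 and 5 are housekeeping blocks intact everywhere.
DEFAULT_DISRUPTION = {
    "sham": frozenset({1, 2, 3}),
    "drugA": frozenset({2, 3}),
    "drugB": frozenset({1, 3}),
    "combo": frozenset({1, 2}),
}


def _default_deg_map(n_genes: int, module_sizes) -> dict[str, list[tuple[str, float]]]:
    """Plant log2(1.5) mean shifts on noise genes: ten per single drug, the
    union of both under the combination."""
    first_noise = sum(module_sizes)
    if first_noise + 20 > n_genes:
        return {}
    ids = [f"G{first_noise + i:04d}" for i in range(20)]
    delta = math.log2(1.5)
    return {
        "drugA": [(g, delta) for g in ids[:10]],
        "drugB": [(g, delta) for g in ids[10:]],
        "combo": [(g, delta) for g in ids],
    }


@dataclass(frozen=True)
class TargetSetSpec:
    """Sizes and placement mode of the two planted network target sets."""

    size_a: int = 30
    size_b: int = 30
    mode: str = "separated"  # or "overlapping"
    shared_fraction: float = 0.3  # overlapping mode only

    def __post_init__(self):
        if self.mode not in ("separated", "overlapping"):
            raise ValueError(f"unknown target-set mode: {self.mode!r}")
        if not 0.0 < self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in (0, 1]")


@dataclass
class SimulationConfig:
    """Full description of one synthetic study; a fixed seed reproduces the
    data byte for byte."""

    n_genes: int = 200
    n_samples_per_group: int = 20
    groups: tuple[str, ...] = GROUPS
    module_sizes: tuple[int, ...] = (30, 30, 30, 30, 30)
    module_corr: float | tuple[float, ...] = 0.9
    disruption_map: dict[str, frozenset[int]] = field(
        default_factory=lambda: dict(DEFAULT_DISRUPTION)
    )
    r_disrupted: float = 0.0
    deg_map: dict[str, list[tuple[str, float]]] | None = None
    noise_sd: float = 0.2
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    network_model: str = "barabasi_albert"
    network_n: int = 500
    network_param: int = 3
    target_set_spec: TargetSetSpec = field(default_factory=TargetSetSpec)
    n_bridges: int = 3
    seed: int = 0

    def __post_init__(self):
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum(module_sizes) exceeds n_genes")
        for r in self.loadings():
            if not 0.0 <= r <= 1.0:
                raise ValueError("module loadings must lie in [0, 1]")
        if not 0.0 <= self.r_disrupted <= 1.0:
            raise ValueError("r_disrupted must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for g in self.disruption_map:
            if g not in self.groups:
                raise ValueError(f"disruption_map names unknown group {g!r}")
        if self.deg_map is None:
            self.deg_map = _default_deg_map(self.n_genes, self.module_sizes)
        for g in self.deg_map:
            if g not in self.groups:
                raise ValueError(f"deg_map names unknown group {g!r}")
        if self.network_model not in ("barabasi_albert", "configuration"):
            raise ValueError(f"unknown network_model {self.network_model!r}")
        if self.network_n < 10:
            raise ValueError("network_n must be at least 10")

    def loadings(self) -> tuple[float, ...]:
        if isinstance(self.module_corr, (int, float)):
            return tuple(float(self.module_corr) for _ in self.module_sizes)
        if len(self.module_corr) != len(self.module_sizes):
            raise ValueError("module_corr length must match module_sizes")
        return tuple(float(r) for r in self.module_corr)

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """Planted structure, serialized alongside the data it describes."""

    module_of: dict[str, int] = field(default_factory=dict)
    disrupted: dict[str, list[int]] = field(default_factory=dict)
    degs: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    target_set_a: list[str] = field(default_factory=list)
    target_set_b: list[str] = field(default_factory=list)
    bridges: list[str] = field(default_factory=list)

    def module_genes(self, label: int) -> list[str]:
        return [g for g, m in self.module_of.items() if m == label]

    def to_json(self, path: str | Path) -> None:
        io.write_json(asdict(self), path)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        import json

        with open(path) as fh:
            raw = json.load(fh)
        raw["degs"] = {
            g: [(gene, float(d)) for gene, d in lst]
            for g, lst in raw.get("degs", {}).items()
        }
        return cls(**raw)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # one root seed, deterministic sub-streams per component
    return np.random.default_rng([int(config.seed), stream])


def simulate_expression(
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Draw one expression matrix per group plus the planted ground truth.

    Returns a dict group -> DataFrame (genes x samples, log2 scale).
    """
    genes = config.gene_ids()
    loadings = config.loadings()
    module_of: dict[str, int] = {g: 0 for g in genes}
    pos = 0
    for label, size in enumerate(config.module_sizes, start=1):
        for g in genes[pos : pos + size]:
            module_of[g] = label
        pos += size

    rng = _rng(config, 1)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    n = config.n_samples_per_group
    labels = np.array([module_of[g] for g in genes])

    matrices: dict[str, pd.DataFrame] = {}
    for gi, group in enumerate(config.groups):
        grng = _rng(config, 100 + gi)
        factors = grng.standard_normal((len(config.module_sizes) + 1, n))
        eps = grng.standard_normal((config.n_genes, n))
        disrupted = set(config.disruption_map.get(group, ()))
        r_gene = np.zeros(config.n_genes)
        for label, r in enumerate(loadings, start=1):
            r_eff = config.r_disrupted if label in disrupted else r
            r_gene[labels == label] = r_eff
        x = r_gene[:, None] * factors[labels] + np.sqrt(
            1.0 - r_gene[:, None] ** 2
        ) * eps
        x = baseline[:, None] + config.noise_sd * x
        for gene, delta in config.deg_map.get(group, ()):
            if gene not in module_of:
                raise ValueError(f"deg_map names unknown gene {gene!r}")
            x[genes.index(gene)] += delta
        cols = [f"{group}_s{j:02d}" for j in range(n)]
        matrices[group] = pd.DataFrame(x, index=genes, columns=cols)

    truth = GroundTruth(
        module_of=module_of,
        disrupted={g: sorted(s) for g, s in config.disruption_map.items()},
        degs={g: list(v) for g, v in config.deg_map.items()},
    )
    return matrices, truth


def _scaffold(config: SimulationConfig, n: int, seed: int) -> nx.Graph:
    if n < 3:
        raise ValueError("scaffold too small; increase network_n")
    m = max(1, min(int(config.network_param), n - 1))
    if config.network_model == "barabasi_albert":
        return nx.barabasi_albert_graph(n, m, seed=seed)
    # configuration model with a truncated power-law degree sequence
    rng = np.random.default_rng(seed)
    while True:
        deg = np.minimum(
            rng.zipf(2.3, size=n) + m - 1, n - 1
        )
        if deg.sum() % 2 == 0:
            break
    g = nx.configuration_model(deg.tolist(), seed=seed)
    g = nx.Graph(g)
    g.remove_edges_from(nx.selfloop_edges(g))
    if not nx.is_connected(g):
        comps = list(nx.connected_components(g))
        for a, b in zip(comps, comps[1:]):
            g.add_edge(next(iter(a)), next(iter(b)))
    return g


def _hub(graph: nx.Graph, exclude=()) -> int:
    return max(
        (v for v in graph if v not in exclude),
        key=lambda v: (graph.degree(v), -v if isinstance(v, int) else 0),
    )


def simulate_network(
    config: SimulationConfig,
    set_a: list[str] | None = None,
    set_b: list[str] | None = None,
    max_retries: int = 10,
) -> tuple[nx.Graph, GroundTruth]:
    """Build the interaction network with planted target sets A and B.

    Node ids are gene symbols; explicit ``set_a``/``set_b`` lists let the
    caller plant the genes of specific expression modules, otherwise ids
    ``A00..``/``B00..`` are used. Target-set members are attached as spokes
    of community hubs so the sign of the separation s_ab is fixed by
    construction (see module docstring).
    """
    spec = config.target_set_spec
    if set_a is None:
        set_a = [f"A{i:03d}" for i in range(spec.size_a)]
    if set_b is None:
        set_b = [f"B{i:03d}" for i in range(spec.size_b)]
    if spec.mode == "overlapping":
        n_shared = max(1, round(spec.shared_fraction * min(len(set_a), len(set_b))))
        # overlay the first n_shared ids of B onto A's tail
        set_b = set_a[len(set_a) - n_shared :] + [
            b for b in set_b if b not in set_a
        ][: len(set_b) - n_shared]

    for attempt in range(max_retries):
        seed = int(
            np.random.default_rng([int(config.seed), 200 + attempt]).integers(2**31)
        )
        graph = _plant(config, set_a, set_b, seed)
        if nx.is_connected(graph):
            break
    else:  # pragma: no cover - construction keeps the graph connected
        raise RuntimeError("could not build a connected network after retries")

    bridges = [v for v in graph if isinstance(v, str) and v.startswith("BRIDGE")]
    truth = GroundTruth(
        target_set_a=sorted(set_a),
        target_set_b=sorted(set_b),
        bridges=sorted(bridges),
    )
    return graph, truth


def _plant(config, set_a, set_b, seed) -> nx.Graph:
    spec = config.target_set_spec
    planted = set(set_a) | set(set_b)
    n_bridges = config.n_bridges if spec.mode == "separated" else 0
    n_filler = config.network_n - len(planted) - n_bridges
    if n_filler < 20:
        raise ValueError("network_n too small for the planted sets")

    graph = nx.Graph()
    if spec.mode == "separated":
        half = n_filler // 2
        ga = _scaffold(config, half, seed)
        gb = _scaffold(config, n_filler - half, seed + 1)
        graph.add_edges_from((f"N{u:04d}", f"N{v:04d}") for u, v in ga.edges())
        off = half
        graph.add_edges_from(
            (f"N{u + off:04d}", f"N{v + off:04d}") for u, v in gb.edges()
        )
        hub_a = f"N{_hub(ga):04d}"
        hub_b = f"N{_hub(gb) + off:04d}"
        for a in set_a:
            graph.add_edge(a, hub_a)
        for b in set_b:
            graph.add_edge(b, hub_b)
        for i in range(n_bridges):
            br = f"BRIDGE{i:02d}"
            graph.add_edge(br, hub_a)
            graph.add_edge(br, hub_b)
    else:
        gf = _scaffold(config, n_filler, seed)
        graph.add_edges_from((f"N{u:04d}", f"N{v:04d}") for u, v in gf.edges())
        hub = f"N{_hub(gf):04d}"
        for v in planted:
            graph.add_edge(v, hub)
    return graph


def make_annotation(
    truth: GroundTruth,
    config: SimulationConfig,
    n_random_terms: int = 20,
    term_size: int = 15,
) -> dict[str, set[str]]:
    """Synthetic gene-set annotation: one term per planted module plus
    random terms, for exercising the over-representation stage."""
    genes = config.gene_ids()
    rng = _rng(config, 300)
    terms: dict[str, set[str]] = {}
    for label in sorted(set(truth.module_of.values()) - {0}):
        terms[f"MODULE_TERM_{label}"] = set(truth.module_genes(label))
    for t in range(n_random_terms):
        size = int(rng.integers(max(5, term_size // 2), term_size * 2))
        terms[f"RANDOM_TERM_{t:02d}"] = set(
            rng.choice(genes, size=min(size, len(genes)), replace=False)
        )
    return terms


def simulate_study(
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], nx.Graph, GroundTruth]:
    """Expression + network with coherent gene ids.

    The planted network target sets default to the genes of the
    drugA-specific module (module 1) and the drugB-specific module
    (module 2), so the network-level A/B sets correspond to the expression
    On-modules the pipeline will discover.
    """
    matrices, truth = simulate_expression(config)
    spec = config.target_set_spec
    set_a = truth.module_genes(1)[: spec.size_a] or None
    set_b = truth.module_genes(2)[: spec.size_b] or None
    graph, net_truth = simulate_network(config, set_a=set_a, set_b=set_b)
    truth.target_set_a = net_truth.target_set_a
    truth.target_set_b = net_truth.target_set_b
    truth.bridges = net_truth.bridges
    return matrices, graph, truth


def write_study(
    config: SimulationConfig, outdir: str | Path
) -> tuple[dict[str, pd.DataFrame], nx.Graph, GroundTruth]:
    """Simulate and write every artifact (TSV/JSON) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrices, graph, truth = simulate_study(config)
    group_map = {}
    for group, df in matrices.items():
        io.write_expression(df, outdir / f"expression_{group}.tsv")
        group_map.update({s: group for s in df.columns})
    io.write_group_map(group_map, outdir / "groups.tsv")
    io.write_edge_list(graph, outdir / "network.tsv")
    truth.to_json(outdir / "ground_truth.json")
    io.write_gmt(make_annotation(truth, config), outdir / "annotation.gmt")
    return matrices, graph, truth
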