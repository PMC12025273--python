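"""End-to-end orchestration of a DiMS run.

Stages, in order: (1) simulate or load the four-group expression study and
the interaction network; (2) detect co-expression modules per treatment
group; (3) preservation Zsummary of each treatment's modules versus sham
and of the combination's modules versus each single drug, then the Sy
rule; (4) DEG screening per treatment versus sham with overlap summaries;
(5) closest-measure separation of the two single-drug On-module gene sets
on the network; (6) driver ranking by total shortest distance and flow
centrality; (7) over-representation of the Sy-module and driver genes.

Every artifact is written as plain TSV/JSON under the output directory and
recorded, with a sha256 checksum, in ``manifest.json``; re-running with the
same config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from dims import io
from dims.deg import differential_expression, filter_degs, overlap_analysis
from dims.drivers import rank_drivers
from dims.enrichment import overrepresentation
from dims.preservation import identify_sy_modules, module_preservation
from dims.proximity import InteractionNetwork, separation
from dims.simulate import SimulationConfig, make_annotation, simulate_study
from dims.wgcna import build_network, detect_modules, pick_soft_threshold


@dataclass
class RunConfig:
    """Everything one DiMS run needs; serialized verbatim into the output
    directory. Group roles are named explicitly, never inferred."""

    outdir: str = "dims_run"
    simulation: SimulationConfig | None = None
    input_dir: str | None = None  # expression_<group>.tsv, network.tsv, annotation.gmt
    sham_group: str = "sham"
    drug_a_group: str = "drugA"
    drug_b_group: str = "drugB"
    combo_group: str = "combo"
    betas: dict[str, int] | None = None  # group -> beta; default_beta if absent
    default_beta: int = 6  # the conventional unsigned-network power
    auto_beta: bool = False  # scale-free-fit selection per group
    min_module_size: int = 3
    n_perm: int = 100
    seed: int = 0
    fc_min: float = 1.2
    p_max: float = 0.05
    use_bonferroni: bool = False
    fc_column: str = "fc_raw"
    k_drivers: int = 10

    def __post_init__(self):
        if self.simulation is None and self.input_dir is None:
            self.simulation = SimulationConfig(seed=self.seed)
        if self.simulation is not None and self.input_dir is not None:
            raise ValueError("give either a simulation config or an input_dir")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            from dims.simulate import TargetSetSpec

            tss = sim.pop("target_set_spec", None)
            if tss is not None:
                sim["target_set_spec"] = TargetSetSpec(**tss)
            for key in ("module_sizes", "groups"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "disruption_map" in sim:
                sim["disruption_map"] = {
                    g: frozenset(v) for g, v in sim["disruption_map"].items()
                }
            cfg.simulation = SimulationConfig(**sim)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: RunConfig):
        self.outdir = outdir
        self.data = {
            "config": json.loads(json.dumps(asdict(config), default=_jsonable)),
            "stages": [],
        }

    def stage(self, name: str, outputs: list[Path], t0: float, **info):
        self.data["stages"].append(
            {
                "stage": name,
                "outputs": {
                    p.name: _sha256(p) for p in outputs
                },
                "wall_time_s": round(time.monotonic() - t0, 3),
                **info,
            }
        )

    def write(self):
        io.write_json(self.data, self.outdir / "manifest.json")


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):
        return obj.item()
    return str(obj)


def _load_inputs(config: RunConfig):
    d = Path(config.input_dir)
    groups = [
        config.sham_group,
        config.drug_a_group,
        config.drug_b_group,
        config.combo_group,
    ]
    matrices = {g: io.read_expression(d / f"expression_{g}.tsv") for g in groups}
    graph = io.read_edge_list(d / "network.tsv")
    gmt = d / "annotation.gmt"
    annotation = io.read_gmt(gmt) if gmt.exists() else None
    return matrices, graph, annotation


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest dict (also written to
    ``<outdir>/manifest.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config)
    sham = config.sham_group
    treatments = [config.drug_a_group, config.drug_b_group, config.combo_group]

    # stage 1: data
    t0 = time.monotonic()
    if config.simulation is not None:
        from dims.simulate import write_study

        matrices, graph, truth = write_study(config.simulation, outdir / "data")
        annotation = make_annotation(truth, config.simulation)
        data_files = sorted((outdir / "data").glob("*"))
    else:
        matrices, graph, annotation = _load_inputs(config)
        truth = None
        data_files = []
    manifest.stage("data", data_files, t0,
                   n_genes=len(next(iter(matrices.values()))),
                   groups=list(matrices))

    # stage 2: modules per treatment group
    t0 = time.monotonic()
    nets, assignments, outputs = {}, {}, []
    sft_rows = []
    for group in treatments:
        expr = matrices[group]
        beta = (config.betas or {}).get(group)
        if beta is None:
            if config.auto_beta:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sft = pick_soft_threshold(expr)
                beta = sft.chosen_beta
                sft_rows.append(sft.table.assign(group=group, chosen=sft.chosen_beta))
            else:
                beta = config.default_beta
        nets[group] = build_network(expr, beta)
        assignments[group] = detect_modules(
            nets[group], min_size=config.min_module_size, prefix=f"{group}-Mod"
        )
        path = outdir / f"modules_{group}.tsv"
        assignments[group].as_frame().to_csv(path, sep="\t", index=False)
        outputs.append(path)
    if sft_rows:
        path = outdir / "soft_thresholds.tsv"
        pd.concat(sft_rows).to_csv(path, sep="\t", index=False)
        outputs.append(path)
    manifest.stage(
        "modules", outputs, t0,
        n_modules={g: len(assignments[g].module_ids) for g in treatments},
    )

    # stage 3: preservation + Sy rule
    t0 = time.monotonic()
    comparisons = [
        (config.drug_a_group, sham),
        (config.drug_b_group, sham),
        (config.combo_group, sham),
        (config.combo_group, config.drug_a_group),
        (config.combo_group, config.drug_b_group),
    ]
    preservation = {}
    outputs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ref_group, test_group in comparisons:
            pres = module_preservation(
                matrices[ref_group],
                matrices[test_group],
                assignments[ref_group],
                n_perm=config.n_perm,
                seed=config.seed,
                beta=nets[ref_group].beta,
            )
            preservation[(ref_group, test_group)] = pres
            path = outdir / f"preservation_{ref_group}_vs_{test_group}.tsv"
            pres.table.to_csv(path, sep="\t")
            outputs.append(path)
    combo = config.combo_group
    sy = identify_sy_modules(
        preservation[(combo, sham)],
        preservation[(combo, config.drug_a_group)],
        preservation[(combo, config.drug_b_group)],
    )
    sy_path = outdir / "sy_modules.json"
    io.write_json(sy.as_dict(), sy_path)
    outputs.append(sy_path)
    manifest.stage("preservation", outputs, t0,
                   sy_modules=sorted(sy.sy_modules))

    # stage 4: DEGs
    t0 = time.monotonic()
    deg_sets, outputs = {}, []
    for group in treatments:
        table = differential_expression(
            matrices[sham],
            matrices[group],
            fc_min=config.fc_min,
            p_max=config.p_max,
            use_bonferroni=config.use_bonferroni,
        )
        path = outdir / f"degs_{group}.tsv"
        table.to_csv(path, sep="\t", index=False)
        outputs.append(path)
        deg_sets[group] = filter_degs(
            table, config.fc_min, config.p_max, config.use_bonferroni
        )
    overlap = overlap_analysis(deg_sets)
    path = outdir / "deg_overlap.tsv"
    overlap.to_csv(path, sep="\t", index=False)
    outputs.append(path)
    manifest.stage("degs", outputs, t0,
                   n_degs={g: len(s) for g, s in deg_sets.items()})

    # stage 5: separation of the single-drug On-module gene sets
    t0 = time.monotonic()
    net = InteractionNetwork(graph)
    set_a = _on_module_genes(assignments, preservation, config.drug_a_group, sham)
    set_b = _on_module_genes(assignments, preservation, config.drug_b_group, sham)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sep = separation(net, set_a, set_b)
    sep_path = outdir / "separation.tsv"
    pd.DataFrame([asdict(sep)]).to_csv(sep_path, sep="\t", index=False)
    manifest.stage("separation", [sep_path], t0, s_ab=sep.s_ab)

    # stage 6: drivers
    t0 = time.monotonic()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ranking = rank_drivers(
            net, set_a, set_b, k=config.k_drivers, fc_column=config.fc_column
        )
    drv_path = outdir / "drivers.tsv"
    ranking.table.to_csv(drv_path, sep="\t")
    summary_path = outdir / "drivers.json"
    io.write_json(
        {
            "k": ranking.k,
            "top_k_distance": ranking.top_k_distance,
            "top_k_fc": ranking.top_k_fc,
            "drivers": sorted(ranking.drivers),
            "common": sorted(ranking.common),
        },
        summary_path,
    )
    manifest.stage("drivers", [drv_path, summary_path], t0,
                   n_drivers=len(ranking.drivers), n_common=len(ranking.common))

    # stage 7: enrichment of Sy-module genes
    t0 = time.monotonic()
    outputs = []
    if annotation:
        background = set(next(iter(matrices.values())).index)
        sy_genes = set()
        for m in sy.sy_modules:
            sy_genes |= set(assignments[combo].module_genes(m))
        if sy_genes:
            enr = overrepresentation(sy_genes, annotation, background)
            path = outdir / "enrichment_sy_modules.tsv"
            enr.to_csv(path, sep="\t", index=False)
            outputs.append(path)
    manifest.stage("enrichment", outputs, t0)

    manifest.write()
    return manifest.data


def _on_module_genes(assignments, preservation, group, sham) -> list[str]:
    """Union of the genes of a treatment group's On modules (vs sham); if
    nothing is On, fall back to all module genes of the group."""
    pres = preservation[(group, sham)]
    on = pres.on_modules
    genes: list[str] = []
    source = on if on else set(assignments[group].module_ids)
    for m in sorted(source):
        genes.extend(assignments[group].module_genes(m))
    return genes
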