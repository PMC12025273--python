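"""Permutation-based module preservation (Zsummary) and the Sy-module rule.

A module detected in a *reference* dataset (a treatment group) is tested
for preservation in a *test* dataset (the comparator: sham or a single
drug). Seven statistics are computed, four describing module density in the
test data and three describing the agreement of connectivity patterns
between reference and test:

density side (test data only)
    meanCor       mean off-diagonal within-module correlation
    meanAdj       mean off-diagonal within-module adjacency |cor|^beta
    propVarExpl   fraction of within-module variance carried by the first
                  principal component (the module eigengene)
    meanKME       mean correlation of member genes with the eigengene
                  (eigengene sign fixed so the mean is non-negative in the
                  reference sense)

connectivity side (reference vs test agreement over member genes)
    cor_kIM       correlation of intramodular connectivity profiles
    cor_kME       correlation of eigengene-based connectivity (kME)
    cor_cor       correlation of the within-module correlation matrices'
                  off-diagonal entries

Each statistic is standardized against a permutation null built from random
gene sets of the module's size drawn from the full gene universe of the
test dataset (the same draws serve the connectivity side, which amounts to
permuting module labels):

    Z = (observed - null mean) / null sd

and the composite is

    Zsummary = ( median(Z_meanCor, Z_meanAdj, Z_propVarExpl, Z_meanKME)
               + median(Z_cor_kIM, Z_cor_kME, Z_cor_cor) ) / 2.

Classification: Zsummary < 0 -> "on" (drug-responsive, structure absent in
the comparator); Zsummary >= 2 -> "conserved"; otherwise "indeterminate".
The Sy rule then declares a combination-group module synergistic when it is
On versus sham AND On versus at least one single drug.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dims.wgcna import ModuleAssignment

DENSITY_STATS = ("meanCor", "meanAdj", "propVarExpl", "meanKME")
CONNECTIVITY_STATS = ("cor_kIM", "cor_kME", "cor_cor")
ALL_STATS = DENSITY_STATS + CONNECTIVITY_STATS


@dataclass
class PreservationResult:
    """Per-module component Zs, composite Zsummary and class labels."""

    table: pd.DataFrame  # index: module label; Z_* columns, zsummary, class
    n_permutations: int
    seed: int
    beta: int

    @property
    def on_modules(self) -> set[int]:
        return set(self.table.index[self.table["class"] == "on"])

    @property
    def conserved_modules(self) -> set[int]:
        return set(self.table.index[self.table["class"] == "conserved"])

    def zsummary(self, module: int) -> float:
        return float(self.table.loc[module, "zsummary"])


@dataclass
class SyModuleReport:
    on_vs_sham: set[int]
    on_vs_drug_a: set[int]
    on_vs_drug_b: set[int]
    sy_modules: set[int]
    provenance: dict[int, list[str]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "on_vs_sham": sorted(self.on_vs_sham),
            "on_vs_drugA": sorted(self.on_vs_drug_a),
            "on_vs_drugB": sorted(self.on_vs_drug_b),
            "sy_modules": sorted(self.sy_modules),
            "provenance": {str(k): v for k, v in sorted(self.provenance.items())},
        }


def classify(zsummary: float) -> str:
    """On/conserved thresholds; the >= 2 bound is inclusive."""
    if zsummary < 0:
        return "on"
    if zsummary >= 2:
        return "conserved"
    return "indeterminate"


def zsummary_composite(components: dict[str, float]) -> float:
    dens = np.median([components[s] for s in DENSITY_STATS])
    conn = np.median([components[s] for s in CONNECTIVITY_STATS])
    return float((dens + conn) / 2.0)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _eigengene_stats(cor_sub: np.ndarray) -> tuple[float, np.ndarray]:
    """(propVarExpl, kME vector) from a within-module correlation matrix.

    For row-standardized data the first-PC correlation of gene g with the
    eigengene is sqrt(lambda_1) * v1_g; the sign of v1 is fixed so that the
    mean kME is non-negative.
    """
    m = cor_sub.shape[0]
    vals, vecs = np.linalg.eigh(cor_sub)
    lam = max(vals[-1], 0.0)
    v1 = vecs[:, -1]
    kme = np.clip(np.sqrt(lam) * v1, -1.0, 1.0)
    if kme.mean() < 0:
        kme = -kme
    return float(lam / m), kme


def _offdiag(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _module_stats(
    idx: np.ndarray,
    ref_cor: np.ndarray,
    test_cor: np.ndarray,
    beta: int,
) -> dict[str, float]:
    rc = ref_cor[np.ix_(idx, idx)]
    tc = test_cor[np.ix_(idx, idx)]
    t_adj = np.abs(tc) ** beta
    r_adj = np.abs(rc) ** beta
    prop_var, kme_test = _eigengene_stats(tc)
    _, kme_ref = _eigengene_stats(rc)
    m = idx.size
    k_test = t_adj.sum(axis=1) - 1.0  # exclude the unit diagonal
    k_ref = r_adj.sum(axis=1) - 1.0
    return {
        "meanCor": float(_offdiag(tc).mean()),
        "meanAdj": float(_offdiag(t_adj).mean()),
        "propVarExpl": prop_var,
        "meanKME": float(kme_test.mean()),
        "cor_kIM": _pearson(k_ref, k_test),
        "cor_kME": _pearson(kme_ref, kme_test),
        "cor_cor": _pearson(_offdiag(rc), _offdiag(tc)),
    }


def module_preservation(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    modules: ModuleAssignment,
    n_perm: int = 200,
    seed: int = 0,
    beta: int = 6,
    min_module_size: int = 3,
) -> PreservationResult:
    """Zsummary preservation of reference-defined modules in a test dataset.

    ``ref_expr`` must be the dataset the modules were detected in; the
    direction matters and is not symmetric. Both matrices must cover the
    same gene universe.
    """
    if set(ref_expr.index) != set(test_expr.index):
        raise ValueError("reference and test datasets must share the gene universe")
    if n_perm < 50:
        raise ValueError("n_perm must be >= 50 for stable null estimates")
    test_expr = test_expr.loc[ref_expr.index]
    gene_pos = {g: i for i, g in enumerate(ref_expr.index)}

    ref_sd = ref_expr.std(axis=1).to_numpy()
    test_sd = test_expr.std(axis=1).to_numpy()
    usable = (ref_sd > 0) & (test_sd > 0)

    ref_cor = np.clip(np.corrcoef(_standardize_rows(ref_expr.to_numpy(float))), -1, 1)
    test_cor = np.clip(np.corrcoef(_standardize_rows(test_expr.to_numpy(float))), -1, 1)

    rng = np.random.default_rng([int(seed), 77])
    universe = np.where(usable)[0]
    rows = []
    for label in modules.module_ids:
        idx = np.array(
            [gene_pos[g] for g in modules.module_genes(label) if usable[gene_pos[g]]]
        )
        dropped = len(modules.module_genes(label)) - idx.size
        if dropped:
            warnings.warn(
                f"module {label}: dropped {dropped} zero-variance genes"
            )
        if idx.size < min_module_size:
            warnings.warn(f"module {label}: fewer than {min_module_size} usable genes; skipped")
            continue
        observed = _module_stats(idx, ref_cor, test_cor, beta)
        null = {s: np.empty(n_perm) for s in ALL_STATS}
        for p in range(n_perm):
            ridx = rng.choice(universe, size=idx.size, replace=False)
            stats = _module_stats(ridx, ref_cor, test_cor, beta)
            for s in ALL_STATS:
                null[s][p] = stats[s]
        comps: dict[str, float] = {}
        for s in ALL_STATS:
            sd = null[s].std(ddof=1)
            if sd == 0:
                warnings.warn(f"module {label}: zero null sd for {s}; Z set to 0")
                comps[s] = 0.0
            else:
                comps[s] = (observed[s] - null[s].mean()) / sd
        row = {"module": label, "size": idx.size}
        row.update({f"Z_{s}": comps[s] for s in ALL_STATS})
        row["zsummary"] = zsummary_composite(comps)
        row["class"] = classify(row["zsummary"])
        rows.append(row)

    table = pd.DataFrame(rows)
    if len(table):
        table = table.set_index("module")
    else:
        table = pd.DataFrame(
            columns=["size", *(f"Z_{s}" for s in ALL_STATS), "zsummary", "class"]
        )
        table.index.name = "module"
    return PreservationResult(
        table=table, n_permutations=n_perm, seed=int(seed), beta=int(beta)
    )


def classify_modules(pres: PreservationResult) -> dict[int, str]:
    """Re-derive the per-module class labels from the stored Zsummary."""
    return {int(m): classify(z) for m, z in pres.table["zsummary"].items()}


def sy_from_on_sets(
    on_vs_sham: set[int],
    on_vs_drug_a: set[int],
    on_vs_drug_b: set[int],
) -> SyModuleReport:
    """Sy rule on already-classified On sets of the combination group.

    A combination module is synergistic when its co-expression structure is
    absent from the sham data AND absent from at least one single-drug
    dataset: sy = (On(vs A) | On(vs B)) & On(vs sham).
    """
    on_vs_sham = set(on_vs_sham)
    on_vs_drug_a = set(on_vs_drug_a)
    on_vs_drug_b = set(on_vs_drug_b)
    sy = (on_vs_drug_a | on_vs_drug_b) & on_vs_sham
    provenance = {}
    for m in sorted(on_vs_sham | on_vs_drug_a | on_vs_drug_b):
        tags = []
        if m in on_vs_sham:
            tags.append("on_vs_sham")
        if m in on_vs_drug_a:
            tags.append("on_vs_drugA")
        if m in on_vs_drug_b:
            tags.append("on_vs_drugB")
        provenance[m] = tags
    return SyModuleReport(
        on_vs_sham=on_vs_sham,
        on_vs_drug_a=on_vs_drug_a,
        on_vs_drug_b=on_vs_drug_b,
        sy_modules=sy,
        provenance=provenance,
    )


def identify_sy_modules(
    combo_vs_sham: PreservationResult,
    combo_vs_drug_a: PreservationResult,
    combo_vs_drug_b: PreservationResult,
) -> SyModuleReport:
    """Apply the Sy rule to three preservation runs of the combination
    group's modules (vs sham, vs drug A, vs drug B)."""
    universes = [set(r.table.index) for r in (combo_vs_sham, combo_vs_drug_a, combo_vs_drug_b)]
    if not universes[0] == universes[1] == universes[2]:
        raise ValueError("preservation results cover different module sets")
    return sy_from_on_sets(
        combo_vs_sham.on_modules,
        combo_vs_drug_a.on_modules,
        combo_vs_drug_b.on_modules,
    )
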