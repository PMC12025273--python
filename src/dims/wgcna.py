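"""Weighted co-expression network construction and module detection.

The construction follows the standard unsigned WGCNA recipe: soft-threshold
the absolute Pearson correlation, a_ij = |cor(x_i, x_j)|^beta, choose beta
by the scale-free topology fit, turn adjacency into the topological overlap
matrix (TOM), cluster genes by average-linkage hierarchical clustering on
the dissimilarity 1 - TOM, and cut the dendrogram into modules with a
minimum size; genes in no module get label 0 (the "grey" module).

The dendrogram cut is an adaptive height cut with a branch-quality gate:
branches obtained from a static cut near the top of the tree are kept as
modules only when their mean internal TOM dissimilarity sits clearly below
the cut height. This rejects the loose, noise-dominated branches that a
plain static cut would return as giant modules, which is the practical role
the dynamic hybrid tree cut plays in WGCNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

# cosmetic aliases for module labels, in WGCNA's conventional order
_COLORS = (
    "grey", "turquoise", "blue", "brown", "yellow", "green", "red",
    "black", "pink", "magenta", "purple", "greenyellow", "tan", "salmon",
    "cyan", "midnightblue", "lightcyan", "grey60", "lightgreen",
    "lightyellow", "royalblue",
)


@dataclass
class SoftThresholdResult:
    """Scale-free fit table over candidate powers and the chosen beta."""

    table: pd.DataFrame  # columns: beta, sft_r2, slope, mean_k
    chosen_beta: int
    target_r2: float
    criterion_met: bool


@dataclass
class CoexpressionNetwork:
    genes: list[str]
    adjacency: np.ndarray
    tom: np.ndarray
    beta: int


@dataclass
class ModuleAssignment:
    """Gene -> module partition; label 0 means unassigned (grey)."""

    genes: list[str]
    labels: np.ndarray  # int, aligned with genes
    prefix: str = "Mod"

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.genes) != len(self.labels):
            raise ValueError("genes and labels length mismatch")

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels.tolist()) - {0})

    def module_genes(self, label: int) -> list[str]:
        return [g for g, l in zip(self.genes, self.labels) if l == label]

    def module_name(self, label: int) -> str:
        return f"{self.prefix}-{label}"

    def color(self, label: int) -> str:
        return _COLORS[label % len(_COLORS)] if label else "grey"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "module_label": self.labels,
                "module": [self.module_name(l) if l else "grey" for l in self.labels],
                "color": [self.color(l) for l in self.labels],
            }
        )

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.genes, self.labels.tolist()))


def _correlation(expr: pd.DataFrame) -> np.ndarray:
    x = expr.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("expression matrix contains missing values")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = [g for g, s in zip(expr.index, sd) if s == 0]
        raise ValueError(f"zero-variance genes present: {bad[:5]} ...")
    return np.clip(np.corrcoef(x), -1.0, 1.0)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit index for a connectivity vector.

    Bins k into equal-width bins, regresses log10 frequency on log10 mean
    connectivity per bin, and returns (R^2, slope). The fit index is
    reported as 0 when the slope is non-negative (no decay, hence no
    scale-free behaviour).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    mean_k, freq = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            mean_k.append(k[mask].mean())
            freq.append(mask.mean())
    if len(mean_k) < 3:
        return 0.0, 0.0
    lx, ly = np.log10(mean_k), np.log10(freq)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 0.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
    if slope >= 0:
        return 0.0, float(slope)
    return float(np.clip(r2, 0.0, 1.0)), float(slope)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers=tuple(range(1, 21)),
    target_r2: float = 0.8,
) -> SoftThresholdResult:
    """Choose the soft-threshold power beta by the scale-free fit criterion.

    The smallest power whose fit index reaches ``target_r2`` is chosen; if
    none qualifies, the best-fitting power is returned with a warning. A
    known beta (e.g. one published for the dataset) can always be passed to
    :func:`build_network` directly, bypassing selection.
    """
    if expr.shape[1] < 4:
        raise ValueError("need at least 4 samples to pick a soft threshold")
    powers = sorted(int(b) for b in powers)
    if len(powers) < 2:
        raise ValueError("need at least 2 candidate powers")
    sd = expr.std(axis=1)
    if (sd == 0).any():
        warnings.warn(
            f"excluding {(sd == 0).sum()} zero-variance genes from soft-threshold fit"
        )
        expr = expr.loc[sd > 0]
    if expr.shape[0] < 2:
        raise ValueError("fewer than 2 usable genes")
    cor = np.abs(_correlation(expr))
    np.fill_diagonal(cor, 0.0)
    rows = []
    for beta in powers:
        k = (cor**beta).sum(axis=1)
        r2, slope = scale_free_fit(k)
        rows.append(
            {"beta": beta, "sft_r2": r2, "slope": slope, "mean_k": float(k.mean())}
        )
    table = pd.DataFrame(rows)
    ok = table[table.sft_r2 >= target_r2]
    if len(ok):
        chosen = int(ok.beta.iloc[0])
        met = True
    else:
        chosen = int(table.loc[table.sft_r2.idxmax(), "beta"])
        met = False
        warnings.warn(
            f"no power reached scale-free fit {target_r2}; "
            f"using beta={chosen} (best fit {table.sft_r2.max():.2f})"
        )
    return SoftThresholdResult(table=table, chosen_beta=chosen, target_r2=target_r2,
                               criterion_met=met)


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (L_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij)."""
    a = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    min_k = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / (min_k + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def build_network(expr: pd.DataFrame, beta: int) -> CoexpressionNetwork:
    """Unsigned adjacency |cor|^beta and its TOM for a complete expression
    matrix (zero-variance genes must be filtered by the caller)."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    cor = _correlation(expr)
    adj = np.abs(cor) ** float(beta)
    np.fill_diagonal(adj, 1.0)
    tom = tom_similarity(adj)
    return CoexpressionNetwork(
        genes=list(expr.index), adjacency=adj, tom=tom, beta=int(beta)
    )


def _harvest_branches(z: np.ndarray, n: int, dissim: np.ndarray,
                      min_size: int, min_gap: float,
                      max_core_scatter: float) -> list[np.ndarray]:
    """Top-down branch harvest on a linkage matrix.

    Walking from the root, a subtree becomes a module when it (a) holds at
    least ``min_size`` leaves, (b) is separated from its sibling by a
    height gap of at least ``min_gap`` (parent merge height minus the
    subtree's own top merge height), and (c) is tight: its mean internal
    dissimilarity stays below ``max_core_scatter``. Otherwise its children
    are examined. Tight co-expression branches finish merging far below
    the loose, noise-dominated band at the top of the dendrogram; the gap
    rejects incidental agglomerations and the scatter bound rejects loose
    noise branches, while genes chained onto a module near the top are
    shed before the branch is accepted.
    """
    # cluster id c: leaf if c < n, else internal node z[c - n]
    sizes = {c: 1 for c in range(n)}
    heights = {c: 0.0 for c in range(n)}
    for i in range(z.shape[0]):
        c = n + i
        sizes[c] = int(z[i, 3])
        heights[c] = float(z[i, 2])

    leaf_cache: dict[int, np.ndarray] = {}

    def leaves(c: int) -> np.ndarray:
        cached = leaf_cache.get(c)
        if cached is not None:
            return cached
        out, stack = [], [c]
        while stack:
            u = stack.pop()
            if u < n:
                out.append(u)
            else:
                stack.extend(int(x) for x in z[u - n, :2])
        arr = np.array(sorted(out))
        leaf_cache[c] = arr
        return arr

    def scatter(c: int) -> float:
        idx = leaves(c)
        if idx.size < 2:
            return 0.0
        sub = dissim[np.ix_(idx, idx)]
        return float(sub[np.triu_indices(idx.size, k=1)].mean())

    modules: list[np.ndarray] = []
    root = n + z.shape[0] - 1
    stack = [(root, heights[root])]  # (cluster, parent merge height)
    while stack:
        c, parent_h = stack.pop()
        if sizes[c] < min_size:
            continue
        if parent_h - heights[c] >= min_gap and scatter(c) <= max_core_scatter:
            modules.append(leaves(c))
            continue
        if c >= n:
            left, right = (int(x) for x in z[c - n, :2])
            stack.append((left, heights[c]))
            stack.append((right, heights[c]))
    return modules


def detect_modules(
    net: CoexpressionNetwork,
    min_size: int = 3,
    min_branch_gap: float = 0.02,
    max_core_scatter: float = 0.92,
    prune_rel: float = 0.25,
    prefix: str = "Mod",
) -> ModuleAssignment:
    """Average-linkage hierarchical clustering on 1 - TOM with a top-down
    branch harvest.

    Subtrees of the dendrogram become modules when they are separated from
    their sibling branch by at least ``min_branch_gap`` (as a fraction of
    the tree height), their mean internal dissimilarity stays below
    ``max_core_scatter`` (as a fraction of the tree height), and they hold
    at least ``min_size`` genes; everything else is labelled 0 (grey).
    ``min_branch_gap`` plays the role of a split sensitivity: smaller
    values admit more, finer modules. Labels are renumbered by decreasing
    module size.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    n = len(net.genes)
    if n < min_size:
        warnings.warn("fewer genes than min_size; all genes unassigned")
        return ModuleAssignment(net.genes, np.zeros(n, dtype=int), prefix)
    dissim = 1.0 - net.tom
    dissim = (dissim + dissim.T) / 2.0
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    z = linkage(condensed, method="average")
    max_h = max(float(z[:, 2].max()), 1e-12)
    branches = _harvest_branches(
        z, n, dissim, min_size, min_branch_gap * max_h, max_core_scatter * max_h
    )
    branches = [
        b
        for b in (_prune_members(m, net.adjacency, prune_rel) for m in branches)
        if b.size >= min_size
    ]
    branches.sort(key=lambda m: (-m.size, m[0]))
    labels = np.zeros(n, dtype=int)
    for new_label, members in enumerate(branches, start=1):
        labels[members] = new_label
    return ModuleAssignment(net.genes, labels, prefix)


def _prune_members(members: np.ndarray, adjacency: np.ndarray,
                   rel_threshold: float) -> np.ndarray:
    """Drop weakly attached members of a harvested branch.

    A gene whose mean adjacency to the other members falls below
    ``rel_threshold`` times the module's median member attachment is
    returned to the grey pool — this sheds noise genes that chained onto
    the branch near the top of the dendrogram.
    """
    if members.size < 3 or rel_threshold <= 0:
        return members
    sub = adjacency[np.ix_(members, members)].copy()
    np.fill_diagonal(sub, 0.0)
    attach = sub.mean(axis=1)
    cutoff = rel_threshold * np.median(attach)
    return members[attach >= cutoff]


def detect_modules_from_expression(
    expr: pd.DataFrame,
    beta: int | None = None,
    min_size: int = 3,
    prefix: str = "Mod",
    **cut_kwargs,
) -> tuple[ModuleAssignment, CoexpressionNetwork, SoftThresholdResult | None]:
    """Convenience: soft threshold (unless beta given), network, modules."""
    sft = None
    if beta is None:
        sft = pick_soft_threshold(expr)
        beta = sft.chosen_beta
    net = build_network(expr, beta)
    modules = detect_modules(net, min_size=min_size, prefix=prefix, **cut_kwargs)
    return modules, net, sft
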