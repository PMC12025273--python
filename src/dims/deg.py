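"""Differential expression screening (treatment vs sham) and overlaps.

Per-gene Welch two-sample t-tests on log2 expression; fold change is
2^|mean difference|, with the direction kept separately. The screening
thresholds follow the study design: fold change > 1.2 and p < 0.05, with a
Bonferroni-corrected column always reported so the stricter screen is one
flag away.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats


def differential_expression(
    ref: pd.DataFrame,
    test: pd.DataFrame,
    fc_min: float = 1.2,
    p_max: float = 0.05,
    use_bonferroni: bool = False,
    moderate_var: bool = False,
    shrink_weight: float = 0.2,
) -> pd.DataFrame:
    """Welch t-test per gene of ``test`` (treatment) vs ``ref`` (sham).

    Returns one row per gene: mean_ref, mean_test, log2fc, direction,
    fold_change (= 2^|log2fc| >= 1), p_raw, p_bonferroni and the boolean
    ``passes`` gate at the given thresholds.

    ``moderate_var`` shrinks each gene's variance toward the mean variance
    across genes (weight ``shrink_weight``) before the t-statistic is
    formed — a lightweight stand-in for empirical-Bayes moderation.
    """
    if set(ref.index) != set(test.index):
        raise ValueError("ref and test must share the gene universe")
    if ref.shape[1] < 2 or test.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    test = test.loc[ref.index]
    x = ref.to_numpy(float)
    y = test.to_numpy(float)
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1, v2 = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    if moderate_var:
        v1 = (1 - shrink_weight) * v1 + shrink_weight * v1.mean()
        v2 = (1 - shrink_weight) * v2 + shrink_weight * v2.mean()
    se2 = v1 / n1 + v2 / n2
    diff = m2 - m1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = np.where(
        se2 > 0,
        2.0 * stats.t.sf(np.abs(t), np.where(np.isfinite(df), df, 1.0)),
        np.where(diff == 0, 1.0, 0.0),
    )
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    n_tested = len(ref)
    p_bonf = np.minimum(1.0, p * n_tested)
    log2fc = diff
    out = pd.DataFrame(
        {
            "gene": ref.index,
            "mean_ref": m1,
            "mean_test": m2,
            "log2fc": log2fc,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "fold_change": 2.0 ** np.abs(log2fc),
            "p_raw": p,
            "p_bonferroni": p_bonf,
        }
    ).reset_index(drop=True)
    p_col = out.p_bonferroni if use_bonferroni else out.p_raw
    out["passes"] = (out.fold_change > fc_min) & (p_col < p_max)
    return out


def filter_degs(
    records: pd.DataFrame,
    fc_min: float = 1.2,
    p_max: float = 0.05,
    use_bonferroni: bool = False,
) -> set[str]:
    """Gene set passing both gates: fold_change > fc_min and p < p_max."""
    p = records.p_bonferroni if use_bonferroni else records.p_raw
    mask = (records.fold_change > fc_min) & (p < p_max)
    return set(records.gene[mask])


def overlap_analysis(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Pairwise and all-way intersection summaries for named gene sets.

    Percentages are reported against two denominators (the union of the
    pair and the union of all sets), since overlap conventions differ.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    total_union = set().union(*sets.values())
    rows = []
    for a, b in itertools.combinations(sorted(sets), 2):
        inter = sets[a] & sets[b]
        union = sets[a] | sets[b]
        rows.append(
            {
                "set_a": a,
                "set_b": b,
                "n_a": len(sets[a]),
                "n_b": len(sets[b]),
                "n_intersection": len(inter),
                "n_union": len(union),
                "pct_of_pair_union": 100.0 * len(inter) / len(union) if union else 0.0,
                "pct_of_total_union": 100.0 * len(inter) / len(total_union)
                if total_union
                else 0.0,
            }
        )
    allway = set.intersection(*map(set, sets.values()))
    rows.append(
        {
            "set_a": "ALL",
            "set_b": "+".join(sorted(sets)),
            "n_a": len(total_union),
            "n_b": len(sets),
            "n_intersection": len(allway),
            "n_union": len(total_union),
            "pct_of_pair_union": 100.0 * len(allway) / len(total_union)
            if total_union
            else 0.0,
            "pct_of_total_union": 100.0 * len(allway) / len(total_union)
            if total_union
            else 0.0,
        }
    )
    return pd.DataFrame(rows)
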