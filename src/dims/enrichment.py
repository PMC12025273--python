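"""Local over-representation analysis of gene sets against annotations.

A one-sided Fisher exact (hypergeometric) test per term: given a query of n
genes from a background of N, and a term covering K background genes of
which k are in the query, the p-value is the probability of drawing >= k
term genes in n draws without replacement. Multiple testing is corrected
by Bonferroni or Benjamini-Hochberg. This is a plain over-representation
test, not a replication of any web service's modified statistic.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def overrepresentation(
    query: set[str],
    annotation: dict[str, set[str]],
    background: set[str],
    alpha: float = 0.05,
    method: str = "bh",
) -> pd.DataFrame:
    """Fisher/hypergeometric over-representation of ``query`` in each term.

    Terms are intersected with the background; the query must be a subset
    of the background. Rows (one per term, k = 0 rows retained) are sorted
    by raw p-value.
    """
    if method not in ("bonferroni", "bh"):
        raise ValueError("method must be 'bonferroni' or 'bh'")
    background = set(background)
    query = set(query) & background
    if not query:
        raise ValueError("query is empty after intersecting with the background")
    n = len(query)
    n_bg = len(background)
    rows = []
    for term, genes in annotation.items():
        term_genes = set(genes) & background
        big_k = len(term_genes)
        if big_k == 0:
            continue
        k = len(query & term_genes)
        p = float(hypergeom.sf(k - 1, n_bg, big_k, n))
        rows.append(
            {
                "term": term,
                "k_overlap": k,
                "term_size": big_k,
                "query_size": n,
                "background_size": n_bg,
                "p_fisher": min(p, 1.0),
            }
        )
    if not rows:
        raise ValueError("no annotation term overlaps the background")
    df = pd.DataFrame(rows)
    sm_method = "fdr_bh" if method == "bh" else "bonferroni"
    df["p_adjusted"] = multipletests(df.p_fisher, method=sm_method)[1]
    df["method"] = method
    df["significant"] = df.p_adjusted < alpha
    return df.sort_values("p_fisher", kind="stable").reset_index(drop=True)
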