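"""Hypergeometric overrepresentation of annotation terms in gene lists.

For a list of n genes drawn from a universe of N genes, of which K carry
a term, the overrepresentation p-value of observing k or more annotated
genes in the list is the upper hypergeometric tail P(X >= k) — the
one-sided Fisher exact test.  Raw p-values carry the significance-star
convention of the source tables ('***' p < 0.001, '**' p < 0.01);
Benjamini-Hochberg q-values over all tested terms are reported
alongside.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .util import DataError

__all__ = ["hypergeom_tail", "stars", "enrich"]


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise DataError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def stars(p: float) -> str:
    """Significance stars: '***' p < 0.001, '**' p < 0.01, else ''."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return ""


def enrich(
    gene_list: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Overrepresentation of every annotation term touching the list.

    ``annotation`` maps term id to its gene set; genes outside the
    universe are ignored.  Returns one row per term with at least one
    hit, sorted by p-value: term_id, k, n, K, N, p_value, q_value,
    stars.
    """
    uni = set(universe)
    if not uni:
        raise DataError("empty gene universe")
    lst = set(gene_list) & uni
    if not set(gene_list) <= uni:
        raise DataError("gene list contains genes outside the universe")
    rows = []
    for term, genes in annotation.items():
        term_genes = set(genes) & uni
        k = len(lst & term_genes)
        if k == 0:
            continue
        rows.append(
            {
                "term_id": term,
                "k": k,
                "n": len(lst),
                "K": len(term_genes),
                "N": len(uni),
                "p_value": hypergeom_tail(k, len(term_genes), len(lst), len(uni)),
            }
        )
    out = pd.DataFrame(
        rows, columns=["term_id", "k", "n", "K", "N", "p_value"]
    )
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["stars"] = out["p_value"].map(stars)
        out = out.sort_values(
            ["p_value", "term_id"], kind="stable"
        ).reset_index(drop=True)
    else:
        out["q_value"] = []
        out["stars"] = []
    return out
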