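"""Hypergeometric over-representation of a gene list against pathway gene sets.

For a universe of N genes containing K members of a pathway, and a list of n
selected genes of which k fall in the pathway, the enrichment p-value is the
hypergeometric upper tail

    p = sum_{x=k}^{min(K, n)} C(K, x) C(N-K, n-x) / C(N, n),

identical to a one-sided Fisher exact test on the 2×2 table. The universe is
taken to be the genes actually measured on the array (the expression
dataset), not the union of the gene-set file — the testable population is
what was measured. No multiple-testing correction is applied across
pathways; a set is flagged significant when p < alpha (default 0.05, strict).
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom

from .io import GeneSetCollection

__all__ = ["hypergeom_upper_tail", "enrich"]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n); computed in log-space by scipy."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K <= N and 0 <= n <= N")
    if not 0 <= k <= min(K, n):
        raise ValueError("need 0 <= k <= min(K, n)")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    dcg_list: set[str] | list[str],
    gene_sets: GeneSetCollection,
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test each gene set for over-representation of ``dcg_list``.

    Sets are intersected with the universe (empty intersections dropped), and
    the selected list is intersected with the universe too. Rows come back
    sorted by ascending p, ties broken by set name, with columns
    ``set_name, count, size, p, significant``.
    """
    selected = set(dcg_list) & universe
    if not selected:
        raise ValueError("no selected genes fall inside the universe")
    N = len(universe)
    n = len(selected)
    rows = []
    for name, genes in gene_sets.sets.items():
        in_universe = genes & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(in_universe & selected)
        p = hypergeom_upper_tail(k, K, n, N)
        rows.append((name, k, K, p))
    table = pd.DataFrame(rows, columns=["set_name", "count", "size", "p"])
    table["significant"] = table["p"] < alpha
    table = table.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)
    return table
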