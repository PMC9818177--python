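"""Hypergeometric over-representation test with Bonferroni control.

For a universe of N annotated genes, a query of n genes, a term of M genes
and an observed overlap of m genes, the enrichment p-value is the
upper-tail probability

    P = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n)
      = P(X >= m),  X ~ Hypergeometric(N, M, n),

evaluated through the survival function of the hypergeometric law (log-space
internally, so large universes are safe).  Family-wise error is controlled
by Bonferroni over the number of terms actually tested; Benjamini-Hochberg
is available as an alternative.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

BONFERRONI = "bonferroni"
BH = "bh"


def hypergeom_upper_p(N: int, n: int, M: int, m: int) -> float:
    """Upper-tail hypergeometric probability P(X >= m).

    ``N``: universe size, ``n``: query size, ``M``: term size, ``m``:
    query-term overlap.  ``m = 0`` gives 1.0 (empty sum).
    """
    N, n, M, m = int(N), int(n), int(M), int(m)
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= M, n <= N (got N={N}, M={M}, n={n})")
    if not 0 <= m <= min(n, M):
        raise ValueError(f"require 0 <= m <= min(n, M) (got m={m}, n={n}, M={M})")
    if m == 0:
        return 1.0
    return float(stats.hypergeom.sf(m - 1, N, M, n))


def enrich(
    query: Iterable[str],
    universe: Iterable[str],
    sets: GeneSetCollection,
    threshold: float = 0.05,
    top_k: int | None = 10,
    correction: str = BONFERRONI,
) -> pd.DataFrame:
    """Screen every term of a collection for over-representation in a query.

    Query genes outside the universe are dropped (with a logged count).
    Terms are restricted to the universe; terms with no universe member are
    not tested.  One record per tested term with columns ``term_id``,
    ``term_name``, ``N``, ``n``, ``M``, ``m``, ``p_value``,
    ``p_adjusted``, ``significant``; the returned table keeps only
    significant terms (adjusted p <= threshold), sorted by ascending
    p-value (ties broken by term_id) and truncated to ``top_k``.
    """
    if correction not in (BONFERRONI, BH):
        raise ValueError(f"unknown correction {correction!r}")
    universe_set = frozenset(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query_set = frozenset(query)
    dropped = query_set - universe_set
    if dropped:
        logger.info("dropped %d query gene(s) outside the universe", len(dropped))
    query_set &= universe_set
    if not query_set:
        logger.warning("query empty after universe filtering")

    N = len(universe_set)
    n = len(query_set)
    rows = []
    for term_id, genes in sets.terms.items():
        term_in_universe = genes & universe_set
        M = len(term_in_universe)
        if M == 0:
            continue
        m = len(query_set & term_in_universe)
        rows.append(
            {
                "term_id": term_id,
                "term_name": sets.names.get(term_id, term_id),
                "N": N,
                "n": n,
                "M": M,
                "m": m,
                "p_value": hypergeom_upper_p(N, n, M, m),
            }
        )
    table = pd.DataFrame(
        rows, columns=["term_id", "term_name", "N", "n", "M", "m", "p_value"]
    )
    if len(table):
        if correction == BONFERRONI:
            table["p_adjusted"] = np.minimum(1.0, table["p_value"] * len(table))
        else:
            table["p_adjusted"] = stats.false_discovery_control(table["p_value"], method="bh")
        table["significant"] = table["p_adjusted"] <= threshold
        table = table[table["significant"]]
        table = table.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
        if top_k is not None:
            table = table.head(top_k)
    else:
        table["p_adjusted"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table
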