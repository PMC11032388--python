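"""Hypergeometric over-representation analysis against GMT collections."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from triomix.diffexp import bh_adjust
from triomix.io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "term_id",
    "term_name",
    "k_overlap",
    "n_query",
    "K_set",
    "N_background",
    "p",
    "padj",
]


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), in log-space.

    N is the background size, K the gene-set size, n the query size and
    k the observed overlap.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent hypergeometric arguments k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    upper = min(n, K)
    if k > upper:
        return 0.0
    support = np.arange(k, upper + 1)
    logp = stats.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def enrich(
    query: list[str],
    collection: GeneSetCollection,
    background: list[str],
    min_set_size: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each gene set of ``collection``.

    Gene sets are intersected with the background universe before
    testing; sets smaller than ``min_set_size`` after intersection are
    skipped.  Query genes outside the background are dropped with a
    warning.  BH adjustment is applied over all tested terms.
    """
    universe = set(background)
    if not universe:
        raise ValueError("background universe is empty")
    query_set = set(query)
    outside = query_set - universe
    if outside:
        logger.warning("%d query gene(s) outside the background; dropped", len(outside))
        query_set &= universe
    N, n = len(universe), len(query_set)

    rows = []
    for term_id, (term_name, members) in collection.items():
        members_in_bg = set(members) & universe
        K = len(members_in_bg)
        if K < min_set_size:
            continue
        k = len(members_in_bg & query_set)
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "k_overlap": k,
                "n_query": n,
                "K_set": K,
                "N_background": N,
                "p": hypergeom_upper_tail(k, n, K, N),
            }
        )
    result = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    if len(result):
        result["padj"] = bh_adjust(result["p"].to_numpy())
    else:
        result["padj"] = pd.Series(dtype=float)
    return result.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
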