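"""Hypergeometric over-representation analysis against GMT gene sets.

The universe is always explicit: the workflow uses two different universes
(all genes tested for differential expression for DEG lists; the network
gene space for DETG lists), so no default would be safe.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .differential import bh_fdr

logger = logging.getLogger(__name__)

__all__ = ["hypergeom_upper_tail", "ora"]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Summed in log space over the support for numerical stability.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    hi = min(K, n)
    if k <= max(0, n + K - N):
        return 1.0
    support = np.arange(k, hi + 1)
    logp = hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def ora(
    gene_list,
    gene_sets: dict[str, set[str]],
    universe,
    alpha: float = 0.05,
    min_term_size: int = 3,
    max_term_size: int = 2000,
) -> pd.DataFrame:
    """One hypergeometric upper-tail test per term, BH-corrected.

    Genes outside the universe are dropped with a warning; term gene sets are
    intersected with the universe before counting; terms smaller than
    ``min_term_size`` or larger than ``max_term_size`` in the universe are
    not tested.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("ora: empty universe")
    genes = set(gene_list)
    outside = genes - universe
    if outside:
        logger.warning("ora: %d genes outside the universe dropped", len(outside))
        genes &= universe
    N, n = len(universe), len(genes)
    rows = []
    for term in sorted(gene_sets):
        term_genes = gene_sets[term] & universe
        K = len(term_genes)
        if not min_term_size <= K <= max_term_size:
            continue
        hits = sorted(term_genes & genes)
        k = len(hits)
        rows.append(
            {
                "term": term,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_upper_tail(k, K, n, N),
                "hits": ",".join(hits),
            }
        )
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p", "hits"])
    if len(df):
        df["p_adj"] = bh_fdr(df["p"].tolist())
        df["significant"] = df["p_adj"] < alpha
    else:
        df["p_adj"] = []
        df["significant"] = []
    return df
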