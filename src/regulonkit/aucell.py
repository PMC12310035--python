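"""AUCell-style per-cell regulon activity scores.

Each cell's transcriptome is ranked by normalized expression (rank 1 =
highest; ties, including the zero bulk, broken by a per-cell seeded shuffle).
A regulon's activity in a cell is the area under the recovery curve of its
targets within the top fraction *f* of the ranking:

    T = ceil(f * G),   h(k) = |{g in R : rank(g) <= k}|
    AUC = sum_{k=1..T} h(k)  /  sum_{k=1..T} min(k, |R|)

so the score is exactly 1 when the regulon's genes fill the top |R| ranks.
Ranking operates on the normalized (not scaled) matrix: gene-level scaling
would destroy the within-cell expression order.  Tie-break randomness is
seeded per cell id, so subsetting cells never changes retained cells' ranks.
"""

from __future__ import annotations

import logging
import math

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import derive_seed
from .consensus import ConsensusRegulon

logger = logging.getLogger(__name__)

__all__ = [
    "rank_genes_per_cell",
    "recovery_auc",
    "score_matrix",
    "standardize_auc",
]


def rank_genes_per_cell(expr: ad.AnnData, seed: int = 0) -> pd.DataFrame:
    """Rank genes within each cell by expression, rank 1 = highest.

    Returns a cells x genes integer DataFrame of ranks in 1..G.  Ties are
    broken by a uniform shuffle drawn once per cell from a seed derived from
    the cell id, deterministic given ``seed``.
    """
    if expr.n_vars < 1:
        raise ValueError("rank_genes_per_cell requires >= 1 gene")
    X = expr.X.toarray() if sp.issparse(expr.X) else np.asarray(expr.X, dtype=float)
    n_cells, n_genes = X.shape
    ranks = np.empty((n_cells, n_genes), dtype=np.int64)
    for i, cell in enumerate(expr.obs_names):
        rng = np.random.default_rng(derive_seed(seed, f"rank:{cell}"))
        keys = rng.random(n_genes)
        order = np.lexsort((keys, -X[i]))  # descending expression, random ties
        ranks[i, order] = np.arange(1, n_genes + 1)
    return pd.DataFrame(ranks, index=expr.obs_names, columns=expr.var_names)


def _auc_denominator(T: int, r: int) -> int:
    # sum_{k=1..T} min(k, r)
    if T <= r:
        return T * (T + 1) // 2
    return r * (r + 1) // 2 + (T - r) * r


def recovery_auc(ranking: pd.Series | dict, regulon_targets, top_fraction: float) -> float:
    """Recovery-curve AUC of one regulon in one cell.

    ``ranking`` maps every gene to its rank (1 = highest expression).
    Regulon genes absent from the ranked gene space are dropped before
    computing; an empty intersection is an error.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    if isinstance(ranking, dict):
        ranking = pd.Series(ranking)
    G = len(ranking)
    present = [g for g in regulon_targets if g in ranking.index]
    if not present:
        raise ValueError(f"regulon has no genes in the ranked gene space: {list(regulon_targets)[:5]}")
    T = math.ceil(top_fraction * G)
    r = len(present)
    ranks = ranking.loc[present].to_numpy()
    contrib = np.clip(T - ranks + 1, 0, None)
    return float(contrib.sum() / _auc_denominator(T, r))


def score_matrix(
    expr: ad.AnnData,
    consensus: list[ConsensusRegulon],
    top_fraction: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """AUC matrix: cells in rows, regulons (named by TF) in columns.

    Regulons whose targets all fall outside the matrix gene space are
    dropped with a warning.  A higher score means more of the regulon's
    targets are near the top of the cell's expression ranking.
    """
    ranks = rank_genes_per_cell(expr, seed).to_numpy()
    loc = {g: i for i, g in enumerate(expr.var_names)}
    G = expr.n_vars
    T = math.ceil(top_fraction * G)
    cols: dict[str, np.ndarray] = {}
    for reg in consensus:
        idx = [loc[t] for t in reg.targets if t in loc]
        if not idx:
            logger.warning("regulon %s lost all targets to the gene space; dropped", reg.tf)
            continue
        sub = ranks[:, idx]
        contrib = np.clip(T - sub + 1, 0, None).sum(axis=1)
        cols[reg.tf] = contrib / _auc_denominator(T, len(idx))
    auc = pd.DataFrame(cols, index=expr.obs_names)
    auc.attrs["top_fraction"] = top_fraction
    auc.attrs["seed"] = seed
    return auc


def standardize_auc(auc: pd.DataFrame) -> pd.DataFrame:
    """Column z-scores (population SD); constant columns map to 0 and are
    flagged in ``.attrs['constant_columns']``."""
    if len(auc) < 2:
        raise ValueError("standardize_auc requires >= 2 cells")
    mean = auc.mean(axis=0)
    sd = auc.std(axis=0, ddof=0)
    constant = sd == 0
    safe = sd.mask(constant, 1.0)
    z = (auc - mean) / safe
    z.loc[:, constant] = 0.0
    z.attrs["constant_columns"] = list(auc.columns[constant])
    return z
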