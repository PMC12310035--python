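"""Quality control, normalization, HVG selection and scaling.

The filtering funnel has a fixed, order-sensitive composition:

    qc_filter_cells -> remove_unannotated_genes -> remove_contaminants
    -> filter_cells_genes -> normalize -> select_hvgs / union_hvgs -> scale

Boundary semantics are literal and documented per operation: the first-stage
QC removes cells with <= ``min_features_exclusive`` detected features, a
mitochondrial fraction >= ``max_mito_fraction`` or >= ``max_umi_exclusive``
total UMIs; the second-stage filter keeps cells detecting strictly more than
``min_genes`` and strictly fewer than ``max_genes`` genes, and genes
expressed in at least ``min_cells_per_gene`` cells (inclusive).
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = [
    "qc_filter_cells",
    "filter_cells_genes",
    "remove_unannotated_genes",
    "remove_contaminants",
    "normalize",
    "select_hvgs",
    "union_hvgs",
    "scale",
    "run_funnel",
]


def _detected(adata: ad.AnnData, axis: int) -> np.ndarray:
    X = adata.X
    if sp.issparse(X):
        return np.asarray((X > 0).sum(axis=axis)).ravel()
    return (np.asarray(X) > 0).sum(axis=axis)


def _totals(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    if sp.issparse(X):
        return np.asarray(X.sum(axis=1)).ravel()
    return np.asarray(X).sum(axis=1)


def mito_fraction(adata: ad.AnnData, mito_prefix: str = "mt-") -> np.ndarray:
    """Per-cell mitochondrial fraction from ``obs['mito_frac']`` if present,
    else computed from genes whose symbol starts with ``mito_prefix``."""
    if "mito_frac" in adata.obs:
        return adata.obs["mito_frac"].to_numpy(dtype=float)
    mito_mask = adata.var_names.str.startswith(mito_prefix)
    totals = _totals(adata)
    if not mito_mask.any():
        return np.zeros(adata.n_obs)
    X = adata.X[:, np.where(mito_mask)[0]]
    mito = np.asarray(X.sum(axis=1)).ravel() if sp.issparse(X) else np.asarray(X).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    return frac


def qc_filter_cells(
    counts: ad.AnnData,
    min_features_exclusive: int = 200,
    max_mito_fraction: float = 0.10,
    max_umi_exclusive: int = 30_000,
    mito_prefix: str = "mt-",
) -> ad.AnnData:
    """First-stage cell QC: low-complexity, high-mito and doublet-like cells.

    Keeps exactly the cells with detected features > ``min_features_exclusive``
    AND mito fraction < ``max_mito_fraction`` AND total UMIs <
    ``max_umi_exclusive``.  Per-criterion removal counts are logged and stored
    in ``.uns['qc_report']``.
    """
    feats = _detected(counts, axis=1)
    mito = mito_fraction(counts, mito_prefix)
    umis = _totals(counts)
    low_feat = feats <= min_features_exclusive
    high_mito = mito >= max_mito_fraction
    doublet = umis >= max_umi_exclusive
    keep = ~(low_feat | high_mito | doublet)
    report = {
        "removed_low_features": int(low_feat.sum()),
        "removed_high_mito": int(high_mito.sum()),
        "removed_doublet_umi": int(doublet.sum()),
        "kept": int(keep.sum()),
    }
    if not keep.any():
        raise ValueError(f"qc_filter_cells removed every cell: {report}")
    logger.info("qc_filter_cells: %s", report)
    out = counts[keep].copy()
    out.uns["qc_report"] = report
    return out


def filter_cells_genes(
    counts: ad.AnnData,
    min_genes: int = 300,
    max_genes: int = 5000,
    min_cells_per_gene: int = 5,
) -> ad.AnnData:
    """Second-stage filter: gene-count bounds on cells (both exclusive), then
    minimum-prevalence filter on genes (inclusive), in that order."""
    detected = _detected(counts, axis=1)
    keep_cells = (detected > min_genes) & (detected < max_genes)
    if not keep_cells.any():
        raise ValueError("filter_cells_genes removed every cell")
    out = counts[keep_cells].copy()
    prevalence = _detected(out, axis=0)
    keep_genes = prevalence >= min_cells_per_gene
    if not keep_genes.any():
        raise ValueError("filter_cells_genes removed every gene")
    logger.info(
        "filter_cells_genes: removed %d cells, %d genes",
        int((~keep_cells).sum()),
        int((~keep_genes).sum()),
    )
    return out[:, keep_genes].copy()


def remove_unannotated_genes(
    matrix: ad.AnnData,
    suffixes: list[str] = ("Rik",),
    prefixes: list[str] = ("Gm",),
) -> ad.AnnData:
    """Drop genes whose symbol ends with any suffix or starts with any prefix.

    Matching is literal and case-sensitive, so e.g. prefix ``Gm`` also removes
    legitimate symbols like ``Gmds``; the rule is documented as such.
    """
    names = matrix.var_names
    drop = np.zeros(matrix.n_vars, dtype=bool)
    for s in suffixes:
        drop |= names.str.endswith(s)
    for p in prefixes:
        drop |= names.str.startswith(p)
    if drop.any():
        logger.info("remove_unannotated_genes: removed %d genes", int(drop.sum()))
    return matrix[:, ~drop].copy()


def remove_contaminants(matrix: ad.AnnData, marker_genes: list[str]) -> ad.AnnData:
    """Remove every cell with count > 0 in ANY listed exclusion marker."""
    present = [m for m in marker_genes if m in matrix.var_names]
    missing = [m for m in marker_genes if m not in matrix.var_names]
    if missing:
        logger.warning("remove_contaminants: markers absent, skipped: %s", missing)
    if not present:
        return matrix.copy()
    idx = [matrix.var_names.get_loc(m) for m in present]
    X = matrix.X[:, idx]
    expressed = (
        np.asarray((X > 0).sum(axis=1)).ravel() if sp.issparse(X) else (np.asarray(X) > 0).sum(axis=1)
    )
    keep = expressed == 0
    logger.info("remove_contaminants: removed %d cells", int((~keep).sum()))
    return matrix[keep].copy()


def normalize(counts: ad.AnnData, target_sum: float = 10_000.0) -> ad.AnnData:
    """Depth-normalize to ``target_sum`` counts per cell, then ln(1 + x)."""
    totals = _totals(counts)
    zero = np.where(totals == 0)[0]
    if zero.size:
        names = list(counts.obs_names[zero[:5]])
        raise ValueError(f"normalize: all-zero cells: {names}")
    X = sp.csc_matrix(counts.X, dtype=np.float64)
    scale_f = target_sum / totals
    X = sp.diags(scale_f) @ X
    X.data = np.log1p(X.data)
    out = ad.AnnData(X=sp.csc_matrix(X), obs=counts.obs.copy(), var=counts.var.copy())
    out.uns["target_sum"] = float(target_sum)
    return out


def select_hvgs(
    norm: ad.AnnData,
    min_mean: float = 0.0125,
    max_mean: float = 3.5,
    min_dispersion: float = 0.45,
    n_bins: int = 20,
) -> list[str]:
    """Mean/dispersion highly-variable-gene selection.

    Per gene, mean and dispersion (variance/mean) are computed on expm1 of
    the normalized values; dispersions are z-normalized within equal-frequency
    mean bins; a gene is selected iff ``min_mean < log1p(mean) < max_mean``
    and its normalized dispersion is >= ``min_dispersion``.
    """
    if norm.n_obs < 2:
        raise ValueError("select_hvgs requires >= 2 cells")
    X = sp.csc_matrix(norm.X, copy=True)
    X.data = np.expm1(X.data)
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = X.copy()
    sq.data **= 2
    var = np.asarray(sq.mean(axis=0)).ravel() - mean**2
    var *= norm.n_obs / max(norm.n_obs - 1, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, np.nan)
    df = pd.DataFrame({"mean": mean, "disp": disp}, index=norm.var_names)
    n_distinct = df["mean"].nunique()
    bins = min(n_bins, n_distinct)
    if bins < n_bins:
        logger.warning("select_hvgs: only %d distinct means; using %d bins", n_distinct, bins)
    # value-based bins so genes with identical means always share a bin
    df["bin"] = pd.qcut(df["mean"], q=bins, labels=False, duplicates="drop")
    grp = df.groupby("bin")["disp"]
    bin_mean = grp.transform("mean")
    bin_std = grp.transform("std").replace(0.0, np.nan)
    df["disp_norm"] = ((df["disp"] - bin_mean) / bin_std).fillna(0.0)
    log_mean = np.log1p(df["mean"])
    sel = (log_mean > min_mean) & (log_mean < max_mean) & (df["disp_norm"] >= min_dispersion)
    return list(df.index[sel])


def union_hvgs(sets: list[list[str]]) -> list[str]:
    """Union of HVG lists in first-appearance order."""
    if not sets:
        raise ValueError("union_hvgs requires at least one set")
    out: dict[str, None] = {}
    for s in sets:
        for g in s:
            out.setdefault(g, None)
    return list(out)


def scale(norm: ad.AnnData, genes: list[str] | None = None) -> ad.AnnData:
    """Per-gene z-scoring to zero mean and unit variance (population SD).

    Constant genes map to all-zero columns and are flagged in
    ``.var['constant']``.  The per-gene mean and SD used are stored in
    ``.var`` so the transform is invertible.
    """
    if norm.n_obs < 2:
        raise ValueError("scale requires >= 2 cells")
    sub = norm[:, genes].copy() if genes is not None else norm.copy()
    X = sub.X.toarray() if sp.issparse(sub.X) else np.asarray(sub.X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD
    constant = sd == 0
    safe_sd = np.where(constant, 1.0, sd)
    Z = (X - mean) / safe_sd
    Z[:, constant] = 0.0
    out = ad.AnnData(X=Z, obs=sub.obs.copy(), var=sub.var.copy())
    out.var["scale_mean"] = mean
    out.var["scale_sd"] = sd
    out.var["constant"] = constant
    return out


def run_funnel(counts: ad.AnnData, config: PipelineConfig) -> dict:
    """Run the fixed preprocessing funnel on one count matrix.

    Returns the filtered counts, the normalized matrix, the HVG list for this
    matrix alone, and a stage-by-stage entity-count report.  Cross-condition
    HVG union and scaling are composed by the caller (see pipeline.run_all),
    since they need all conditions at once.
    """
    stages = []

    def record(name: str, a: ad.AnnData) -> None:
        stages.append({"stage": name, "n_cells": a.n_obs, "n_genes": a.n_vars})

    record("input", counts)
    a = qc_filter_cells(
        counts,
        config.min_features_exclusive,
        config.max_mito_fraction,
        config.max_umi_exclusive,
        config.mito_prefix,
    )
    record("qc_filter_cells", a)
    a = remove_unannotated_genes(a, config.unannotated_suffixes, config.unannotated_prefixes)
    record("remove_unannotated_genes", a)
    a = remove_contaminants(a, config.contaminant_markers)
    record("remove_contaminants", a)
    a = filter_cells_genes(a, config.min_genes, config.max_genes, config.min_cells_per_gene)
    record("filter_cells_genes", a)
    norm = normalize(a, config.target_sum)
    record("normalize", norm)
    hvgs = select_hvgs(
        norm,
        config.hvg_min_mean,
        config.hvg_max_mean,
        config.hvg_min_dispersion,
        config.hvg_n_bins,
    )
    stages.append({"stage": "select_hvgs", "n_cells": norm.n_obs, "n_genes": len(hvgs)})
    return {
        "counts": a,
        "normalized": norm,
        "hvgs": hvgs,
        "funnel": pd.DataFrame(stages),
    }
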