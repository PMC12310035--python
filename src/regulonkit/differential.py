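"""Differential regulon activity and hurdle-model differential expression.

Differential regulons: per regulon, a Wilcoxon rank-sum test on raw
(unstandardized) AUC scores between two cell groups, Benjamini-Hochberg
correction across regulons, and a significance call requiring both the
adjusted p-value and a minimum absolute mean-AUC difference — the activity
gate operates on the AUC scale, which is why the raw scores are used.

Differential expression: a two-part hurdle model per gene.  A logistic part
models detection (count > 0) on group; a Gaussian part models the positive
normalized values on group.  The likelihood-ratio chi-square statistics of
the group term in the two parts are summed (degrees of freedom add) and the
combined statistic is referred to a chi-square tail, as in hurdle models
tailored to zero-inflated single-cell data.  With the default design (group
only) both parts have closed-form maximum-likelihood fits, which keeps the
per-gene test exact and fast; an optional per-cell detection-rate covariate
switches to iterative fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wilcoxon_rank_sum",
    "bh_fdr",
    "bonferroni",
    "differential_regulons",
    "log2_fold_change",
    "hurdle_de_test",
    "deg_filter",
    "extract_detgs",
]


# ---------------------------------------------------------------------------
# rank-sum test


@lru_cache(maxsize=None)
def _ranksum_counts(n: int, n1: int) -> dict[int, int]:
    """Number of ways to choose n1 of the ranks 1..n with each rank sum
    (the exact tie-free Mann-Whitney null distribution, by recursion)."""
    if n1 == 0:
        return {0: 1}
    if n1 > n:
        return {}
    # either rank n is chosen or it is not
    with_n = _ranksum_counts(n - 1, n1 - 1)
    without = _ranksum_counts(n - 1, n1)
    out: dict[int, int] = dict(without)
    for s, c in with_n.items():
        out[s + n] = out.get(s + n, 0) + c
    return out


def wilcoxon_rank_sum(x, y, mode: str = "normal") -> tuple[float, float]:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    ``normal`` uses the tie-corrected normal approximation with continuity
    correction; ``exact`` enumerates the null distribution and requires
    n1 + n2 <= 16 with no ties.  Returns (U statistic of x over y, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum: empty sample")
    n1, n2 = x.size, y.size
    if mode == "exact":
        if n1 + n2 > 16:
            raise ValueError("exact mode requires n1 + n2 <= 16")
        pooled = np.concatenate([x, y])
        if np.unique(pooled).size != pooled.size:
            raise ValueError("exact mode requires tie-free data")
        ranks = sps.rankdata(pooled)
        U = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
        counts = _ranksum_counts(n1 + n2, n1)
        total = math.comb(n1 + n2, n1)
        offset = n1 * (n1 + 1) // 2
        center = n1 * n2 / 2
        dev = abs(U - center)
        tail = sum(c for s, c in counts.items() if abs((s - offset) - center) >= dev - 1e-12)
        return U, tail / total
    if mode == "normal":
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# multiple testing


def bh_fdr(pvals) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(list(pvals), dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])


def bonferroni(pvals, m: int | None = None) -> list[float]:
    """min(1, p * m); ``m`` defaults to the number of p-values."""
    arr = np.asarray(list(pvals), dtype=float)
    if m is None:
        m = arr.size
    if m < arr.size:
        raise ValueError(f"m={m} smaller than the number of tests {arr.size}")
    return list(np.minimum(1.0, arr * m))


# ---------------------------------------------------------------------------
# differential regulons


def differential_regulons(
    auc: pd.DataFrame,
    cells_a,
    cells_b,
    alpha: float = 0.05,
    min_abs_auc_diff: float = 0.15,
) -> pd.DataFrame:
    """Wilcoxon + BH + |ΔAUC| gate, one row per regulon.

    ``delta_auc`` is mean(A) - mean(B); a regulon is significant iff its
    BH-adjusted p is below ``alpha`` AND |delta_auc| exceeds
    ``min_abs_auc_diff``.
    """
    cells_a, cells_b = list(cells_a), list(cells_b)
    if set(cells_a) & set(cells_b):
        raise ValueError("cell groups overlap")
    if not cells_a or not cells_b:
        raise ValueError("cell groups must be non-empty")
    A = auc.loc[cells_a]
    B = auc.loc[cells_b]
    rows = []
    for reg in auc.columns:
        x, y = A[reg].to_numpy(), B[reg].to_numpy()
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            u, p = float("nan"), 1.0
        else:
            u, p = wilcoxon_rank_sum(x, y, mode="normal")
        rows.append(
            {
                "regulon": reg,
                "mean_auc_a": float(x.mean()),
                "mean_auc_b": float(y.mean()),
                "delta_auc": float(x.mean() - y.mean()),
                "U": u,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_fdr(df["p"].tolist())
    df["significant"] = (df["p_adj"] < alpha) & (df["delta_auc"].abs() > min_abs_auc_diff)
    return df


# ---------------------------------------------------------------------------
# hurdle differential expression


def log2_fold_change(values_1, values_2, pseudocount: float = 1.0) -> float:
    """log2 ratio of group means on the depth-normalized (expm1) scale."""
    v1 = np.expm1(np.asarray(values_1, dtype=float))
    v2 = np.expm1(np.asarray(values_2, dtype=float))
    if v1.size == 0 or v2.size == 0:
        raise ValueError("log2_fold_change: empty group")
    return float(np.log2((v1.mean() + pseudocount) / (v2.mean() + pseudocount)))


def _binomial_ll(d: int, n: int) -> float:
    # maximized Bernoulli log-likelihood of d detections in n cells
    if d == 0 or d == n:
        return 0.0
    p = d / n
    return d * math.log(p) + (n - d) * math.log(1 - p)


def _logistic_lrt(det_a: np.ndarray, det_b: np.ndarray) -> float:
    """Group-term LRT chi-square of the detection (logistic) part; closed
    form from the 2x2 detection table under the group-only design."""
    da, na = int(det_a.sum()), det_a.size
    db, nb = int(det_b.sum()), det_b.size
    ll_full = _binomial_ll(da, na) + _binomial_ll(db, nb)
    ll_null = _binomial_ll(da + db, na + nb)
    return max(0.0, 2.0 * (ll_full - ll_null))


def _gaussian_lrt(pos_a: np.ndarray, pos_b: np.ndarray) -> float:
    """Group-term LRT chi-square of the positive (Gaussian) part:
    n * ln(RSS_null / RSS_group)."""
    y = np.concatenate([pos_a, pos_b])
    n = y.size
    rss0 = float(np.sum((y - y.mean()) ** 2))
    rss1 = float(
        np.sum((pos_a - pos_a.mean()) ** 2) + np.sum((pos_b - pos_b.mean()) ** 2)
    )
    if rss1 <= 0 or rss0 <= 0:
        return 0.0 if rss0 <= rss1 else float("inf")
    return max(0.0, n * math.log(rss0 / rss1))


def _covariate_lrt_logit(det: np.ndarray, group: np.ndarray, covar: np.ndarray) -> tuple[float, bool]:
    import statsmodels.api as sm

    Xf = sm.add_constant(np.column_stack([group, covar]))
    X0 = sm.add_constant(covar)
    flagged = False
    try:
        full = sm.Logit(det, Xf).fit(disp=0, maxiter=100)
        null = sm.Logit(det, X0).fit(disp=0, maxiter=100)
        if not (full.mle_retvals.get("converged", True) and null.mle_retvals.get("converged", True)):
            raise RuntimeError("no convergence")
        stat = 2.0 * (full.llf - null.llf)
    except Exception:
        # separation or non-convergence: ridge-penalized fallback
        flagged = True
        full = sm.Logit(det, Xf).fit_regularized(disp=0, alpha=1e-4, L1_wt=0.0)
        null = sm.Logit(det, X0).fit_regularized(disp=0, alpha=1e-4, L1_wt=0.0)
        stat = 2.0 * (full.llf - null.llf)
    return max(0.0, float(stat)), flagged


def hurdle_de_test(
    norm: ad.AnnData,
    group_labels: pd.Series | dict,
    include_detection_covariate: bool = False,
) -> pd.DataFrame:
    """Two-part hurdle test of every gene between two cell groups.

    ``group_labels`` maps each cell of the matrix to one of exactly two
    labels.  Returns one row per gene with the combined chi-square statistic,
    its degrees of freedom, the tail p-value, per-part components, detection
    fractions and the log2 fold change.  Genes detected in fewer than 3
    cells overall (or when either group has fewer than 3 cells) are assigned
    p = 1 and flagged rather than fitted.
    """
    labels = pd.Series(group_labels)
    labels = labels.reindex(norm.obs_names)
    if labels.isna().any():
        raise ValueError("group_labels must cover every cell in the matrix")
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    ga, gb = groups
    mask_a = (labels == ga).to_numpy()
    mask_b = (labels == gb).to_numpy()
    X = norm.X.toarray() if sp.issparse(norm.X) else np.asarray(norm.X, dtype=float)
    det_all = X > 0
    covar = det_all.mean(axis=1) if include_detection_covariate else None
    group_ind = mask_a.astype(float)

    small_groups = mask_a.sum() < 3 or mask_b.sum() < 3
    if include_detection_covariate:
        rows = []
        for j, gene in enumerate(norm.var_names):
            col = X[:, j]
            det = det_all[:, j]
            xa, xb = col[mask_a], col[mask_b]
            da, db = det[mask_a], det[mask_b]
            base = {
                "gene": gene,
                "pct_1": float(da.mean()),
                "pct_2": float(db.mean()),
                "log2fc": log2_fold_change(xa, xb),
            }
            if small_groups or det.sum() < 3:
                rows.append(
                    base
                    | {
                        "chi2_detection": np.nan,
                        "chi2_positive": np.nan,
                        "df": 0,
                        "stat": np.nan,
                        "p": 1.0,
                        "flag": "insufficient_cells",
                    }
                )
                continue
            chi_d, flagged = _covariate_lrt_logit(det.astype(float), group_ind, covar)
            chi_c, df_total = 0.0, 1
            pa, pb = xa[xa > 0], xb[xb > 0]
            if pa.size >= 2 and pb.size >= 2:
                chi_c = _gaussian_lrt(pa, pb)
                df_total += 1
            stat = chi_d + chi_c
            rows.append(
                base
                | {
                    "chi2_detection": chi_d,
                    "chi2_positive": chi_c,
                    "df": df_total,
                    "stat": stat,
                    "p": float(sps.chi2.sf(stat, df_total)),
                    "flag": "penalized_logistic" if flagged else "",
                }
            )
        return pd.DataFrame(rows)

    # group-only design: every per-gene fit is closed-form, so vectorize
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    Xa, Xb = X[mask_a], X[mask_b]
    da = det_all[mask_a].sum(axis=0).astype(float)
    db = det_all[mask_b].sum(axis=0).astype(float)

    def binom_ll(d, n):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = d / n
            ll = d * np.log(p) + (n - d) * np.log(1 - p)
        return np.where((d == 0) | (d == n), 0.0, ll)

    chi_d = 2.0 * (binom_ll(da, na) + binom_ll(db, nb) - binom_ll(da + db, na + nb))
    chi_d = np.maximum(chi_d, 0.0)

    # Gaussian part over positive values, from per-group sums of x and x^2
    pos_a, pos_b = Xa > 0, Xb > 0
    ka, kb = pos_a.sum(axis=0), pos_b.sum(axis=0)
    sa, sb = (Xa * pos_a).sum(axis=0), (Xb * pos_b).sum(axis=0)
    qa, qb = (Xa**2 * pos_a).sum(axis=0), (Xb**2 * pos_b).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rss_a = qa - sa**2 / np.maximum(ka, 1)
        rss_b = qb - sb**2 / np.maximum(kb, 1)
        k = ka + kb
        s, q = sa + sb, qa + qb
        rss0 = q - s**2 / np.maximum(k, 1)
        rss1 = rss_a + rss_b
        cont_ok = (ka >= 2) & (kb >= 2)
        ratio = np.where((rss1 > 0) & (rss0 > 0), rss0 / np.maximum(rss1, 1e-300), 1.0)
        chi_c = np.where(cont_ok, np.maximum(k * np.log(ratio), 0.0), 0.0)
        chi_c = np.where(cont_ok & (rss1 <= 0) & (rss0 > rss1), np.inf, chi_c)
    df_total = 1 + cont_ok.astype(int)
    stat = chi_d + chi_c
    p = sps.chi2.sf(stat, df_total)

    mean_a = np.expm1(Xa).mean(axis=0)
    mean_b = np.expm1(Xb).mean(axis=0)
    lfc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    unfit = small_groups | (det_all.sum(axis=0) < 3)
    out = pd.DataFrame(
        {
            "gene": norm.var_names,
            "chi2_detection": np.where(unfit, np.nan, chi_d),
            "chi2_positive": np.where(unfit, np.nan, chi_c),
            "df": np.where(unfit, 0, df_total),
            "stat": np.where(unfit, np.nan, stat),
            "p": np.where(unfit, 1.0, p),
            "pct_1": da / na,
            "pct_2": db / nb,
            "log2fc": lfc,
            "flag": np.where(unfit, "insufficient_cells", ""),
        }
    )
    return out.reset_index(drop=True)


def deg_filter(
    stats: pd.DataFrame,
    lfc_threshold: float = 0.585,
    min_pct: float = 0.15,
    min_diff_pct: float = 0.15,
    alpha: float = 0.05,
    m: int | None = None,
) -> pd.DataFrame:
    """Report genes passing all four gates with Bonferroni-adjusted p.

    Gates: max(pct_1, pct_2) >= min_pct, |pct_1 - pct_2| >= min_diff_pct,
    |log2fc| >= lfc_threshold, and adjusted p < alpha.  Bonferroni uses ``m``
    (by convention, the total number of genes considered, not only those
    passing the speed gates).
    """
    df = stats.copy()
    if m is None:
        m = len(df)
    df["p_adj"] = bonferroni(df["p"].tolist(), m)
    keep = (
        (df[["pct_1", "pct_2"]].max(axis=1) >= min_pct)
        & ((df["pct_1"] - df["pct_2"]).abs() >= min_diff_pct)
        & (df["log2fc"].abs() >= lfc_threshold)
        & (df["p_adj"] < alpha)
    )
    out = df.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out.reset_index(drop=True)


def extract_detgs(regulon, degs: pd.DataFrame) -> pd.DataFrame:
    """Differentially expressed target genes of one consensus regulon.

    Intersects the regulon's target table with a DEG table by gene symbol;
    members keep their within-regulon consensus rank and are sorted by it.
    """
    table = regulon.table[["target", "rank", "frequency"]].rename(columns={"target": "gene"})
    merged = table.merge(degs, on="gene", how="inner")
    merged.insert(0, "tf", regulon.tf)
    return merged.sort_values("rank").reset_index(drop=True)
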