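"""Frequency-based consensus regulons aggregated over stochastic runs.

A target's rank inside a consensus regulon is driven by the fraction of
inference runs whose module for that TF contained it; importance scores only
break ties because gain-sums are not comparable across targets' models.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .enrichment import hypergeom_upper_tail
from .grn import RunRegulon

__all__ = [
    "ConsensusRegulon",
    "aggregate_runs",
    "attach_expression_stats",
    "common_and_unique",
    "tf_overlap_validation",
    "consensus_to_frame",
    "consensus_from_frame",
]

_COLUMNS = [
    "target",
    "frequency",
    "imp_mean",
    "imp_median",
    "imp_sd",
    "expr_mean",
    "expr_median",
    "expr_sd",
    "rank",
]


@dataclass
class ConsensusRegulon:
    """A TF with its frequency-ranked target table across runs."""

    tf: str
    table: pd.DataFrame  # columns _COLUMNS, sorted by rank
    n_runs: int
    condition: str = ""

    @property
    def targets(self) -> list[str]:
        return list(self.table["target"])


def aggregate_runs(
    per_run: list[list[RunRegulon]], condition: str = ""
) -> list[ConsensusRegulon]:
    """Union-aggregate per-run regulons into consensus regulons.

    Per target: frequency = (# runs whose module for the TF contains it) /
    n_runs; importance summaries (mean/median/population SD) are taken over
    the runs where the target appeared.  Targets sort by frequency desc, mean
    importance desc, symbol asc; aggregation is invariant to run order.
    """
    n_runs = len(per_run)
    if n_runs < 1:
        raise ValueError("aggregate_runs requires >= 1 run")
    hits: dict[str, dict[str, list[float]]] = {}
    for run in per_run:
        for mod in run:
            tgt = hits.setdefault(mod.tf, {})
            for t in mod.targets:
                tgt.setdefault(t, []).append(mod.importances.get(t, np.nan))
    out: list[ConsensusRegulon] = []
    for tf in sorted(hits):
        rows = []
        for target, imps in hits[tf].items():
            arr = np.asarray(imps, dtype=float)
            rows.append(
                {
                    "target": target,
                    "frequency": len(imps) / n_runs,
                    "imp_mean": float(np.mean(arr)),
                    "imp_median": float(np.median(arr)),
                    "imp_sd": float(np.std(arr)),
                    "expr_mean": np.nan,
                    "expr_median": np.nan,
                    "expr_sd": np.nan,
                }
            )
        df = pd.DataFrame(rows)
        df = df.sort_values(
            ["frequency", "imp_mean", "target"],
            ascending=[False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        out.append(ConsensusRegulon(tf=tf, table=df[_COLUMNS], n_runs=n_runs, condition=condition))
    return out


def attach_expression_stats(
    consensus: list[ConsensusRegulon], norm: ad.AnnData
) -> list[ConsensusRegulon]:
    """Fill per-target mean/median/population-SD of normalized expression
    over all cells of the condition; targets absent from the matrix keep
    null statistics."""
    X = norm.X.toarray() if sp.issparse(norm.X) else np.asarray(norm.X, dtype=float)
    loc = {g: i for i, g in enumerate(norm.var_names)}
    out = []
    for reg in consensus:
        df = reg.table.copy()
        means, medians, sds = [], [], []
        for t in df["target"]:
            if t in loc:
                col = X[:, loc[t]]
                means.append(float(col.mean()))
                medians.append(float(np.median(col)))
                sds.append(float(col.std()))
            else:
                means.append(np.nan)
                medians.append(np.nan)
                sds.append(np.nan)
        df["expr_mean"], df["expr_median"], df["expr_sd"] = means, medians, sds
        out.append(ConsensusRegulon(reg.tf, df, reg.n_runs, reg.condition))
    return out


def common_and_unique(
    consA: list[ConsensusRegulon], consB: list[ConsensusRegulon]
) -> tuple[list[str], list[str], list[str]]:
    """Partition regulon TFs into common and condition-unique sets."""
    a, b = {r.tf for r in consA}, {r.tf for r in consB}
    return sorted(a & b), sorted(a - b), sorted(b - a)


def tf_overlap_validation(
    detected_tfs: set[str], curated: set[str], background: set[str]
) -> dict:
    """Overlap of detected regulon TFs with a curated TF list.

    Reports the overlap count, the fraction of detected TFs found in the
    curated list, the same fraction for the non-detected background
    complement, and a hypergeometric over-representation p-value.
    """
    if not detected_tfs <= background:
        raise ValueError("detected TFs must be a subset of the background")
    curated_bg = curated & background
    k = len(detected_tfs & curated_bg)
    n = len(detected_tfs)
    rest = background - detected_tfs
    rest_overlap = len(rest & curated_bg)
    p = hypergeom_upper_tail(k, len(curated_bg), n, len(background))
    return {
        "n_detected": n,
        "n_curated_in_background": len(curated_bg),
        "overlap": k,
        "fraction_detected_in_curated": k / n if n else float("nan"),
        "fraction_rest_in_curated": rest_overlap / len(rest) if rest else float("nan"),
        "hypergeometric_p": p,
    }


def consensus_to_frame(consensus: list[ConsensusRegulon]) -> pd.DataFrame:
    """Flatten to the documented TSV layout (one row per tf-target pair)."""
    frames = []
    for reg in consensus:
        df = reg.table.copy()
        df.insert(0, "tf", reg.tf)
        df["n_runs"] = reg.n_runs
        df["condition"] = reg.condition
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["tf", *_COLUMNS, "n_runs", "condition"])
    return pd.concat(frames, ignore_index=True)


def consensus_from_frame(df: pd.DataFrame) -> list[ConsensusRegulon]:
    out = []
    for tf, grp in df.groupby("tf", sort=True):
        out.append(
            ConsensusRegulon(
                tf=str(tf),
                table=grp[_COLUMNS].sort_values("rank").reset_index(drop=True),
                n_runs=int(grp["n_runs"].iloc[0]),
                condition=str(grp["condition"].iloc[0]),
            )
        )
    return out
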