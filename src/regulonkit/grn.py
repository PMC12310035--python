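"""Tree-ensemble TF->target network inference and module construction.

Each gene's scaled expression profile is regressed on the profiles of all
candidate transcription factors (excluding itself) with a stochastic
gradient-boosted regression ensemble; the importance of an edge tf->target is
the total split-improvement (gain) the ensemble attributes to that TF.  To
absorb the stochasticity of the fits, inference is repeated ``n_runs`` times
with derived seeds and downstream consensus works on run frequency.

Motif-based regulon pruning requires external ranking databases; this module
instead prunes modules against a user- or generator-supplied TF->target
evidence table (``prune_with_prior``).  That substitution is deliberate and
is the only step of the workflow replaced by an interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.ensemble import GradientBoostingRegressor

from .config import derive_seed

__all__ = [
    "GBMHyperparams",
    "RunRegulon",
    "infer_edges",
    "build_modules",
    "prune_with_prior",
    "run_multi",
]


@dataclass(frozen=True)
class GBMHyperparams:
    """Stochastic GBM settings (the published GRNBoost2 defaults)."""

    max_trees: int = 500
    learning_rate: float = 0.01
    subsample: float = 0.9
    max_features: float = 0.1
    early_stop_window: int = 25


@dataclass
class RunRegulon:
    """One TF's module from a single inference run."""

    tf: str
    targets: list[str]  # ordered by importance desc, then symbol asc
    importances: dict[str, float] = field(default_factory=dict)
    run_index: int = 0


class _EarlyStopMonitor:
    """Stop boosting once the mean out-of-bag improvement over the trailing
    window turns negative (the GRNBoost2 stopping rule)."""

    def __init__(self, window: int):
        self.window = window

    def __call__(self, i: int, regressor, _locals) -> bool:
        if i >= self.window - 1:
            lo = max(0, i - self.window + 1)
            return float(np.mean(regressor.oob_improvement_[lo : i + 1])) < 0.0
        return False


def infer_edges(
    expr: ad.AnnData,
    tf_list: list[str],
    seed: int = 0,
    hyperparams: GBMHyperparams = GBMHyperparams(),
) -> pd.DataFrame:
    """Infer a TF->target edge importance list from scaled expression.

    Returns a DataFrame with columns ``tf``, ``target``, ``importance``
    (gain-sum, strictly positive rows only), sorted by importance within
    target.  Fits iterate over cells in canonically sorted cell-id order, so
    permuting the input rows leaves all importances unchanged.  Importances
    are not normalized across targets: only within-target comparisons (and
    cross-run frequencies) are meaningful.
    """
    if expr.n_obs < 10:
        raise ValueError(f"infer_edges needs >= 10 cells, got {expr.n_obs}")
    tfs = [t for t in tf_list if t in expr.var_names]
    if len(tfs) < 2:
        raise ValueError(f"need >= 2 TFs present in the matrix, found {len(tfs)}")
    order = np.argsort(expr.obs_names.to_numpy())
    X_all = expr.X.toarray() if sp.issparse(expr.X) else np.asarray(expr.X, dtype=float)
    X_all = X_all[order]
    tf_idx = {t: expr.var_names.get_loc(t) for t in tfs}
    tf_cols = X_all[:, [tf_idx[t] for t in tfs]]

    hp = hyperparams
    records: list[tuple[str, str, float]] = []
    for j, target in enumerate(expr.var_names):
        y = X_all[:, j]
        if np.all(y == y[0]):
            continue  # constant target: no split can improve the loss
        if target in tf_idx:
            keep = [i for i, t in enumerate(tfs) if t != target]
            X = tf_cols[:, keep]
            regs = [tfs[i] for i in keep]
        else:
            X = tf_cols
            regs = tfs
        if X.shape[1] == 0:
            continue
        model = GradientBoostingRegressor(
            n_estimators=hp.max_trees,
            learning_rate=hp.learning_rate,
            subsample=hp.subsample,
            max_features=hp.max_features,
            random_state=derive_seed(seed, f"gbm:{target}"),
        )
        model.fit(X, y, monitor=_EarlyStopMonitor(hp.early_stop_window))
        gains = np.sum(
            [t[0].tree_.compute_feature_importances(normalize=False) for t in model.estimators_],
            axis=0,
        )
        for r, g in zip(regs, gains):
            if g > 0:
                records.append((r, target, float(g)))
    df = pd.DataFrame(records, columns=["tf", "target", "importance"])
    return df.sort_values(
        ["target", "importance", "tf"], ascending=[True, False, True]
    ).reset_index(drop=True)


def build_modules(
    edges: pd.DataFrame,
    top_n_targets: int = 50,
    importance_quantile: float = 0.0,
    run_index: int = 0,
) -> list[RunRegulon]:
    """Select each TF's module from the edge list.

    Retains, per TF, the union of (a) the ``top_n_targets`` targets by
    importance and (b) targets whose importance exceeds the global
    ``importance_quantile`` of all edge importances (disabled at 0).  Ties at
    the top-n cutoff keep the lexicographically smaller target symbol.
    """
    if edges.empty:
        raise ValueError("build_modules: empty edge list")
    threshold = (
        float(np.quantile(edges["importance"].to_numpy(), importance_quantile))
        if importance_quantile > 0
        else np.inf
    )
    modules: list[RunRegulon] = []
    for tf, grp in edges.groupby("tf", sort=True):
        grp = grp.sort_values(
            ["importance", "target"], ascending=[False, True], kind="mergesort"
        )
        kept = set(grp["target"].head(top_n_targets) if top_n_targets else [])
        if importance_quantile > 0:
            kept |= set(grp.loc[grp["importance"] > threshold, "target"])
        if not kept:
            continue
        ordered = [t for t in grp["target"] if t in kept]
        imps = dict(zip(grp["target"], grp["importance"]))
        modules.append(
            RunRegulon(
                tf=str(tf),
                targets=ordered,
                importances={t: imps[t] for t in ordered},
                run_index=run_index,
            )
        )
    return modules


def prune_with_prior(
    modules: list[RunRegulon],
    prior: pd.DataFrame,
    min_size: int = 3,
    permissive: bool = False,
) -> list[RunRegulon]:
    """Intersect each module's targets with prior TF->target evidence.

    TFs absent from the prior are dropped (conservative) or passed through
    unchanged (``permissive``); pruned modules smaller than ``min_size`` are
    dropped.
    """
    if prior.empty:
        raise ValueError("prune_with_prior: empty prior table")
    allowed: dict[str, set[str]] = {
        tf: set(grp["target"]) for tf, grp in prior.groupby("tf")
    }
    if not any(m.tf in allowed for m in modules):
        raise ValueError("prior covers no module TF")
    out: list[RunRegulon] = []
    for m in modules:
        if m.tf not in allowed:
            if permissive:
                out.append(m)
            continue
        targets = [t for t in m.targets if t in allowed[m.tf]]
        if len(targets) < min_size:
            continue
        out.append(
            RunRegulon(
                tf=m.tf,
                targets=targets,
                importances={t: m.importances[t] for t in targets},
                run_index=m.run_index,
            )
        )
    return out


def run_multi(
    expr: ad.AnnData,
    tf_list: list[str],
    prior: pd.DataFrame | None,
    n_runs: int = 20,
    master_seed: int = 0,
    hyperparams: GBMHyperparams = GBMHyperparams(),
    top_n_targets: int = 50,
    importance_quantile: float = 0.0,
    prior_min_size: int = 3,
    prior_permissive: bool = False,
) -> list[list[RunRegulon]]:
    """Repeat infer_edges -> build_modules -> prune_with_prior for each run.

    Run *r* uses ``derive_seed(master_seed, "grn", r)``; output order and
    content match sequential execution by construction.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    runs: list[list[RunRegulon]] = []
    for r in range(n_runs):
        try:
            edges = infer_edges(expr, tf_list, derive_seed(master_seed, "grn", r), hyperparams)
            mods = build_modules(edges, top_n_targets, importance_quantile, run_index=r)
            if prior is not None:
                mods = prune_with_prior(mods, prior, prior_min_size, prior_permissive)
        except Exception as e:  # annotate failures with the run index
            raise RuntimeError(f"GRN run {r} failed: {e}") from e
        runs.append(mods)
    return runs
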