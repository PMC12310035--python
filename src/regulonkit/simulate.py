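"""Two-condition single-cell count simulator with planted regulons.

The generator emulates the population structure the pipeline is built to
analyse: two mouse-group-like conditions sharing several subclusters of one
focal cell type, one condition carrying an additional unique subcluster, and
a small admixture of contaminating cells expressing exclusion markers.

Each transcription factor (TF) owns a disjoint set of target genes.  A
subcluster is defined by a binary activity program over the TFs: in cells of
a subcluster where TF *t* is active, the TF's own mean and every target's
mean are multiplied by ``activity_effect``.  Counts are negative binomial
(gamma-Poisson) with a shared dispersion, per-cell log-normal depth factors,
and independent per-entry Bernoulli dropout — the simplest noise model with
the zero inflation the hurdle differential-expression test assumes.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GroundTruth",
    "make_ground_truth",
    "simulate_counts",
    "spike_contaminants",
    "prior_table",
    "planted_gmt",
]

CONDITIONS = ("A", "B")
DEFAULT_MARKERS = ("Ptprc", "Adgre1")


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset; the oracle for recovery tests."""

    tf_ids: list[str]
    regulon_targets: dict[str, list[str]]
    # programs[condition][subcluster][tf] -> activity in [0, 1]
    subcluster_programs: dict[str, dict[str, dict[str, float]]]
    unique_subcluster: tuple[str, str] | None
    activity_effect: float
    housekeeping_genes: list[str] = field(default_factory=list)
    # per-gene program-independent baseline means for housekeeping genes;
    # log-normal across genes so flat genes span the whole mean range, as in
    # real transcriptomes (anchors the binned HVG dispersion statistic)
    housekeeping_means: list[float] = field(default_factory=list)
    # per-gene baseline means of TFs and targets, log-uniform around
    # baseline_mean: regulon members have diverse expression levels
    planted_means: dict[str, float] = field(default_factory=dict)
    marker_genes: list[str] = field(default_factory=lambda: list(DEFAULT_MARKERS))
    cell_assignments: dict[str, tuple[str, str]] = field(default_factory=dict)
    contaminant_cells: set[str] = field(default_factory=set)
    baseline_mean: float = 6.0
    flat_mean_scale: float = 2.5
    nb_dispersion: float = 0.3
    dropout_rate: float = 0.1
    depth_sigma: float = 0.3

    @property
    def all_genes(self) -> list[str]:
        targets = [g for tf in self.tf_ids for g in self.regulon_targets[tf]]
        return self.tf_ids + targets + self.housekeeping_genes + self.marker_genes

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return {(tf, g) for tf in self.tf_ids for g in self.regulon_targets[tf]}

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contaminant_cells"] = sorted(self.contaminant_cells)
        d["cell_assignments"] = {c: list(v) for c, v in self.cell_assignments.items()}
        d["unique_subcluster"] = list(self.unique_subcluster) if self.unique_subcluster else None
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["contaminant_cells"] = set(d["contaminant_cells"])
        d["cell_assignments"] = {c: tuple(v) for c, v in d["cell_assignments"].items()}
        if d["unique_subcluster"] is not None:
            d["unique_subcluster"] = tuple(d["unique_subcluster"])
        return cls(**d)


def _sample_programs(
    rng: np.random.Generator, n_shared: int, n_programs: int, n_tfs: int, min_hamming: int
) -> np.ndarray:
    """Binary program matrix (programs x TFs; the first ``n_shared`` rows are
    the shared programs) with pairwise Hamming distance >= min_hamming.

    Per-TF activity patterns are drawn from the pool of patterns that vary
    across the shared programs (a TF constant within a condition carries no
    co-expression signal there), without replacement while the pool allows:
    two TFs with identical activity everywhere would be indistinguishable by
    co-expression, by construction rather than by method failure."""
    import itertools

    pats = []
    for bits in itertools.product((0.0, 1.0), repeat=n_programs):
        shared_bits = bits[:n_shared]
        if n_shared >= 2 and not 0 < sum(shared_bits) < n_shared:
            continue
        if n_shared < 2 and n_programs >= 2 and not 0 < sum(bits) < n_programs:
            continue
        # a regulon active in most subpopulations is close to ubiquitous:
        # its inactive minority gives little between-population variance,
        # so cap activity at half the programs
        if n_programs >= 2 and sum(bits) > math.ceil(n_programs / 2):
            continue
        pats.append(bits)
    pool = np.array(pats, dtype=float)
    for _ in range(100_000):
        replace = len(pool) < n_tfs
        idx = rng.choice(len(pool), size=n_tfs, replace=replace)
        progs = pool[idx].T  # programs x TFs
        ok = all(progs[i].sum() >= 1 for i in range(n_programs))
        for i in range(n_programs):
            for j in range(i + 1, n_programs):
                if np.abs(progs[i] - progs[j]).sum() < min_hamming:
                    ok = False
        if ok:
            return progs
    raise RuntimeError(
        f"could not sample {n_programs} programs over {n_tfs} TFs with "
        f"pairwise Hamming distance >= {min_hamming}"
    )


def make_ground_truth(
    n_tfs: int,
    targets_per_tf: int,
    n_shared_subclusters: int,
    include_unique: bool = True,
    activity_effect: float = 4.0,
    seed: int = 0,
    n_housekeeping: int = 3000,
    gene_budget: int | None = None,
    graded: bool = False,
    **noise_params,
) -> GroundTruth:
    """Draw planted regulons and subcluster activity programs.

    Shared subcluster programs are identical in both conditions; when
    ``include_unique`` is set, condition A receives one extra subcluster
    whose program differs from every shared program in at least 25% of the
    TF activities.  Target sets are pairwise disjoint and disjoint from the
    TF set.
    """
    needed = n_tfs * targets_per_tf + n_tfs + n_housekeeping
    if gene_budget is not None and needed > gene_budget:
        raise ValueError(
            f"gene budget {gene_budget} infeasible: need {needed} genes "
            f"({n_tfs} TFs x {targets_per_tf} targets + {n_housekeeping} housekeeping)"
        )
    if activity_effect < 1:
        raise ValueError(f"activity_effect must be >= 1, got {activity_effect}")
    rng = np.random.default_rng(seed)
    tf_ids = [f"Tf{i + 1:02d}" for i in range(n_tfs)]
    regulon_targets = {
        tf: [f"Tg{i * targets_per_tf + j + 1:04d}" for j in range(targets_per_tf)]
        for i, tf in enumerate(tf_ids)
    }
    hk = [f"Hk{i + 1:03d}" for i in range(n_housekeeping)]
    # flat-gene means are log-normal on their own scale with a rare high
    # tail: most genes lowly expressed, a few strongly expressed, as in real
    # transcriptomes.  This anchors every HVG mean bin with non-variable
    # genes while keeping the top of each cell's expression ranking
    # reachable by active regulon targets (planted modules are moderately
    # high-expressed genes, above nearly all flat genes when active).
    flat_scale = noise_params.get("flat_mean_scale", GroundTruth.flat_mean_scale)
    hk_means = [
        float(flat_scale * 2.0 ** np.clip(rng.normal(-0.5, 1.5), -3.0, 4.5))
        for _ in range(n_housekeeping)
    ]
    base = noise_params.get("baseline_mean", GroundTruth.baseline_mean)
    planted = tf_ids + [g for tf in tf_ids for g in regulon_targets[tf]]
    planted_means = {g: float(base * 2.0 ** rng.uniform(-1.0, 1.0)) for g in planted}

    min_hamming = max(1, math.ceil(0.25 * n_tfs))
    n_programs = n_shared_subclusters + (1 if include_unique else 0)
    progs = _sample_programs(rng, n_shared_subclusters, n_programs, n_tfs, min_hamming)
    if graded:
        # graded activities: active entries draw a strength in [0.5, 1]
        progs = progs * rng.uniform(0.5, 1.0, size=progs.shape)

    shared_names = [f"S{i + 1}" for i in range(n_shared_subclusters)]
    programs: dict[str, dict[str, dict[str, float]]] = {c: {} for c in CONDITIONS}
    for i, name in enumerate(shared_names):
        vec = {tf: float(progs[i, j]) for j, tf in enumerate(tf_ids)}
        for c in CONDITIONS:
            programs[c][name] = dict(vec)
    unique: tuple[str, str] | None = None
    if include_unique:
        # unique subcluster lives in condition A, the control analogue
        vec = {tf: float(progs[-1, j]) for j, tf in enumerate(tf_ids)}
        programs["A"]["U1"] = vec
        unique = ("A", "U1")

    return GroundTruth(
        tf_ids=tf_ids,
        regulon_targets=regulon_targets,
        subcluster_programs=programs,
        unique_subcluster=unique,
        activity_effect=float(activity_effect),
        housekeeping_genes=hk,
        housekeeping_means=hk_means,
        planted_means=planted_means,
        **noise_params,
    )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_counts(
    gt: GroundTruth, cells_per_subcluster: int = 150, seed: int = 0
) -> dict[str, ad.AnnData]:
    """Simulate one count matrix per condition.

    Gene *g* in a cell of subcluster *s* has mean
    ``baseline * (1 + (activity_effect - 1) * program[s][tf(g)]) * depth_c``
    where ``tf(g)`` is the TF owning *g* (a TF gene scales by its own
    activity); housekeeping genes keep the baseline mean and exclusion-marker
    genes are silent.  Cell metadata records the true condition, subcluster,
    contaminant status and a mitochondrial fraction drawn below the QC
    threshold for genuine cells.
    """
    rng = np.random.default_rng(seed)
    genes = gt.all_genes
    n_genes = len(genes)
    gene_tf = np.full(n_genes, -1)  # index of owning TF, -1 = none
    for j, g in enumerate(genes):
        if g in gt.tf_ids:
            gene_tf[j] = gt.tf_ids.index(g)
        else:
            for i, tf in enumerate(gt.tf_ids):
                if g in gt.regulon_targets[tf]:
                    gene_tf[j] = i
                    break
    is_marker = np.array([g in gt.marker_genes for g in genes])
    hk_mean = dict(zip(gt.housekeeping_genes, gt.housekeeping_means or []))
    base_flat = np.array(
        [gt.planted_means.get(g, hk_mean.get(g, gt.baseline_mean)) for g in genes]
    )

    out: dict[str, ad.AnnData] = {}
    for cond in CONDITIONS:
        sub_names = list(gt.subcluster_programs[cond])
        rows, cell_ids, sub_labels, depths = [], [], [], []
        for s in sub_names:
            prog = np.array([gt.subcluster_programs[cond][s][tf] for tf in gt.tf_ids])
            act = np.where(gene_tf >= 0, prog[np.clip(gene_tf, 0, None)], 0.0)
            base = base_flat * (1.0 + (gt.activity_effect - 1.0) * act)
            base = np.where(is_marker, 0.0, base)
            for i in range(cells_per_subcluster):
                depth = float(rng.lognormal(0.0, gt.depth_sigma))
                counts = _nb_counts(rng, base * depth, gt.nb_dispersion)
                keep = rng.random(n_genes) >= gt.dropout_rate
                counts = counts * keep
                rows.append(counts)
                cell_ids.append(f"{cond}_{s}_c{i + 1:04d}")
                sub_labels.append(s)
                depths.append(depth)
        X = sp.csc_matrix(np.asarray(rows, dtype=np.int64))
        obs = pd.DataFrame(
            {
                "condition": cond,
                "subcluster": sub_labels,
                "mito_frac": rng.beta(2.0, 48.0, size=len(cell_ids)),
                "depth_factor": depths,
                "is_contaminant": False,
            },
            index=pd.Index(cell_ids, name="cell"),
        )
        adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
        for c, s in zip(cell_ids, sub_labels):
            gt.cell_assignments[c] = (cond, s)
        out[cond] = adata
    return out


def spike_contaminants(
    adata: ad.AnnData,
    gt: GroundTruth,
    marker_genes: list[str] | None = None,
    fraction: float = 0.02,
    seed: int = 0,
) -> ad.AnnData:
    """Append ``ceil(fraction * n_cells)`` contaminating cells.

    Contaminants express every listed marker gene (count >= 1) on top of a
    Poisson draw around the existing per-gene mean; their ids are recorded in
    ``gt.contaminant_cells`` so downstream filters can be validated exactly.
    """
    if fraction > 0.5:
        raise ValueError(f"contaminant fraction {fraction} > 0.5 is unrealistic")
    if fraction < 0:
        raise ValueError("fraction must be non-negative")
    markers = list(marker_genes if marker_genes is not None else gt.marker_genes)
    missing = [m for m in markers if m not in adata.var_names]
    if missing:
        raise ValueError(f"marker genes absent from matrix: {missing}")
    n_new = math.ceil(fraction * adata.n_obs)
    if n_new == 0:
        return adata
    rng = np.random.default_rng(seed)
    gene_means = np.asarray(adata.X.mean(axis=0)).ravel()
    marker_idx = [adata.var_names.get_loc(m) for m in markers]
    cond = str(adata.obs["condition"].iloc[0]) if "condition" in adata.obs else "A"
    rows, ids = [], []
    for i in range(n_new):
        counts = rng.poisson(gene_means)
        for j in marker_idx:
            counts[j] = 1 + rng.poisson(3.0)
        rows.append(counts)
        ids.append(f"{cond}_CONTAM_c{i + 1:04d}")
    new_obs = pd.DataFrame(
        {
            "condition": cond,
            "subcluster": "CONTAM",
            "mito_frac": rng.beta(2.0, 48.0, size=n_new),
            "depth_factor": 1.0,
            "is_contaminant": True,
        },
        index=pd.Index(ids, name="cell"),
    )
    extra = ad.AnnData(
        X=sp.csc_matrix(np.asarray(rows, dtype=np.int64)),
        obs=new_obs,
        var=adata.var.copy(),
    )
    combined = ad.concat([adata, extra], join="outer", merge="same")
    combined.X = sp.csc_matrix(combined.X).astype(np.int64)
    gt.contaminant_cells.update(ids)
    for c in ids:
        gt.cell_assignments[c] = (cond, "CONTAM")
    return combined


def prior_table(gt: GroundTruth, false_edge_rate: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """TF->target evidence table from the planted edges.

    ``false_edge_rate`` adds that many false edges per true edge, drawn
    uniformly from non-planted (tf, gene) pairs, to emulate a noisy motif
    prior.
    """
    rows = [(tf, g) for tf in gt.tf_ids for g in gt.regulon_targets[tf]]
    if false_edge_rate > 0:
        rng = np.random.default_rng(seed)
        pool = [
            (tf, g)
            for tf in gt.tf_ids
            for g in gt.all_genes
            if g != tf and (tf, g) not in gt.edge_set and g not in gt.marker_genes
        ]
        n_false = int(round(false_edge_rate * len(rows)))
        picks = rng.choice(len(pool), size=min(n_false, len(pool)), replace=False)
        rows += [pool[i] for i in picks]
    return pd.DataFrame(rows, columns=["tf", "target"])


def planted_gmt(gt: GroundTruth) -> dict[str, set[str]]:
    """Planted regulon target sets as a toy gene-set collection for ORA."""
    return {f"REGULON_{tf}": set(gt.regulon_targets[tf]) for tf in gt.tf_ids}
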