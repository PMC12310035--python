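"""End-to-end orchestration of the comparison workflow.

``run_all`` chains: per-condition preprocessing funnel -> cross-condition
HVG union -> scaling -> multi-run GRN inference -> consensus regulons ->
AUC activity scoring -> subcluster extraction and cross-condition alignment
-> differential regulons -> hurdle differential expression -> DETGs ->
optional over-representation analysis.  Every stage draws its randomness
from seeds derived from ``config.master_seed``, so two runs with the same
inputs and config produce byte-identical outputs.

Contrasts follow the alignment: each matched subcluster pair is compared
across conditions (null under shared programs), and each unique subcluster
is compared against all other cells of its own condition.
"""

from __future__ import annotations

import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from . import aucell, cluster, consensus, differential, enrichment, grn, io, preprocess
from .config import PipelineConfig, derive_seed

logger = logging.getLogger(__name__)

__all__ = ["run_all", "write_outputs"]


def _network_matrices(counts: dict[str, ad.AnnData], tf_list: list[str], config: PipelineConfig):
    """Funnel each condition, form the HVG union, scale the network genes."""
    funnels = {c: preprocess.run_funnel(counts[c], config) for c in sorted(counts)}
    genes_common = None
    for c, f in funnels.items():
        g = set(f["counts"].var_names)
        genes_common = g if genes_common is None else genes_common & g
    combined_counts = ad.concat(
        [f["counts"][:, sorted(genes_common)] for f in funnels.values()], merge="same"
    )
    combined_norm = preprocess.normalize(combined_counts, config.target_sum)
    hv_sets = [f["hvgs"] for f in funnels.values()]
    hv_sets.append(
        preprocess.select_hvgs(
            combined_norm,
            config.hvg_min_mean,
            config.hvg_max_mean,
            config.hvg_min_dispersion,
            config.hvg_n_bins,
        )
    )
    hvg_union = preprocess.union_hvgs(hv_sets)
    # regulators must be present as predictor columns in the network matrix
    tfs_present = [t for t in tf_list if t in combined_norm.var_names]
    network_genes = preprocess.union_hvgs([hvg_union, tfs_present])
    scaled = {}
    for c, f in funnels.items():
        genes = [g for g in network_genes if g in f["normalized"].var_names]
        scaled[c] = preprocess.scale(f["normalized"], genes=genes)
    return funnels, hvg_union, network_genes, scaled


def run_all(
    counts: dict[str, ad.AnnData],
    tf_list: list[str],
    config: PipelineConfig | None = None,
    prior: pd.DataFrame | None = None,
    gene_sets: dict[str, set[str]] | None = None,
    curated_tfs: set[str] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full two-condition comparison.

    ``counts`` maps exactly two condition labels to raw count matrices; the
    lexicographically first label is the reference condition (its regulon
    ordering and subcluster count ``k_condition_a`` apply).  Returns a dict
    of all intermediate and final artifacts; writes them under ``out_dir``
    when given.
    """
    config = config or PipelineConfig()
    conds = sorted(counts)
    if len(conds) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {conds}")
    ca, cb = conds

    funnels, hvg_union, network_genes, scaled = _network_matrices(counts, tf_list, config)

    hp = grn.GBMHyperparams(
        max_trees=config.grn_max_trees,
        learning_rate=config.grn_learning_rate,
        subsample=config.grn_subsample,
        max_features=config.grn_max_features,
        early_stop_window=config.grn_early_stop_window,
    )
    runs, cons = {}, {}
    for c in conds:
        runs[c] = grn.run_multi(
            scaled[c],
            tf_list,
            prior,
            n_runs=config.n_runs,
            master_seed=derive_seed(config.master_seed, f"grn_{c}"),
            hyperparams=hp,
            top_n_targets=config.module_top_n_targets,
            importance_quantile=config.module_importance_quantile,
            prior_min_size=config.prior_min_regulon_size,
            prior_permissive=config.prior_permissive,
        )
        regs = consensus.aggregate_runs(runs[c], condition=c)
        if config.min_target_frequency > 0:
            for r in regs:
                r.table = r.table[r.table["frequency"] >= config.min_target_frequency]
        cons[c] = consensus.attach_expression_stats(regs, funnels[c]["normalized"])
    common_tfs, unique_a, unique_b = consensus.common_and_unique(cons[ca], cons[cb])

    # activity scoring ranks the full post-filter transcriptome of each cell
    auc = {}
    for c in conds:
        norm = funnels[c]["normalized"]
        auc[c] = aucell.score_matrix(
            norm,
            cons[c],
            top_fraction=config.auc_top_fraction,
            seed=derive_seed(config.master_seed, f"auc_{c}"),
        )
    auc_common = {c: auc[c][[t for t in common_tfs if t in auc[c].columns]] for c in conds}
    std = {c: aucell.standardize_auc(auc_common[c]) for c in conds}

    # reference-condition regulon ordering; B's columns follow it
    regulon_dend = cluster.hcluster(std[ca], axis="columns")
    std_a = std[ca][regulon_dend.leaf_order]
    std_b = cluster.reorder_by_reference(std[cb], regulon_dend.leaf_order)

    cell_dend = {ca: cluster.hcluster(std_a, axis="rows"), cb: cluster.hcluster(std_b, axis="rows")}
    k = {ca: config.k_condition_a, cb: config.k_condition_b}
    labels = {c: cluster.cut_subclusters(cell_dend[c], k[c]) for c in conds}

    embedding = cluster.embed_joint(
        auc_common[ca],
        auc_common[cb],
        n_pcs=config.n_pcs,
        n_neighbors=config.n_neighbors,
        min_dist=config.min_dist,
        seed=derive_seed(config.master_seed, "umap"),
    )
    alignment = cluster.align_by_centroids(
        embedding, labels[ca], labels[cb], unique_margin=config.unique_margin
    )

    # contrasts: matched pairs across conditions; uniques vs rest within
    contrasts: list[dict] = []
    for la, lb in alignment.matches:
        contrasts.append(
            {
                "name": f"{ca}{la}_vs_{cb}{lb}",
                "kind": "matched",
                "cells_1": list(labels[ca].index[labels[ca] == int(la)]),
                "cells_2": list(labels[cb].index[labels[cb] == int(lb)]),
            }
        )
    for cond, uniq in ((ca, alignment.unique_a), (cb, alignment.unique_b)):
        for lu in uniq:
            members = labels[cond] == int(lu)
            contrasts.append(
                {
                    "name": f"{cond}{lu}_vs_rest_{cond}",
                    "kind": "unique",
                    "cells_1": list(labels[cond].index[members]),
                    "cells_2": list(labels[cond].index[~members]),
                }
            )

    auc_all = pd.concat([auc_common[ca], auc_common[cb]], axis=0)
    diffreg_frames = []
    for ct in contrasts:
        d = differential.differential_regulons(
            auc_all,
            ct["cells_1"],
            ct["cells_2"],
            alpha=config.alpha,
            min_abs_auc_diff=config.min_abs_auc_diff,
        )
        d.insert(0, "contrast", ct["name"])
        d.insert(1, "kind", ct["kind"])
        diffreg_frames.append(d)
    diffreg = (
        pd.concat(diffreg_frames, ignore_index=True)
        if diffreg_frames
        else pd.DataFrame()
    )

    # hurdle DE on the normalized matrices (full post-filter gene space)
    norm_all = ad.concat([funnels[c]["normalized"] for c in conds], merge="same")
    dge_frames, detg_frames = [], []
    cons_a_by_tf = {r.tf: r for r in cons[ca]}
    for ct in contrasts:
        lab = pd.Series("g2", index=ct["cells_1"] + ct["cells_2"])
        lab.loc[ct["cells_1"]] = "g1"
        sub = norm_all[lab.index].copy()
        stats = differential.hurdle_de_test(sub, lab)
        degs = differential.deg_filter(
            stats,
            lfc_threshold=config.lfc_threshold,
            min_pct=config.min_pct,
            min_diff_pct=config.min_diff_pct,
            alpha=config.alpha,
            m=sub.n_vars,
        )
        sig_tfs = (
            diffreg.loc[
                (diffreg["contrast"] == ct["name"]) & diffreg["significant"], "regulon"
            ]
            if len(diffreg)
            else []
        )
        for tf in sig_tfs:
            if tf in cons_a_by_tf:
                detg = differential.extract_detgs(cons_a_by_tf[tf], degs)
                if len(detg):
                    detg.insert(0, "contrast", ct["name"])
                    detg_frames.append(detg)
        degs.insert(0, "contrast", ct["name"])
        dge_frames.append(degs)
    dge = pd.concat(dge_frames, ignore_index=True) if dge_frames else pd.DataFrame()
    detgs = pd.concat(detg_frames, ignore_index=True) if detg_frames else pd.DataFrame()

    enrich_tables = {}
    if gene_sets:
        for ct in contrasts:
            genes = (
                list(dge.loc[dge["contrast"] == ct["name"], "gene"]) if len(dge) else []
            )
            if genes:
                enrich_tables[ct["name"]] = enrichment.ora(
                    genes,
                    gene_sets,
                    universe=list(norm_all.var_names),
                    alpha=config.alpha,
                    min_term_size=config.ora_min_term_size,
                    max_term_size=config.ora_max_term_size,
                )

    validation = None
    if curated_tfs is not None:
        detected = {r.tf for c in conds for r in cons[c]}
        background = set(t for t in tf_list if t in set(norm_all.var_names)) | detected
        validation = consensus.tf_overlap_validation(detected, set(curated_tfs), background)

    results = {
        "config": config,
        "conditions": conds,
        "funnels": funnels,
        "hvg_union": hvg_union,
        "network_genes": network_genes,
        "scaled": scaled,
        "runs": runs,
        "consensus": cons,
        "common_tfs": common_tfs,
        "unique_tfs": {ca: unique_a, cb: unique_b},
        "auc": auc,
        "auc_common": auc_common,
        "std_auc": {ca: std_a, cb: std_b},
        "regulon_dendrogram": regulon_dend,
        "cell_dendrograms": cell_dend,
        "labels": labels,
        "embedding": embedding,
        "alignment": alignment,
        "contrasts": contrasts,
        "diffreg": diffreg,
        "dge": dge,
        "detgs": detgs,
        "enrichment": enrich_tables,
        "validation": validation,
    }
    if out_dir is not None:
        write_outputs(results, out_dir)
    return results


def write_outputs(results: dict, out_dir: str | Path) -> None:
    """Write the primary artifacts as TSV/JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results["config"].to_yaml(out / "config.yaml")
    ca, cb = results["conditions"]
    for c in results["conditions"]:
        io.write_tsv_matrix(results["funnels"][c]["funnel"].set_index("stage"), out / f"funnel_{c}.tsv")
        io.write_gene_list(results["funnels"][c]["hvgs"], out / f"hvgs_{c}.txt")
        io.write_tsv_matrix(
            consensus.consensus_to_frame(results["consensus"][c]).set_index("tf"),
            out / f"regulons_{c}.tsv",
        )
        io.write_tsv_matrix(results["auc"][c], out / f"auc_{c}.tsv")
        io.write_tsv_matrix(results["std_auc"][c], out / f"std_auc_{c}.tsv")
        results["labels"][c].rename("subcluster").rename_axis("cell").to_frame().to_csv(
            out / f"labels_{c}.tsv", sep="\t"
        )
        io.write_json(results["cell_dendrograms"][c].to_json_dict(), out / f"dendrogram_cells_{c}.json")
    io.write_gene_list(results["hvg_union"], out / "hvgs_union.txt")
    io.write_gene_list(results["network_genes"], out / "network_genes.txt")
    io.write_json(
        {
            "common": results["common_tfs"],
            f"unique_{ca}": results["unique_tfs"][ca],
            f"unique_{cb}": results["unique_tfs"][cb],
        },
        out / "common_unique_tfs.json",
    )
    io.write_json(results["regulon_dendrogram"].to_json_dict(), out / "dendrogram_regulons.json")
    io.write_tsv_matrix(results["embedding"], out / "embedding.tsv")
    io.write_json(results["alignment"].to_json_dict(), out / "alignment.json")
    if len(results["diffreg"]):
        io.write_tsv_matrix(results["diffreg"].set_index("contrast"), out / "diffreg.tsv")
    if len(results["dge"]):
        io.write_tsv_matrix(results["dge"].set_index("contrast"), out / "dge.tsv")
    if len(results["detgs"]):
        io.write_tsv_matrix(results["detgs"].set_index("contrast"), out / "detgs.tsv")
    for name, table in results["enrichment"].items():
        io.write_tsv_matrix(table.set_index("term"), out / f"enrichment_{name}.tsv")
    if results["validation"] is not None:
        io.write_json(results["validation"], out / "tf_validation.json")
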