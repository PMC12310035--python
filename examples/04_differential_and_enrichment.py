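"""Test regulons and genes for differential activity between cell groups.

Differential regulons: Wilcoxon rank-sum on raw AUC scores with BH
correction and an absolute mean-difference gate of 0.15.  Differential
expression: a two-part hurdle model (detection + positive expression) with
the log2 fold-change / detection-fraction gates and Bonferroni correction.
DETGs are a regulon's targets that are also differentially expressed, and
over-representation of a gene list in a gene-set collection is scored by
the hypergeometric upper tail.
"""

import pandas as pd

from regulonkit.aucell import score_matrix
from regulonkit.config import derive_seed
from regulonkit.differential import (
    deg_filter,
    differential_regulons,
    extract_detgs,
    hurdle_de_test,
)
from regulonkit.enrichment import ora
from regulonkit.evaluate import truth_regulons
from regulonkit.preprocess import normalize
from regulonkit.simulate import make_ground_truth, planted_gmt, simulate_counts

seed = 0
# moderate baseline + strong effect: activity separates the AUC scores and
# detection fractions still track activity, so the min.diff.pct gate and the
# |dAUC| gate both have signal to work with
gt = make_ground_truth(8, 10, 3, include_unique=True, activity_effect=6.0,
                       seed=seed, n_housekeeping=600, baseline_mean=2.0)
mats = simulate_counts(gt, cells_per_subcluster=100, seed=derive_seed(seed, "counts"))
norm = normalize(mats["A"], target_sum=2500.0)
auc = score_matrix(norm, truth_regulons(gt), 0.05, seed=1)

# contrast: the unique subcluster vs all other cells of the same condition
sub = pd.Series({c: gt.cell_assignments[c][1] for c in norm.obs_names})
cells_u = list(sub.index[sub == "U1"])
cells_rest = list(sub.index[sub != "U1"])

dreg = differential_regulons(auc, cells_u, cells_rest, alpha=0.05, min_abs_auc_diff=0.15)
print("differential regulons (U1 vs rest):")
print(dreg[["regulon", "delta_auc", "p_adj", "significant"]].round(4).to_string(index=False))
print(f"-> {int(dreg['significant'].sum())} regulons pass FDR<0.05 and |dAUC|>0.15\n")

labels = sub.map(lambda s: "U1" if s == "U1" else "rest")
stats = hurdle_de_test(norm, labels)
degs = deg_filter(stats, lfc_threshold=0.585, min_pct=0.15, min_diff_pct=0.15,
                  alpha=0.05, m=norm.n_vars)
print(f"{len(degs)} DEGs pass all four gates (|log2FC|>=0.585, pct gates, Bonferroni).")

sig_tf = dreg.loc[dreg["significant"], "regulon"].iloc[0]
reg = next(r for r in truth_regulons(gt) if r.tf == sig_tf)
detg = extract_detgs(reg, degs)
print(f"DETGs of regulon {sig_tf}: {len(detg)} of its {len(reg.targets)} targets are DEGs")

res = ora(list(degs["gene"]), planted_gmt(gt), universe=list(norm.var_names), alpha=0.05)
top = res.nsmallest(3, "p_adj")
print("\ntop enriched planted gene sets among the DEGs (hypergeometric, BH):")
print(top[["term", "k", "K", "p_adj", "significant"]].to_string(index=False))
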