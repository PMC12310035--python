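"""Simulate a two-condition single-cell dataset and run the QC funnel.

The generator plants TF regulons and subcluster activity programs, spikes in
a few contaminating cells expressing exclusion markers (Ptprc/Adgre1 style),
and the preprocessing funnel removes low-quality cells, unannotated-symbol
genes, contaminants and rare genes before normalization and HVG selection.
"""

from regulonkit.config import PipelineConfig, derive_seed
from regulonkit.preprocess import run_funnel
from regulonkit.simulate import make_ground_truth, simulate_counts, spike_contaminants

seed = 0
gt = make_ground_truth(
    n_tfs=6, targets_per_tf=8, n_shared_subclusters=3,
    include_unique=True, activity_effect=4.0, seed=seed, n_housekeeping=600,
)
mats = simulate_counts(gt, cells_per_subcluster=60, seed=derive_seed(seed, "counts"))
spiked = spike_contaminants(mats["A"], gt, fraction=0.02, seed=derive_seed(seed, "spike"))
print(f"condition A: {spiked.n_obs} cells x {spiked.n_vars} genes "
      f"({len(gt.contaminant_cells)} spiked contaminants)")

cfg = PipelineConfig(target_sum=2000.0)  # target near the library size of this small gene space
res = run_funnel(spiked, cfg)
print("\nFunnel (cells x genes after each stage):")
print(res["funnel"].to_string(index=False))
print(f"\n{len(res['hvgs'])} highly variable genes selected.")
# The contaminant removal stage should have removed exactly the spiked cells:
survivors = set(res["counts"].obs_names)
print("spiked contaminants remaining after the funnel:",
      len(survivors & gt.contaminant_cells))
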