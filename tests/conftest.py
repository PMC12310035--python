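"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from regulonkit.config import PipelineConfig, derive_seed
from regulonkit.preprocess import normalize, scale
from regulonkit.simulate import make_ground_truth, prior_table, simulate_counts


@pytest.fixture(scope="session")
def mini_gt():
    """Small planted design: 6 TFs x 8 targets, 3 shared + 1 unique subcluster."""
    return make_ground_truth(
        n_tfs=6,
        targets_per_tf=8,
        n_shared_subclusters=3,
        include_unique=True,
        activity_effect=4.0,
        seed=11,
        n_housekeeping=120,
    )


@pytest.fixture(scope="session")
def mini_counts(mini_gt):
    return simulate_counts(mini_gt, cells_per_subcluster=80, seed=derive_seed(11, "counts"))


@pytest.fixture(scope="session")
def mini_scaled(mini_gt, mini_counts):
    """Scaled planted-gene matrix of condition A, ready for GRN inference."""
    norm = normalize(mini_counts["A"])
    genes = mini_gt.tf_ids + [g for t in mini_gt.tf_ids for g in mini_gt.regulon_targets[t]]
    return scale(norm, genes=genes)


@pytest.fixture(scope="session")
def mini_runs(mini_gt, mini_scaled):
    """Five pruned GRN runs on the mini dataset (shared: inference is the
    slow stage, so stability/consensus tests reuse one computation)."""
    from regulonkit.grn import run_multi

    return run_multi(
        mini_scaled,
        mini_gt.tf_ids,
        prior_table(mini_gt),
        n_runs=5,
        master_seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def default_config():
    return PipelineConfig()
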