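"""Pipeline configuration and deterministic seed derivation.

All numeric thresholds of the workflow live in :class:`PipelineConfig` so a
single YAML file fully determines a run.  Every source of randomness in the
pipeline is derived from ``master_seed`` through :func:`derive_seed`; no stage
reads global random state.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "derive_seed"]


@dataclass
class PipelineConfig:
    """Every tunable of the workflow, with the defaults used throughout.

    QC boundary semantics are literal: a cell is kept iff detected features
    > ``min_features_exclusive``, mitochondrial fraction
    < ``max_mito_fraction`` and total UMIs < ``max_umi_exclusive``.
    """

    # QC (cell-level, first-stage)
    min_features_exclusive: int = 200
    max_mito_fraction: float = 0.10
    max_umi_exclusive: int = 30_000
    # cell/gene filter (second-stage)
    min_genes: int = 300
    max_genes: int = 5000
    min_cells_per_gene: int = 5
    # gene symbol hygiene / contamination
    unannotated_suffixes: list[str] = field(default_factory=lambda: ["Rik"])
    unannotated_prefixes: list[str] = field(default_factory=lambda: ["Gm"])
    contaminant_markers: list[str] = field(default_factory=lambda: ["Ptprc", "Adgre1"])
    mito_prefix: str = "mt-"
    # normalization / HVG
    target_sum: float = 10_000.0
    hvg_min_mean: float = 0.0125
    hvg_max_mean: float = 3.5
    hvg_min_dispersion: float = 0.45
    hvg_n_bins: int = 20
    # network inference
    n_runs: int = 20
    grn_max_trees: int = 500
    grn_learning_rate: float = 0.01
    grn_subsample: float = 0.9
    grn_max_features: float = 0.1
    grn_early_stop_window: int = 25
    module_top_n_targets: int = 50
    module_importance_quantile: float = 0.0
    prior_min_regulon_size: int = 3
    prior_permissive: bool = False
    min_target_frequency: float = 0.0
    # activity scoring
    auc_top_fraction: float = 0.05
    # clustering / alignment
    linkage: str = "average"
    distance: str = "correlation"
    k_condition_a: int = 4
    k_condition_b: int = 3
    n_pcs: int = 15
    n_neighbors: int = 30
    min_dist: float = 0.3
    unique_margin: float = 1.5
    # differential testing
    alpha: float = 0.05
    min_abs_auc_diff: float = 0.15
    lfc_threshold: float = 0.585
    min_pct: float = 0.15
    min_diff_pct: float = 0.15
    lfc_pseudocount: float = 1.0
    # enrichment
    ora_min_term_size: int = 3
    ora_max_term_size: int = 2000
    # reproducibility
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "max_mito_fraction",
            "module_importance_quantile",
            "min_target_frequency",
            "auc_top_fraction",
            "alpha",
            "min_pct",
            "min_diff_pct",
            "grn_subsample",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "min_features_exclusive",
            "max_umi_exclusive",
            "min_genes",
            "max_genes",
            "min_cells_per_gene",
        ):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_runs < 1:
            raise ValueError(f"n_runs must be >= 1, got {self.n_runs}")

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path: str | Path | None = None) -> str:
        """Serialize to YAML; round-trips bit-exactly through from_yaml."""
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def derive_seed(master_seed: int, stage_name: str, run_index: int = 0) -> int:
    """Deterministic per-stage seed below 2**31.

    Hash-based so distinct ``(stage_name, run_index)`` pairs collide only
    with negligible probability; identical inputs always map to the same
    seed.
    """
    if run_index < 0:
        raise ValueError(f"run_index must be >= 0, got {run_index}")
    payload = f"{master_seed}:{stage_name}:{run_index}".encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
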