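"""Pipeline configuration.

All tunables for the profiling pipeline live in a single :class:`PipelineConfig`
dataclass; a YAML file mirroring the field names is the only external entry
point.  Every source of randomness in the pipeline is derived from ``rng_seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """Tunable parameters of the hospital-profiling pipeline.

    Attributes
    ----------
    row_completeness_min, col_completeness_min:
        Minimum fraction of observed cells an entity (row) / measure (column)
        must have to survive filtering.  Rows are filtered first.
    clip_sd:
        Standardized values are clamped to ``[-clip_sd, +clip_sd]``.
    n_reference_profiles:
        Number of leaf groups of the entity partition tree used as reference
        profiles; must be a power of two (the tree is dyadic).
    n_neighborhoods:
        Number of heat sources / neighborhoods on the final embedding.
    n_profile_neighbors:
        Neighborhood profiles average the source plus this many nearest
        neighbors (10 -> 11 entities per profile).
    embed_dims:
        Dimension of the final diffusion-map embedding.
    n_coupled_iterations:
        Maximum rounds of the alternating measure/entity co-organization.
    n_eigenvectors:
        Number of nontrivial eigenpairs retained in each diffusion geometry.
    diffusion_time:
        Diffusion time ``t`` in the diffusion distance and map coordinates.
    emd_level_decay:
        Exponential level decay ``alpha`` of the tree-EMD node weights
        ``2**(-alpha * level) * |node| / n``.
    ensemble_size, hidden_widths:
        Size and architecture of the score-regression network ensemble.
    kernel_bandwidth_rule:
        ``"median_sq_dist"`` (self-tuning: epsilon = median squared pairwise
        distance) or ``"fixed"`` (use ``kernel_bandwidth_fixed``).
    standardize_method:
        ``"zscore"`` (mean 0 / SD 1) or ``"rank_normal"`` (rank-based inverse
        normal transform).
    measure_tree_depth:
        Depth of the dyadic partition tree built on the measures for the
        tree-approximate earth mover's distance.
    domain_margin:
        Half-width (in SD units) of the "near average" band used when
        classifying domain-level performance.
    early_stop_ari:
        Coupled iterations stop early once consecutive entity-leaf partitions
        agree at this adjusted Rand index.
    train_epochs, learning_rate:
        Full-batch gradient-descent budget for each ensemble member.
    propagate_bandwidth:
        Kernel bandwidth for score propagation; ``None`` selects the median
        squared diffusion distance to the nearest reference representative
        (a local smoothing scale).
    rng_seed:
        Master seed; all stage seeds are derived from it.
    """

    row_completeness_min: float = 0.90
    col_completeness_min: float = 0.90
    clip_sd: float = 4.0
    n_reference_profiles: int = 32
    n_neighborhoods: int = 16
    n_profile_neighbors: int = 10
    embed_dims: int = 3
    n_coupled_iterations: int = 3
    n_eigenvectors: int = 8
    diffusion_time: float = 1.0
    emd_level_decay: float = 0.5
    ensemble_size: int = 10
    hidden_widths: list[int] = field(default_factory=lambda: [32, 16])
    kernel_bandwidth_rule: str = "median_sq_dist"
    kernel_bandwidth_fixed: float = 1.0
    standardize_method: str = "zscore"
    measure_tree_depth: int = 5
    domain_margin: float = 0.1
    early_stop_ari: float = 0.99
    train_epochs: int = 500
    learning_rate: float = 0.05
    propagate_bandwidth: Optional[float] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        d = self.n_reference_profiles
        if d < 2 or d & (d - 1):
            raise ValueError(
                f"n_reference_profiles must be a power of two >= 2, got {d}"
            )
        for name in ("row_completeness_min", "col_completeness_min"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.clip_sd <= 0:
            raise ValueError("clip_sd must be positive")
        if self.kernel_bandwidth_rule not in ("median_sq_dist", "fixed"):
            raise ValueError(
                f"unknown kernel_bandwidth_rule {self.kernel_bandwidth_rule!r}"
            )
        if self.standardize_method not in ("zscore", "rank_normal"):
            raise ValueError(
                f"unknown standardize_method {self.standardize_method!r}"
            )

    @property
    def tree_depth(self) -> int:
        """Entity-tree depth implied by ``n_reference_profiles`` (log2)."""
        return self.n_reference_profiles.bit_length() - 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML file whose keys mirror :class:`PipelineConfig` fields."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
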