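"""Reference performance profiles and expert score handling.

The entity partition tree, cut at its deepest level, yields 32 leaf groups by
default.  The mean standardized profile of each group is an *illustrative
performance profile* — a reference point that domain experts rank on a 1-10
scale (10 = top performance).  The consolidated expert scores are then
propagated to every entity by kernel regression (Nadaraya-Watson) in the
entity diffusion geometry, giving each entity a rough quality score used to
supervise the embedding stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .coupled_geometry import DiffusionGeometry, PartitionTree
from .preprocessing import QualityMatrix

__all__ = [
    "ReferenceProfile",
    "ReferenceProfileSet",
    "extract_reference_profiles",
    "load_expert_scores",
    "validate_expert_scores",
    "consolidate_scores",
    "ScoreConsolidation",
    "propagate_scores",
]

SCORE_MIN, SCORE_MAX = 1.0, 10.0
DISCREPANCY_RANGE = 2.0  # rater range above this flags a leaf for review


@dataclass(frozen=True)
class ReferenceProfile:
    leaf_id: str
    entity_ids: list[str]
    centroid: np.ndarray
    representative_id: str
    expert_score: Optional[float] = None


@dataclass(frozen=True)
class ReferenceProfileSet:
    """The leaf-group centroids (reference points) with optional expert scores."""

    profiles: list[ReferenceProfile]
    measure_ids: list[str]

    @property
    def leaf_ids(self) -> list[str]:
        return [p.leaf_id for p in self.profiles]

    def centroids(self) -> np.ndarray:
        return np.vstack([p.centroid for p in self.profiles])

    def scores(self) -> dict[str, float]:
        out = {}
        for p in self.profiles:
            if p.expert_score is None:
                raise ValueError(f"reference profile {p.leaf_id} has no expert score")
            out[p.leaf_id] = p.expert_score
        return out

    def with_scores(self, scores: dict[str, float]) -> "ReferenceProfileSet":
        missing = [p.leaf_id for p in self.profiles if p.leaf_id not in scores]
        if missing:
            raise ValueError(f"unscored leaf(s): {missing}")
        profiles = [replace(p, expert_score=float(scores[p.leaf_id])) for p in self.profiles]
        return ReferenceProfileSet(profiles, self.measure_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.centroids(), index=self.leaf_ids, columns=self.measure_ids)
        df.insert(0, "n_members", [len(p.entity_ids) for p in self.profiles])
        df.insert(1, "representative", [p.representative_id for p in self.profiles])
        if all(p.expert_score is not None for p in self.profiles):
            df.insert(2, "expert_score", [p.expert_score for p in self.profiles])
        df.index.name = "leaf_id"
        return df


def extract_reference_profiles(
    tree: PartitionTree, m: QualityMatrix, cfg: PipelineConfig
) -> ReferenceProfileSet:
    """One profile per tree leaf: the arithmetic mean of the members'
    standardized profiles.  The leaf *representative* is the member entity
    nearest (Euclidean) to the centroid; it embodies the reference point when
    distances to reference points are needed."""
    leaves = tree.leaves()
    if len(leaves) < cfg.n_reference_profiles:
        raise ValueError(
            f"tree has {len(leaves)} leaves; {cfg.n_reference_profiles} configured"
        )
    if list(tree.ids) != list(m.entity_ids):
        raise ValueError("tree ids do not match matrix entities")
    width = len(str(len(leaves) - 1))
    profiles = []
    for i, leaf in enumerate(leaves):
        members = np.sort(leaf.members)
        rows = m.values[members]
        centroid = rows.mean(axis=0)
        rep = members[int(np.argmin(np.linalg.norm(rows - centroid, axis=1)))]
        profiles.append(
            ReferenceProfile(
                leaf_id=f"L{i:0{width}d}",
                entity_ids=[m.entity_ids[k] for k in members],
                centroid=centroid,
                representative_id=m.entity_ids[rep],
            )
        )
    return ReferenceProfileSet(profiles, list(m.measure_ids))


# ---------------------------------------------------------------------------
# expert scores


def validate_expert_scores(files: dict[str, dict[str, float]]) -> None:
    for rater, scores in files.items():
        for leaf_id, s in scores.items():
            if not SCORE_MIN <= float(s) <= SCORE_MAX:
                raise ValueError(
                    f"score {s} for leaf {leaf_id} by rater {rater!r} outside "
                    f"[{SCORE_MIN:g}, {SCORE_MAX:g}]"
                )


def load_expert_scores(path: str | Path) -> dict[str, dict[str, float]]:
    """Read an expert score file: JSON ``{"rater": {"leaf_id": score}}``."""
    with open(path) as fh:
        data = json.load(fh)
    files = {str(r): {str(k): float(v) for k, v in d.items()} for r, d in data.items()}
    validate_expert_scores(files)
    return files


@dataclass(frozen=True)
class ScoreConsolidation:
    scores: dict[str, float]
    discrepancies: dict[str, float]  # leaf -> rater range, where range > 2

    def report(self) -> str:
        if not self.discrepancies:
            return "No rater discrepancies (all ranges <= 2)."
        lines = ["Leaves with rater range > 2 (would trigger expert re-ranking):"]
        for leaf, rng in sorted(self.discrepancies.items()):
            lines.append(f"  {leaf}: range {rng:g}")
        return "\n".join(lines)


def consolidate_scores(
    files: list[dict[str, dict[str, float]]] | dict[str, dict[str, float]],
    leaf_ids: Optional[list[str]] = None,
) -> ScoreConsolidation:
    """Median score per leaf across raters, plus a discrepancy report naming
    leaves whose rater range exceeds 2 (the stand-in for the experts'
    re-ranking loop)."""
    if isinstance(files, dict):
        files = [files]
    merged: dict[str, dict[str, float]] = {}
    for f in files:
        validate_expert_scores(f)
        for rater, scores in f.items():
            merged.setdefault(rater, {}).update(
                {k: float(v) for k, v in scores.items()}
            )
    by_leaf: dict[str, list[float]] = {}
    for scores in merged.values():
        for leaf_id, s in scores.items():
            by_leaf.setdefault(leaf_id, []).append(s)
    if leaf_ids is not None:
        unscored = [l for l in leaf_ids if l not in by_leaf]
        if unscored:
            raise ValueError(f"unscored leaf(s): {unscored}")
    consolidated = {l: float(np.median(v)) for l, v in sorted(by_leaf.items())}
    discrepancies = {
        l: float(np.ptp(v))
        for l, v in sorted(by_leaf.items())
        if np.ptp(v) > DISCREPANCY_RANGE
    }
    return ScoreConsolidation(consolidated, discrepancies)


# ---------------------------------------------------------------------------
# propagation


def propagate_scores(
    refs: ReferenceProfileSet,
    g: DiffusionGeometry,
    bandwidth: Optional[float] = None,
) -> dict[str, float]:
    """Nadaraya-Watson propagation of expert scores to every entity.

    Each reference point is embodied by its leaf representative; entity i
    gets score sum_j w_ij s_j / sum_j w_ij with
    w_ij = exp(-d(i, rep_j)^2 / bandwidth) where d is the diffusion distance.
    The default bandwidth is the median squared diffusion distance to the
    *nearest* (distinct) representative — a local scale, so each entity is
    scored mainly by the few reference points around it rather than smoothed
    toward the global mean.
    """
    scores = refs.scores()
    index = {e: k for k, e in enumerate(g.ids)}
    rep_idx = []
    for p in refs.profiles:
        if p.representative_id not in index:
            raise ValueError(f"representative {p.representative_id} not in geometry")
        rep_idx.append(index[p.representative_id])
    coords = g.coordinates()
    diff = coords[:, None, :] - coords[None, rep_idx, :]
    sq = np.einsum("ijk,ijk->ij", diff, diff)
    if bandwidth is None:
        # per-entity squared distance to the nearest distinct representative
        masked = np.where(sq > 0, sq, np.inf)
        nearest = masked.min(axis=1)
        nearest = nearest[np.isfinite(nearest)]
        bandwidth = float(np.median(nearest)) if nearest.size else 1.0
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    w = np.exp(-sq / bandwidth)
    totals = w.sum(axis=1)
    if (totals == 0).any():
        bad = [g.ids[i] for i in np.flatnonzero(totals == 0)]
        raise ValueError(
            f"all kernel weights underflow for {bad[:5]}; increase the bandwidth"
        )
    s = np.array([scores[p.leaf_id] for p in refs.profiles])
    propagated = (w @ s) / totals
    return {e: float(v) for e, v in zip(g.ids, propagated)}
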