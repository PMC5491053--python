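"""Heat-diffusion neighborhoods on the embedding and their profiles.

Simultaneous heat diffusion from k sources covers a point cloud fastest when
the maximal distance from any point to its nearest source is smallest, so
the "fastest-spreading configuration of heat sources" is found as a k-center
(minimax cover) problem on embedding distances: greedy farthest-point
seeding followed by swap-based local search.  A literal heat-propagation
simulation (kernel powers) is available as a slow cross-check of the
cover-time surrogate.  Every entity is assigned to its nearest source;
neighborhoods are labeled A, B, ... in descending size.  Each neighborhood's
profile is the average *standardized performance* (not embedding
coordinates) of its central entity and the 10 nearest neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import QualityMatrix
from .ssl_embedding import EmbeddingResult

__all__ = [
    "NeighborhoodAssignment",
    "place_sources",
    "heat_cover_time",
    "assign_neighborhoods",
    "neighborhood_profile",
    "classify_domain_performance",
    "DomainClassification",
]


def _letter_label(i: int) -> str:
    """0 -> A, 1 -> B, ..., 25 -> Z, 26 -> AA, ..."""
    label = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        label = chr(ord("A") + r) + label
    return label


@dataclass
class NeighborhoodAssignment:
    """Partition of the entities induced by the heat sources."""

    labels: dict[str, str]
    sources: list[str]
    source_of_label: dict[str, str]
    objective: float
    sizes: dict[str, int]
    distance_to_source: dict[str, float]
    profiles: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        src = set(self.sources)
        rows = [
            {
                "entity_id": e,
                "label": lab,
                "is_source": e in src,
                "distance_to_source": self.distance_to_source[e],
            }
            for e, lab in self.labels.items()
        ]
        return pd.DataFrame(rows)


def _cover_objective(D: np.ndarray, sources: np.ndarray) -> float:
    return float(D[:, sources].min(axis=1).max())


def place_sources(e: EmbeddingResult, k: int, seed: int) -> list[str]:
    """Minimax (k-center) source placement on embedding distances.

    Greedy farthest-point seeding from a seeded start, then single-swap local
    search until no swap lowers the cover radius.  Deterministic given seed.
    """
    n = len(e.entity_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} entities")
    if k < 1:
        raise ValueError("k must be >= 1")
    D = e.distance_matrix()
    rng = np.random.default_rng(seed)
    chosen = [int(rng.integers(n))]
    mind = D[:, chosen[0]].copy()
    while len(chosen) < k:
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        np.minimum(mind, D[:, nxt], out=mind)

    sources = np.array(sorted(chosen))
    improved = True
    while improved:
        improved = False
        cur = _cover_objective(D, sources)
        best_obj, best_swap = cur, None
        Dsub = D[:, sources]
        order = np.argsort(Dsub, axis=1)
        min1 = Dsub[np.arange(n), order[:, 0]]
        min2 = Dsub[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        for si in range(k):
            rest = np.where(order[:, 0] == si, min2, min1)
            outside = np.setdiff1d(np.arange(n), sources)
            for c in outside:
                obj = float(np.minimum(rest, D[:, c]).max())
                if obj < best_obj - 1e-12:
                    best_obj, best_swap = obj, (si, c)
        if best_swap is not None:
            si, c = best_swap
            sources[si] = c
            sources = np.sort(sources)
            improved = True
    return [e.entity_ids[i] for i in sources]


def heat_cover_time(
    e: EmbeddingResult, sources: list[str], bandwidth: float, threshold: float = 1e-3
) -> int:
    """Slow verification mode: literal heat propagation by kernel powers.

    Heat starts at the sources; each step multiplies by the row-normalized
    heat kernel.  Returns the number of steps until every entity holds at
    least ``threshold`` heat.
    """
    D = e.distance_matrix()
    W = np.exp(-(D**2) / bandwidth)
    P = W / W.sum(axis=1, keepdims=True)
    idx = [e.entity_ids.index(s) for s in sources]
    heat = np.zeros(len(e.entity_ids))
    heat[idx] = 1.0 / len(idx)
    for step in range(1, 10_000):
        heat = heat @ P
        if heat.min() >= threshold:
            return step
    raise RuntimeError("heat did not cover the map within 10000 steps")


def assign_neighborhoods(
    e: EmbeddingResult, sources: list[str], k: int
) -> NeighborhoodAssignment:
    """Assign every entity to its nearest source (ties to the earliest source
    in canonical id order); label neighborhoods A, B, ... in descending size,
    ties broken by source id."""
    if len(set(sources)) != len(sources):
        raise ValueError("duplicate sources")
    if len(sources) != k:
        raise ValueError(f"expected {k} sources, got {len(sources)}")
    index = {eid: i for i, eid in enumerate(e.entity_ids)}
    canonical = sorted(sources)
    src_idx = np.array([index[s] for s in canonical])
    D = e.distance_matrix()[:, src_idx]
    nearest = D.argmin(axis=1)  # ties -> first (earliest in canonical order)
    dist = D[np.arange(len(e.entity_ids)), nearest]

    counts = np.bincount(nearest, minlength=k)
    rank = sorted(range(k), key=lambda j: (-counts[j], canonical[j]))
    label_of_src = {j: _letter_label(r) for r, j in enumerate(rank)}
    labels = {
        eid: label_of_src[int(nearest[i])] for i, eid in enumerate(e.entity_ids)
    }
    sizes = {label_of_src[j]: int(counts[j]) for j in range(k)}
    source_of_label = {label_of_src[j]: canonical[j] for j in range(k)}
    return NeighborhoodAssignment(
        labels=labels,
        sources=canonical,
        source_of_label=source_of_label,
        objective=float(dist.max()),
        sizes=sizes,
        distance_to_source={eid: float(dist[index[eid]]) for eid in e.entity_ids},
    )


def neighborhood_profile(
    m: QualityMatrix, e: EmbeddingResult, source: str, n_neighbors: int
) -> np.ndarray:
    """Mean standardized profile of the source entity and its ``n_neighbors``
    nearest entities in embedding distance."""
    if list(m.entity_ids) != list(e.entity_ids):
        raise ValueError("matrix and embedding entities differ")
    n = len(m.entity_ids)
    if n_neighbors + 1 > n:
        raise ValueError(
            f"requested {n_neighbors + 1} entities but only {n} available"
        )
    si = m.entity_ids.index(source)
    d = np.linalg.norm(e.coordinates - e.coordinates[si], axis=1)
    d[si] = -np.inf  # the source itself always included first
    order = np.argsort(d, kind="stable")
    members = order[: n_neighbors + 1]
    return m.values[members].mean(axis=0)


@dataclass(frozen=True)
class DomainClassification:
    """Per-domain verdicts plus measures beyond +/-1 SD."""

    by_domain: dict[str, str]
    particularly_good: list[str]  # measures > +1 SD
    particularly_poor: list[str]  # measures < -1 SD


def classify_domain_performance(
    profile: np.ndarray, meta: pd.DataFrame, margin: float = 0.1
) -> DomainClassification:
    """Classify a neighborhood profile within each quality domain.

    good: most measures above +margin; poor: most below -margin;
    average: most within the margin band; otherwise mixed.  Measures more
    than 1 SD above/below average are flagged as particularly good/poor.
    """
    if len(profile) != len(meta):
        raise ValueError("profile length does not match measure metadata")
    vals = pd.Series(np.asarray(profile, dtype=float), index=meta.index)
    by_domain: dict[str, str] = {}
    for domain, group in meta.groupby("domain", sort=True):
        v = vals.loc[group.index]
        if len(v) == 0:
            raise ValueError(f"empty domain {domain!r}")
        f_good = (v > margin).mean()
        f_poor = (v < -margin).mean()
        f_avg = (v.abs() <= margin).mean()
        if f_good > 0.5:
            verdict = "good"
        elif f_poor > 0.5:
            verdict = "poor"
        elif f_avg > 0.5:
            verdict = "average"
        else:
            verdict = "mixed"
        by_domain[str(domain)] = verdict
    return DomainClassification(
        by_domain=by_domain,
        particularly_good=list(vals.index[vals > 1.0]),
        particularly_poor=list(vals.index[vals < -1.0]),
    )
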