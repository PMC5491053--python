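"""Synthetic entity-by-measure data with planted structure.

The generator emulates the structure of a public hospital quality-measure
release: ~84 measures grouped into 7 domains (process, experience, value,
safety, surgery, readmission, mortality), entities falling into a number of
performance clusters with distinct domain-level signatures, within-domain
correlation induced by a shared entity factor, Gaussian measurement noise,
missing-completely-at-random cells, and a block of poorly reporting entities
that the 90% completeness filter should remove.  Expert scores for the
reference profiles can be auto-generated from the planted truth with a
value-based-purchasing-style domain weighting, so the whole pipeline runs
without a human in the loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .preprocessing import DOMAINS
from .reference_profiles import ReferenceProfileSet

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "SyntheticDataset",
    "generate",
    "score_centroids",
    "auto_expert_scores",
    "DOMAIN_WEIGHTS",
]

# Relative domain importance used for auto-generated expert scores, mimicking
# value-based-purchasing weighting: outcomes (mortality, readmission) weigh
# most, then patient experience, then process and the remaining domains.
DOMAIN_WEIGHTS = {
    "mortality": 3.0,
    "readmission": 3.0,
    "experience": 2.0,
    "process": 1.0,
    "value": 1.0,
    "safety": 1.0,
    "surgery": 1.0,
}

# Domains whose raw measures are rates where lower is better.
_LOWER_BETTER_DOMAINS = {"value", "safety", "surgery", "readmission", "mortality"}


@dataclass
class SyntheticSpec:
    """Shape and signal parameters of the planted-structure generator."""

    n_entities: int = 600
    n_measures: int = 84
    n_domains: int = 7
    measures_per_domain: Optional[list[int]] = None
    n_clusters: int = 16
    domain_effect_scale: float = 1.5
    entity_factor_sd: float = 0.5
    noise_sd: float = 0.7
    missing_rate: float = 0.03
    n_low_completeness_entities: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.measures_per_domain is None:
            base, extra = divmod(self.n_measures, self.n_domains)
            self.measures_per_domain = [
                base + (1 if d < extra else 0) for d in range(self.n_domains)
            ]
        if sum(self.measures_per_domain) != self.n_measures:
            raise ValueError("measures_per_domain must sum to n_measures")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_clusters > self.n_entities:
            raise ValueError("more clusters than entities")
        if self.n_low_completeness_entities > self.n_entities:
            raise ValueError("more low-completeness entities than entities")
        if self.n_domains > len(DOMAINS):
            raise ValueError(f"at most {len(DOMAINS)} domains supported")


@dataclass
class GroundTruth:
    """Planted structure: cluster labels, domain effects, measure map."""

    cluster_labels: dict[str, int]
    domain_effects: np.ndarray  # (n_clusters, n_domains)
    measure_domains: dict[str, str]
    measure_directions: dict[str, str]
    cluster_quality: dict[int, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "cluster_labels": self.cluster_labels,
                "domain_effects": self.domain_effects.tolist(),
                "measure_domains": self.measure_domains,
                "measure_directions": self.measure_directions,
                "cluster_quality": {str(k): v for k, v in self.cluster_quality.items()},
            },
            indent=1,
        )


@dataclass
class SyntheticDataset:
    matrix: pd.DataFrame  # entity_id + one column per measure; NaN = missing
    meta: pd.DataFrame  # measure_id, domain, direction
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "matrix": outdir / "matrix.csv",
            "meta": outdir / "measure_meta.csv",
            "truth": outdir / "ground_truth.json",
        }
        self.matrix.to_csv(paths["matrix"], index=False)
        self.meta.to_csv(paths["meta"], index=False)
        paths["truth"].write_text(self.truth.to_json())
        return paths


def _planted_quality(effects: np.ndarray, domains: list[str]) -> np.ndarray:
    """Weighted domain-effect mean per cluster: the planted quality ordering."""
    w = np.array([DOMAIN_WEIGHTS[d] for d in domains])
    return effects @ w / w.sum()


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a planted-structure dataset.

    Cluster c has a domain-effect mu[c, d] ~ N(0, domain_effect_scale^2); the
    value of measure j (domain d, loading l_j ~ U(0.5, 1)) for entity i in
    cluster c is mu[c, d] + l_j * u[i, d] + N(0, noise_sd^2) with an
    entity-by-domain factor u[i, d] ~ N(0, entity_factor_sd^2) that induces
    within-domain correlation between measures (~0.2 at the defaults,
    matching the moderate inter-measure correlations of real quality data);
    measures of different domains are correlated only through the cluster
    effects.  Lower-is-better measures are sign-flipped in the raw file.
    MCAR missingness is applied at ``missing_rate``; the first
    ``n_low_completeness_entities`` entities additionally lose >10% of their
    cells so the row-completeness filter has something to drop.
    """
    rng = np.random.default_rng(spec.seed)
    domains = list(DOMAINS[: spec.n_domains])
    measure_domains: list[str] = []
    for d, count in zip(domains, spec.measures_per_domain):
        measure_domains.extend([d] * count)

    entity_ids = [f"H{i:04d}" for i in range(spec.n_entities)]
    measure_ids = [
        f"{dom[:4].upper()}_{j:03d}" for j, dom in enumerate(measure_domains)
    ]
    directions = [
        "lower_better" if dom in _LOWER_BETTER_DOMAINS else "higher_better"
        for dom in measure_domains
    ]

    clusters = rng.integers(0, spec.n_clusters, size=spec.n_entities)
    # guarantee every cluster is populated
    clusters[: spec.n_clusters] = np.arange(spec.n_clusters)
    effects = rng.normal(0.0, spec.domain_effect_scale, (spec.n_clusters, spec.n_domains))
    loadings = rng.uniform(0.5, 1.0, spec.n_measures)
    u = rng.normal(0.0, spec.entity_factor_sd, (spec.n_entities, spec.n_domains))
    dom_idx = np.array([domains.index(d) for d in measure_domains])

    values = (
        effects[clusters][:, dom_idx]
        + u[:, dom_idx] * loadings[None, :]
        + rng.normal(0.0, spec.noise_sd, (spec.n_entities, spec.n_measures))
    )
    flip = np.array([d == "lower_better" for d in directions])
    values[:, flip] = -values[:, flip]

    mask = rng.random(values.shape) < spec.missing_rate
    if spec.n_low_completeness_entities:
        # delete a random 15% of each poorly reporting entity's cells
        k = max(int(np.ceil(0.15 * spec.n_measures)), int(0.10 * spec.n_measures) + 1)
        for i in range(spec.n_low_completeness_entities):
            cols = rng.choice(spec.n_measures, size=k, replace=False)
            mask[i, cols] = True
    values = values.copy()
    values[mask] = np.nan

    matrix = pd.DataFrame(values, columns=measure_ids)
    matrix.insert(0, "entity_id", entity_ids)
    meta = pd.DataFrame(
        {"measure_id": measure_ids, "domain": measure_domains, "direction": directions}
    )
    quality = _planted_quality(effects, domains)
    truth = GroundTruth(
        cluster_labels={e: int(c) for e, c in zip(entity_ids, clusters)},
        domain_effects=effects,
        measure_domains=dict(zip(measure_ids, measure_domains)),
        measure_directions=dict(zip(measure_ids, directions)),
        cluster_quality={c: float(q) for c, q in enumerate(quality)},
    )
    return SyntheticDataset(matrix, meta, truth)


def score_centroids(
    centroids: np.ndarray, measure_domains: list[str], seed: int = 0
) -> dict[int, tuple[int, list[int]]]:
    """Map centroid weighted-domain means affinely onto the 1-10 scale and
    simulate three raters with +/-1 jitter.  Returns, per centroid index,
    (base score, the three rater scores)."""
    w = np.array([DOMAIN_WEIGHTS[d] for d in measure_domains])
    q = centroids @ w / w.sum()
    lo, hi = float(q.min()), float(q.max())
    if hi == lo:
        base = np.full(len(q), 5.5)
    else:
        base = 1.0 + 9.0 * (q - lo) / (hi - lo)
    rng = np.random.default_rng(seed)
    out: dict[int, tuple[int, list[int]]] = {}
    for i, b in enumerate(base):
        b_round = int(np.clip(np.rint(b), 1, 10))
        raters = [
            int(np.clip(b_round + jit, 1, 10))
            for jit in rng.integers(-1, 2, size=3)
        ]
        out[i] = (b_round, raters)
    return out


def auto_expert_scores(
    gt: GroundTruth, refs: ReferenceProfileSet, seed: int = 0
) -> dict[str, dict[str, float]]:
    """Auto-generated expert score file for the reference profiles: three
    simulated raters scoring each centroid's weighted domain mean on 1-10."""
    measure_domains = [gt.measure_domains[mid] for mid in refs.measure_ids]
    scored = score_centroids(refs.centroids(), measure_domains, seed)
    files: dict[str, dict[str, float]] = {
        f"rater{r + 1}": {} for r in range(3)
    }
    for i, p in enumerate(refs.profiles):
        _, raters = scored[i]
        for r, s in enumerate(raters):
            files[f"rater{r + 1}"][p.leaf_id] = float(s)
    return files
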