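"""End-to-end orchestration, reports, and the run manifest.

``run_core`` executes the whole method in memory:

    preprocess -> coupled co-organization -> reference profiles
    -> expert scores (file or auto) -> score propagation
    -> ensemble features -> heat kernel -> 3-D diffusion map
    -> heat-source neighborhoods -> neighborhood profiles & reports

``run_pipeline`` wraps it with file I/O: it reads the matrix / metadata /
score files, writes every stage's exports into an output directory, and
records a manifest (config snapshot, input digests, stage timings, outputs,
seed) sufficient to reproduce the run byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import PipelineConfig, save_config
from .coupled_geometry import CoupledResult, run_coupled_iterations
from .neighborhoods import (
    DomainClassification,
    NeighborhoodAssignment,
    assign_neighborhoods,
    classify_domain_performance,
    neighborhood_profile,
    place_sources,
)
from .preprocessing import QualityMatrix, load_matrix, preprocess
from .reference_profiles import (
    ReferenceProfileSet,
    ScoreConsolidation,
    consolidate_scores,
    extract_reference_profiles,
    load_expert_scores,
    propagate_scores,
)
from .ssl_embedding import (
    EmbeddingResult,
    FeatureSet,
    diffusion_map,
    feature_heat_kernel,
    train_ensemble,
)
from .synthetic import GroundTruth, auto_expert_scores, score_centroids

logger = logging.getLogger("hospmap")

__all__ = ["PipelineResult", "RunManifest", "run_core", "run_pipeline", "report_neighborhoods"]


@dataclass
class PipelineResult:
    """All in-memory artifacts of one pipeline run."""

    cfg: PipelineConfig
    matrix: QualityMatrix  # preprocessed
    coupled: CoupledResult
    references: ReferenceProfileSet  # scored
    consolidation: ScoreConsolidation
    expert_files: dict[str, dict[str, float]]
    propagated: dict[str, float]
    features: FeatureSet
    embedding: EmbeddingResult
    assignment: NeighborhoodAssignment
    classifications: dict[str, DomainClassification]
    timings: dict[str, float] = field(default_factory=dict)


def _resolve_scores(
    refs: ReferenceProfileSet,
    m: QualityMatrix,
    cfg: PipelineConfig,
    expert_files: Optional[dict[str, dict[str, float]]],
    truth: Optional[GroundTruth],
    auto_scores: bool,
) -> dict[str, dict[str, float]]:
    if expert_files is not None:
        return expert_files
    if not auto_scores:
        raise ValueError(
            "no expert score file provided and auto-scoring disabled; "
            "cannot propagate scores"
        )
    if truth is not None:
        return auto_expert_scores(truth, refs, cfg.rng_seed + 9001)
    # no planted truth: weight by the measure metadata's domains
    domains = [str(m.meta.loc[mid, "domain"]) for mid in refs.measure_ids]
    scored = score_centroids(refs.centroids(), domains, cfg.rng_seed + 9001)
    files: dict[str, dict[str, float]] = {f"rater{r+1}": {} for r in range(3)}
    for i, p in enumerate(refs.profiles):
        for r, s in enumerate(scored[i][1]):
            files[f"rater{r+1}"][p.leaf_id] = float(s)
    return files


def run_core(
    raw: QualityMatrix,
    cfg: PipelineConfig,
    expert_files: Optional[dict[str, dict[str, float]]] = None,
    truth: Optional[GroundTruth] = None,
    auto_scores: bool = False,
) -> PipelineResult:
    """Run the full method on an in-memory raw matrix."""
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage: %s", name)
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = time.perf_counter() - timings[name]

    s = stage("preprocess")
    m = preprocess(raw, cfg)
    done(s)
    logger.info("matrix after filters: %d entities x %d measures", *m.shape)

    s = stage("coupled_geometry")
    coupled = run_coupled_iterations(m, cfg)
    done(s)
    if coupled.ari_log:
        logger.info("entity-tree agreement per round: %s",
                    [round(a, 3) for a in coupled.ari_log])

    s = stage("reference_profiles")
    refs = extract_reference_profiles(coupled.entity_tree, m, cfg)
    done(s)

    s = stage("expert_scores")
    files = _resolve_scores(refs, m, cfg, expert_files, truth, auto_scores)
    consolidation = consolidate_scores(files, leaf_ids=refs.leaf_ids)
    refs = refs.with_scores(consolidation.scores)
    done(s)
    if consolidation.discrepancies:
        logger.warning(consolidation.report())

    s = stage("propagate")
    propagated = propagate_scores(refs, coupled.entity_geometry, cfg.propagate_bandwidth)
    done(s)

    s = stage("train_ensemble")
    features = train_ensemble(m, propagated, cfg)
    done(s)

    s = stage("diffusion_map")
    kernel = feature_heat_kernel(features, cfg)
    embedding = diffusion_map(kernel, cfg)
    done(s)

    s = stage("neighborhoods")
    sources = place_sources(embedding, cfg.n_neighborhoods, cfg.rng_seed + 4001)
    assignment = assign_neighborhoods(embedding, sources, cfg.n_neighborhoods)
    classifications: dict[str, DomainClassification] = {}
    for label in sorted(assignment.sizes):
        prof = neighborhood_profile(
            m, embedding, assignment.source_of_label[label], cfg.n_profile_neighbors
        )
        assignment.profiles[label] = prof
        classifications[label] = classify_domain_performance(
            prof, m.meta, cfg.domain_margin
        )
    done(s)

    return PipelineResult(
        cfg=cfg,
        matrix=m,
        coupled=coupled,
        references=refs,
        consolidation=consolidation,
        expert_files=files,
        propagated=propagated,
        features=features,
        embedding=embedding,
        assignment=assignment,
        classifications=classifications,
        timings=timings,
    )


# ---------------------------------------------------------------------------
# reports


def report_neighborhoods(
    assignment: NeighborhoodAssignment,
    classifications: dict[str, DomainClassification],
    meta: pd.DataFrame,
) -> tuple[pd.DataFrame, str]:
    """Per-neighborhood table (size, source, per-domain verdicts, flagged
    measures) as a DataFrame plus a Markdown rendering."""
    domains = sorted(meta["domain"].unique())
    rows = []
    for label in sorted(assignment.sizes):
        cls = classifications[label]
        row = {
            "label": label,
            "n": assignment.sizes[label],
            "source": assignment.source_of_label[label],
        }
        for d in domains:
            row[d] = cls.by_domain.get(d, "")
        row["particularly_good"] = ";".join(cls.particularly_good)
        row["particularly_poor"] = ";".join(cls.particularly_poor)
        rows.append(row)
    df = pd.DataFrame(rows)

    lines = ["# Neighborhood performance profiles", ""]
    header = ["label", "n", *domains]
    lines.append("| " + " | ".join(header) + " |")
    lines.append("|" + "---|" * len(header))
    for _, r in df.iterrows():
        lines.append(
            "| " + " | ".join(str(r[h]) for h in header) + " |"
        )
    lines.append("")
    for _, r in df.iterrows():
        extra = []
        if r["particularly_good"]:
            extra.append(f">+1 SD: {r['particularly_good']}")
        if r["particularly_poor"]:
            extra.append(f"<-1 SD: {r['particularly_poor']}")
        if extra:
            lines.append(f"- **{r['label']}**: " + "; ".join(extra))
    return df, "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# file-based run


@dataclass
class RunManifest:
    config: dict
    inputs: dict[str, str]  # path -> sha256
    seed: int
    n_entities: int
    n_measures: int
    n_reference_profiles: int
    n_neighborhoods: int
    stage_seconds: dict[str, float]
    outputs: list[str]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, default=str)


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(
    matrix_path: str | Path,
    meta_path: str | Path,
    cfg: PipelineConfig,
    outdir: str | Path,
    expert_scores_path: Optional[str | Path] = None,
    truth: Optional[GroundTruth] = None,
    auto_scores: bool = False,
) -> RunManifest:
    """Run the pipeline from files and write every stage's exports."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    raw = load_matrix(matrix_path, meta_path)
    expert_files = (
        load_expert_scores(expert_scores_path) if expert_scores_path else None
    )
    res = run_core(raw, cfg, expert_files, truth, auto_scores)

    outputs: list[Path] = []

    def write(name: str, text_or_df) -> None:
        p = outdir / name
        if isinstance(text_or_df, pd.DataFrame):
            text_or_df.to_csv(p, index=False)
        else:
            p.write_text(text_or_df)
        outputs.append(p)

    pre = res.matrix.to_frame().reset_index(names="entity_id")
    write("preprocessed.csv", pre)
    write("measure_tree.json", res.coupled.measure_tree.to_json())
    write("entity_tree.json", res.coupled.entity_tree.to_json())
    write("entity_tree.csv", res.coupled.entity_tree.to_frame())
    write("reference_profiles.csv", res.references.to_frame().reset_index())
    write("expert_scores_used.json", json.dumps(res.expert_files, indent=1))
    write(
        "consolidated_scores.json",
        json.dumps(
            {"scores": res.consolidation.scores,
             "discrepancies": res.consolidation.discrepancies},
            indent=1,
        ),
    )
    write(
        "propagated_scores.csv",
        pd.DataFrame(
            sorted(res.propagated.items()), columns=["entity_id", "score"]
        ),
    )
    emb = pd.DataFrame(
        res.embedding.coordinates,
        columns=[f"dim{i+1}" for i in range(res.embedding.coordinates.shape[1])],
    )
    emb.insert(0, "entity_id", res.embedding.entity_ids)
    write("embedding.csv", emb)
    write("assignment.csv", res.assignment.to_frame())
    prof = pd.DataFrame(
        {lab: res.assignment.profiles[lab] for lab in sorted(assignment_labels(res))},
        index=res.matrix.measure_ids,
    ).T
    prof.index.name = "label"
    write("neighborhood_profiles.csv", prof.reset_index())
    table, md = report_neighborhoods(res.assignment, res.classifications, res.matrix.meta)
    write("neighborhood_report.csv", table)
    write("neighborhood_report.md", md)
    save_config(res.cfg, outdir / "config_snapshot.yaml")
    outputs.append(outdir / "config_snapshot.yaml")

    inputs = {str(matrix_path): _digest(matrix_path), str(meta_path): _digest(meta_path)}
    if expert_scores_path:
        inputs[str(expert_scores_path)] = _digest(expert_scores_path)
    manifest = RunManifest(
        config=res.cfg.to_dict(),
        inputs=inputs,
        seed=res.cfg.rng_seed,
        n_entities=res.matrix.shape[0],
        n_measures=res.matrix.shape[1],
        n_reference_profiles=len(res.references.profiles),
        n_neighborhoods=len(res.assignment.sizes),
        stage_seconds={k: round(v, 3) for k, v in res.timings.items()},
        outputs=[str(p) for p in outputs],
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def assignment_labels(res: PipelineResult) -> list[str]:
    return sorted(res.assignment.sizes)
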