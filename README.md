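# hospmap

Semi-supervised diffusion-geometry profiling of hospitals across many
quality measures.

## The problem

Public reporting programs describe each hospital with dozens of quality
measures spanning several domains — care processes, patient experience,
value, safety, surgical quality, readmission and mortality.  A hospital's
**performance profile** (its vector of standardized scores across all
measures) carries far more information than any single composite rating,
but profiles are hard to compare: two "average" hospitals may be average in
completely different ways.  `hospmap` organizes an entity-by-measure matrix
so that hospitals with similar profiles sit close together, produces a
quality-oriented 3-D map of all hospitals, and identifies commonly occurring
performance profiles ("neighborhoods"), each characterized across every
measurement domain.

The package is written for health-services and outcomes researchers, but
nothing in it is specific to hospitals: any entity-by-measure panel with
domain-tagged, direction-tagged columns fits.

## The method

1. **Preprocessing** — entities reporting <90% of measures are dropped, then
   measures reported by <90% of the remaining entities; adverse ("lower is
   better") measures are negated so positive always means better; each
   measure is z-scored (mean 0, SD 1) and winsorized at ±4 SD; the ≤10%
   residual missing cells are set to the column mean (0).
2. **Coupled co-organization** — a diffusion geometry is built on the
   *measures* from cosine affinities; a binary partition tree on its
   low-frequency eigenvectors groups related measures; a tree-approximate
   earth mover's distance (EMD) over that tree,

   d(x, y) = Σ_nodes 2^(−α·level) · (|node|/p) · |mean_node(x) − mean_node(y)|,

   gives a metric on the *entities*, whose own diffusion geometry and tree
   feed back to re-organize the measures.  Iterating builds successively
   more reliable metrics on both axes.
3. **Reference profiles and expert scores** — the entity tree, refined
   dyadically to 32 leaves, yields 32 *illustrative performance profiles*
   (leaf centroids).  Experts rank these on a 1–10 scale (10 = top); scores
   are consolidated by median with a discrepancy report.  A simulated-rater
   mode scores profiles automatically from value-based-purchasing-style
   domain weights (outcomes > experience > process and the rest).
4. **Score propagation** — Nadaraya–Watson kernel regression in diffusion
   distance spreads the 32 expert scores to every entity ("rough quality
   score").
5. **Supervised embedding** — an ensemble of small tanh networks regresses
   the propagated score from the profile; the concatenated last-hidden-layer
   activations define a learned non-Euclidean metric; a heat kernel
   k(x,y) = exp(−‖feat(x)−feat(y)‖²/ε) on these features, Markov-normalized
   and eigendecomposed, gives the 3-D **diffusion map**, oriented by quality.
6. **Neighborhoods** — the configuration of 16 heat sources that spreads
   fastest (minimax cover radius, a k-center objective) partitions the map
   into neighborhoods labeled A–P by size; each neighborhood's profile is
   the mean standardized profile of its central entity and 10 nearest
   neighbors, classified per domain as good / poor / mixed / average with
   ±1 SD flags for standout measures.

A synthetic-data generator plants cluster structure, domain-level
signatures, within-domain correlation, noise and missingness so the whole
pipeline runs and is testable without any external data.

## Worked example

```bash
hospmap simulate --seed 1 --outdir demo/data
hospmap run-all --matrix demo/data/matrix.csv --meta demo/data/measure_meta.csv \
    --seed 1 --auto-scores --outdir demo/run
```

prints (log lines omitted):

```
580 entities, 84 measures, 32 reference profiles, 16 neighborhoods
manifest: demo/run/manifest.json
```

Twenty of the 600 simulated hospitals report fewer than 90% of the measures
and are filtered out, leaving 580.  The run directory contains the
preprocessed matrix, both partition trees, the 32 reference profiles with
their simulated expert scores, per-hospital propagated scores (here spanning
the full 1.0–10.0 scale), the 3-D embedding, the A–P assignment and the
neighborhood report.  The first lines of `neighborhood_report.csv`:

```
label,n,source,experience,mortality,process,readmission,safety,surgery,value,...
A,94,H0083,good,poor,good,good,poor,good,good,...
B,76,H0023,good,poor,poor,good,good,poor,good,...
```

Neighborhood A holds 94 hospitals whose typical profile is good in most
domains but poor in mortality and safety; B's 76 hospitals pair a good
patient experience with poor process scores — the kind of nuance a single
composite rating hides.  The `particularly_good` / `particularly_poor`
columns flag measures more than 1 SD from the average.

## Layout

- `src/hospmap/preprocessing.py` — loading, filtering, orientation, z-scoring,
  clipping, imputation
- `src/hospmap/coupled_geometry.py` — affinity kernels, diffusion geometry,
  partition trees, tree-EMD, the coupled iteration
- `src/hospmap/reference_profiles.py` — reference profiles, expert-score
  consolidation, kernel-regression propagation
- `src/hospmap/ssl_embedding.py` — network ensemble, feature heat kernel,
  diffusion map
- `src/hospmap/neighborhoods.py` — heat-source placement, assignment,
  profiles, domain classification
- `src/hospmap/synthetic.py` — planted-structure generator and simulated raters
- `src/hospmap/pipeline.py`, `src/hospmap/cli.py` — orchestration, reports,
  manifest, command line

See `docs/methods.md` for the model, parameter meanings, numerical choices
and limitations.
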