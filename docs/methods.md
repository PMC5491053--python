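# Methods

This note documents the model behind `hospmap`, the parameters that matter,
the synthetic-data generator, and the numerical choices made where the
design was genuinely open.

## Data model and preprocessing

The input is an entity-by-measure matrix with missing cells plus per-measure
metadata (domain tag; direction tag `higher_better` / `lower_better`).  The
analysis assumes near-complete data, so rows (entities) with completeness
below `row_completeness_min` (default 0.90) are dropped first, then columns
below `col_completeness_min` (default 0.90) over the surviving rows.  Row
filtering precedes column filtering; the order matters and is fixed.

Adverse measures are negated *before* standardization so that positive
always denotes better care — downstream domain classifications read sign
directly.  Standardization is a per-measure z-score over observed cells
(sample SD, n−1); a rank-based inverse-normal transform (Blom offsets) is
available behind `standardize_method: rank_normal` for heavy-tailed
measures, but z-scoring is the default because the subsequent ±`clip_sd`
(default 4) winsorization is only meaningful on the z scale.  Residual
missing cells are set to 0 — the column mean on the standardized scale — a
neutral choice that preserves column moments; the observed mask is retained
for audit.

## Diffusion geometry

All geometries share one construction: an affinity kernel W (symmetric,
entries in [0,1], unit diagonal) is Markov-normalized, P = D⁻¹W, and
eigendecomposed through the symmetric conjugate D^(−1/2) W D^(−1/2).
Eigenvectors are rescaled to be orthonormal under the stationary
distribution π = deg/Σdeg, which makes the trivial eigenvector the constant
1 and gives the exact identity

    d_t(i,j)² = Σ_l λ_l^(2t) (ψ_l(i) − ψ_l(j))²
              = Σ_k (P^t_ik − P^t_jk)² / π_k          (full spectrum)

so diffusion distances computed from eigenpairs coincide with distances
between Markov rows.  `n_eigenvectors` (default 8) nontrivial pairs are
retained; `diffusion_time` t defaults to 1.  Eigenvector signs are fixed by
making each vector's largest-magnitude entry positive, so runs and plots
are bit-reproducible.

Kernels built from distances use the heat form exp(−d²/ε) with ε from
`kernel_bandwidth_rule`: the median of squared pairwise distances
(self-tuning default) or a fixed value.  If clipping negative cosines (see
below) disconnects the affinity graph — possible when one domain is
uncorrelated with the rest — pipeline-level kernels raise zero off-diagonal
weights to a floor of 1e−6, keeping the walk irreducible without visibly
changing the geometry.  The low-level embedding functions still reject
disconnected kernels, as a guard against malformed inputs.

## Coupled co-organization

Measures are compared by cosine affinity between their standardized
profiles, with negative cosines clipped to 0 (affinities must be
nonnegative; the alternative (1+cos)/2 would put anti-correlated measures at
0.5, erasing the distinction from orthogonal ones).  A binary partition
tree is grown on the measure diffusion coordinates by recursive 2-means
(seeded per node from `rng_seed` plus a hash of the node path).  When a
2-means split degenerates or would strand a child too small to fill its
subtree, the node falls back to a balanced median split on the first
nontrivial eigenvector; this guarantees exactly 2^depth leaves whenever the
point count allows it.

`measure_tree_depth` defaults to 5 (32 leaves, ~2–3 measures each at the
default 84 measures).  The depth governs the granularity of the tree-EMD
below: averaging inside a node suppresses measure-level noise, but a node
that spans several domains averages *away* genuine domain-level signal, so
leaves should be small groups of strongly correlated measures.

The entity metric is a tree-approximate earth mover's distance: nodes are
weighted 2^(−α·level) · |node|/p with `emd_level_decay` α = 0.5, and the
distance is the weighted L1 difference of per-node profile means.  It is a
pseudometric (nonnegative, symmetric, triangle inequality) and, on
normalized mass profiles, orders pairs like exact LP transport with a tree
ground metric.

The coupled loop alternates: measure geometry → measure tree → tree-EMD
entity kernel → entity geometry → entity tree → tree-EMD measure kernel →
… for `n_coupled_iterations` (default 3) rounds, stopping early when
consecutive entity-leaf partitions agree at adjusted Rand ≥
`early_stop_ari` (default 0.99).

## Reference profiles, expert scores, propagation

The entity tree is cut at depth log2(`n_reference_profiles`) (default 32
leaves).  Each leaf's centroid (mean standardized profile of its members)
is a reference profile; the leaf's *representative* is the member nearest
the centroid in Euclidean profile distance and embodies the reference point
wherever a concrete entity is needed.

Expert scores arrive as JSON `{rater: {leaf_id: score}}`, scores in [1,10].
Consolidation takes the per-leaf median across raters and reports leaves
whose rater range exceeds 2 — a mechanical stand-in for an iterative human
re-ranking meeting, chosen so the pipeline runs unattended.  In synthetic
mode three simulated raters score each centroid's weighted domain mean
(weights: mortality = readmission 3, experience 2, process/value/safety/
surgery 1 — an outcomes-heavy hierarchy in the style of value-based
purchasing) mapped affinely onto 1–10, rounded, with ±1 jitter.

Scores propagate to all entities by Nadaraya–Watson regression in diffusion
distance: score(i) = Σ_j w_ij s_j / Σ_j w_ij, w_ij = exp(−d(i, rep_j)²/h).
The default bandwidth h is the **median squared diffusion distance to the
nearest distinct representative**.  A global scale (median over all
entity×representative pairs) was evaluated and rejected: it sits at the
between-group scale, so every entity averages over most of the 32 reference
scores and the propagated field collapses toward the grand mean, destroying
the ranking information the supervision is meant to carry.  The local scale
keeps propagation "rough" — each entity is scored by the few reference
points around it.  Propagated scores are convex combinations of expert
scores (hence within [1,10]) and monotone in any single leaf score.

## Supervised embedding

`ensemble_size` (default 10) networks with tanh hidden layers
(`hidden_widths`, default [32,16]) and a linear output regress the
propagated score from the standardized profile.  Training is full-batch
Adam (`learning_rate` 0.05) for `train_epochs` (default 500) with plateau
early stopping, an L2 weight decay of 1e−3 (smooths the fit between
bootstrap points and measurably improves out-of-sample prediction), and a
standardized target for conditioning.  Members differ by seeded
initialization and bootstrap resampling; every member must end at or below
its initial loss, and training is bit-reproducible from `rng_seed`.  The
trainer is a ~100-line numpy implementation because the contract requires
access to the loss at initialization and exact determinism of refits.

The entity features are the concatenated last-hidden-layer activations of
all members (entities × 16·10 by default).  A heat kernel on these features
followed by the diffusion-map construction yields `embed_dims` (default 3)
coordinates λ_l^t ψ_l.  Coordinates are mean-centered — a translation that
leaves all pairwise distances unchanged — so the cloud is origin-centered
for plotting and the centroid-zero invariant holds exactly.

## Neighborhoods

Heat applied simultaneously at k sources covers a point cloud fastest when
the maximal distance from any point to its nearest source is minimal, so
source placement is solved as a k-center problem on embedding distances:
greedy farthest-point seeding from a seeded start, then single-swap local
search to a local (on small instances verified global) optimum.  A literal
heat-propagation simulation (`heat_cover_time`, kernel powers) is provided
as a slow cross-check of the surrogate.  Entities join their nearest source
(ties to the canonically first source), and labels A, B, … are assigned in
descending neighborhood size — the letters are descriptive only.

A neighborhood's profile is the mean *standardized profile* (not embedding
coordinates) of its source and the `n_profile_neighbors` (default 10)
nearest entities in the map.  Per domain the profile is classified good /
poor / average / mixed by majority of measures above +m, below −m, or
within ±m, with `domain_margin` m = 0.1 SD; measures beyond ±1 SD are
flagged as particularly good/poor.

## Synthetic data

The generator emulates the structure of a public hospital quality release:
`n_measures` 84 in `n_domains` 7 domains, `n_entities` 600, `n_clusters` 16
planted performance archetypes.  Cluster c has domain effects
μ_cd ~ N(0, `domain_effect_scale`² = 1.5²); measure j in domain d for
entity i in cluster c is

    x_ij = μ_{c(i),d(j)} + l_j·u_{i,d(j)} + ε_ij,
    l_j ~ U(0.5, 1),  u_{i,d} ~ N(0, `entity_factor_sd`² = 0.5²),
    ε_ij ~ N(0, `noise_sd`² = 0.7²)

The entity-by-domain factor u induces within-domain correlation between
measures (~0.2 at the defaults, the moderate level seen in real
quality-measure panels) while keeping idiosyncratic domain deviations
subordinate to the planted archetypes; domains are correlated only through
the cluster effects.  Adverse-domain measures (value, safety, surgery,
readmission, mortality) are sign-flipped in the raw file and tagged
`lower_better`.  Cells are deleted MCAR at `missing_rate` 0.03, and
`n_low_completeness_entities` 20 entities lose 15% of their cells to
exercise the row filter.  Planted cluster quality is the
domain-weight-averaged effect, used both for simulated expert scores and as
the ground truth for recovery checks.

What the generator does **not** emulate: real marginal distributions,
measure-specific scales and skew, informative (non-MCAR) missingness,
measure redundancy within a domain beyond a single shared factor, and
hospital covariates (size, region, teaching status).  Passing recovery
tests on this generator shows the pipeline preserves planted geometric and
ordinal structure at realistic noise; it does not certify behavior under
informative missingness or non-Gaussian tails.

## Problem sizes and runtime

Default runs use the 600×84 synthetic release (~580 entities after
filtering); a full pipeline run takes a few seconds on one CPU.  Recovery
and stability checks use 240-entity variants and 5 seeds.  Exact-EMD and
exhaustive k-center cross-checks run at n ≤ 12 where enumeration is
feasible.

## Known limitations

- **Low-dimensional projection merges fine structure.**  With 16 planted
  clusters at the default noise, the 3-D map (and the 8 stored
  eigenvectors) cannot hold all 15 between-cluster contrasts; clusters that
  differ only in fine eigen-directions overlap in the map, and neighborhood
  recovery of planted labels tops out around adjusted Rand ~0.6.  Recovery
  is essentially complete when cluster separation is large relative to
  within-cluster spread (≥6×).  On real data, where profiles form a
  continuum rather than discrete clusters, this is the intended behavior of
  a 3-D visualization, not a defect — but quantitative cluster recovery at
  tight separation needs more dimensions.
- The tree-EMD level weighting (2^(−α·level)) emphasizes coarse nodes, as
  an EMD approximation should; as a *discriminative* metric it underweights
  fine detail relative to plain Euclidean distance on profiles.
- The expert-scoring stand-in replaces an iterative human reconciliation
  with a median plus a discrepancy report; the 1–10 integer scale also
  forces ties between archetypes of similar quality.
- k-center placement is a surrogate for literal heat-diffusion cover time;
  the two agree in ranking on separated clouds but are not identical
  objectives.
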