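"""Coupled diffusion co-organization of measures and entities.

The matrix is organized along both axes in alternation: a cosine-affinity
diffusion geometry is built on the measures, a binary partition tree on its
low-frequency eigenvectors groups related measures, and a tree-approximate
earth mover's distance (EMD) over that tree gives a metric on the entities;
the entity geometry and tree then feed back to re-organize the measures.
Each round builds a successively more reliable metric on each axis.

Diffusion geometry follows the standard construction: the affinity kernel is
Markov-normalized, its eigenpairs are taken through the symmetric conjugate,
and the eigenvectors are scaled so they are orthonormal under the stationary
distribution (the trivial eigenvector is the constant 1).  With that scaling
the diffusion distance

    d_t(i, j)^2 = sum_l  lambda_l^(2t) * (psi_l(i) - psi_l(j))^2

over nontrivial pairs equals, exactly for the full spectrum, the weighted
L2 distance between rows of the t-step Markov matrix.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.sparse import csgraph, csr_matrix
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .config import PipelineConfig
from .preprocessing import QualityMatrix

__all__ = [
    "AffinityKernel",
    "DiffusionGeometry",
    "TreeNode",
    "PartitionTree",
    "cosine_affinity",
    "diffusion_embed",
    "build_partition_tree",
    "tree_emd_distance",
    "tree_emd_affinity",
    "run_coupled_iterations",
    "CoupledResult",
    "bandwidth_from_rule",
]


# ---------------------------------------------------------------------------
# kernels


@dataclass(frozen=True)
class AffinityKernel:
    """Symmetric nonnegative affinity matrix with unit diagonal."""

    ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = self.weights
        if w.shape != (len(self.ids), len(self.ids)):
            raise ValueError("weights shape does not match ids")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("kernel not symmetric")
        if w.min() < 0 or w.max() > 1 + 1e-12:
            raise ValueError("kernel entries must lie in [0, 1]")
        if not np.all(w.diagonal() == 1.0):
            raise ValueError("kernel diagonal must be 1")


def bandwidth_from_rule(sq_dists: np.ndarray, cfg: PipelineConfig) -> float:
    """Heat-kernel bandwidth epsilon: median squared pairwise distance
    (self-tuning) or the fixed config value."""
    if cfg.kernel_bandwidth_rule == "fixed":
        return cfg.kernel_bandwidth_fixed
    eps = float(np.median(sq_dists))
    if eps == 0.0:
        raise ValueError("zero kernel bandwidth: all points coincide")
    return eps


def ensure_connected(k: AffinityKernel, floor: float = 1e-6) -> AffinityKernel:
    """If the kernel graph is disconnected, raise every zero off-diagonal
    weight to ``floor`` so the random walk is irreducible.  The floor is far
    below any data-driven affinity, so geometry is unchanged in practice;
    connected kernels are returned as-is."""
    n_comp, _ = csgraph.connected_components(
        csr_matrix(k.weights > 0), directed=False
    )
    if n_comp == 1:
        return k
    w = k.weights.copy()
    w[w == 0] = floor
    np.fill_diagonal(w, 1.0)
    return AffinityKernel(list(k.ids), w)


def cosine_affinity(m: QualityMatrix, axis: str = "measures") -> AffinityKernel:
    """Cosine affinity between measure profiles (columns) or entity profiles
    (rows), with negative cosines clipped to 0 and unit diagonal."""
    if axis == "measures":
        X, ids = m.values.T, m.measure_ids
    elif axis == "entities":
        X, ids = m.values, m.entity_ids
    else:
        raise ValueError(f"axis must be 'measures' or 'entities', got {axis!r}")
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        bad = [ids[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"zero-norm profile(s): {bad}")
    unit = X / norms[:, None]
    w = np.clip(unit @ unit.T, 0.0, 1.0)
    np.fill_diagonal(w, 1.0)
    w = (w + w.T) / 2.0
    return AffinityKernel(list(ids), w)


# ---------------------------------------------------------------------------
# diffusion geometry


@dataclass(frozen=True)
class DiffusionGeometry:
    """Eigenpairs of a Markov-normalized kernel plus a diffusion-distance
    accessor.

    ``eigenvalues`` are sorted descending with leading value 1;
    ``eigenvectors`` holds the matching columns, scaled to be orthonormal
    under the kernel's stationary distribution (leading column constant 1).
    """

    ids: list[str]
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    diffusion_time: float = 1.0

    def __post_init__(self) -> None:
        if abs(self.eigenvalues[0] - 1.0) > 1e-8:
            raise ValueError("leading eigenvalue must be 1")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def n_points(self) -> int:
        return len(self.ids)

    def coordinates(self, n_dims: Optional[int] = None) -> np.ndarray:
        """Diffusion coordinates lambda_l^t * psi_l over nontrivial pairs."""
        lam = self.eigenvalues[1:]
        psi = self.eigenvectors[:, 1:]
        if n_dims is not None:
            lam, psi = lam[:n_dims], psi[:, :n_dims]
        return psi * np.abs(lam) ** self.diffusion_time

    def distance_matrix(self) -> np.ndarray:
        c = self.coordinates()
        d = cdist(c, c)
        np.fill_diagonal(d, 0.0)
        return d

    def diffusion_distance(self, i: int, j: int) -> float:
        c = self.coordinates()
        return float(np.linalg.norm(c[i] - c[j]))


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector signs: largest-magnitude entry positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        k = int(np.argmax(np.abs(out[:, j])))
        if out[k, j] < 0:
            out[:, j] = -out[:, j]
    return out


def diffusion_embed(k: AffinityKernel, cfg: PipelineConfig) -> DiffusionGeometry:
    """Markov-normalize the kernel and eigendecompose via the symmetric
    conjugate; keep the trivial pair plus the top ``cfg.n_eigenvectors``
    nontrivial pairs."""
    w = k.weights
    n = w.shape[0]
    n_comp, labels = csgraph.connected_components(csr_matrix(w > 0), directed=False)
    if n_comp > 1:
        sizes = sorted(np.bincount(labels).tolist(), reverse=True)
        raise ValueError(f"kernel graph is disconnected (component sizes {sizes})")
    deg = w.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    sym = inv_sqrt[:, None] * w * inv_sqrt[None, :]
    vals, vecs = np.linalg.eigh((sym + sym.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # scale so eigenvectors are orthonormal under pi = deg / sum(deg);
    # the trivial eigenvector becomes the constant 1
    psi = vecs * inv_sqrt[:, None] * np.sqrt(deg.sum())
    psi = _fix_signs(psi)
    n_keep = min(cfg.n_eigenvectors + 1, n)
    vals = np.clip(vals[:n_keep], -1.0, 1.0)
    vals[0] = 1.0
    return DiffusionGeometry(list(k.ids), vals, psi[:, :n_keep], cfg.diffusion_time)


# ---------------------------------------------------------------------------
# partition trees


@dataclass
class TreeNode:
    """A node of a dyadic partition tree: member indices, level, 0/2 children."""

    members: np.ndarray
    level: int
    node_id: str = ""
    children: Optional[tuple["TreeNode", "TreeNode"]] = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class PartitionTree:
    """Binary dyadic partition tree over a set of identified points."""

    ids: list[str]
    root: TreeNode
    depth: int

    def iter_nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if node.children is not None:
                stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.iter_nodes() if n.is_leaf]

    def leaf_labels(self) -> np.ndarray:
        """Integer leaf index (in leaf order) for every point."""
        labels = np.empty(len(self.ids), dtype=int)
        for i, leaf in enumerate(self.leaves()):
            labels[leaf.members] = i
        return labels

    def to_json(self) -> str:
        def node_dict(n: TreeNode) -> dict:
            d = {
                "node_id": n.node_id,
                "level": n.level,
                "members": [self.ids[i] for i in np.sort(n.members)],
            }
            if n.children is not None:
                d["children"] = [node_dict(c) for c in n.children]
            return d

        return json.dumps({"depth": self.depth, "root": node_dict(self.root)}, indent=1)

    def to_frame(self) -> pd.DataFrame:
        """Flat table: id, leaf_id, and the root-to-leaf path string."""
        rows = []
        for li, leaf in enumerate(self.leaves()):
            for i in np.sort(leaf.members):
                rows.append({"id": self.ids[i], "leaf": li, "path": leaf.node_id})
        return pd.DataFrame(rows)


def _node_seed(base_seed: int, node_id: str) -> int:
    return (base_seed + zlib.crc32(node_id.encode())) % (2**31)


def _split_members(
    members: np.ndarray,
    coords: np.ndarray,
    first_coord: np.ndarray,
    seed: int,
    min_child: int,
) -> tuple[np.ndarray, np.ndarray]:
    """2-means bipartition of a node; fall back to a balanced median split on
    the first nontrivial eigenvector when 2-means degenerates or would strand
    a child too small to fill its subtree."""
    pts = coords[members]
    left = right = None
    if np.ptp(pts, axis=0).max() > 0:
        km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(pts)
        lab = km.labels_
        if 0 < lab.sum() < len(lab):
            a, b = members[lab == 0], members[lab == 1]
            if min(len(a), len(b)) >= min_child:
                left, right = a, b
    if left is None:
        order = np.lexsort((members, first_coord[members]))
        half = len(members) // 2
        left, right = members[order[:half]], members[order[half:]]
    # deterministic child order: side holding the smallest member index first
    if right.min() < left.min():
        left, right = right, left
    return left, right


def build_partition_tree(
    g: DiffusionGeometry, depth: int, seed: int
) -> PartitionTree:
    """Recursive 2-means bipartition on diffusion coordinates down to
    ``depth`` (2**depth leaves).  Splits are seeded from ``seed`` plus a hash
    of the node path so repeated runs are bit-identical."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    n = g.n_points
    if n < 2**depth:
        raise ValueError(
            f"insufficient entities for requested depth: {n} points, "
            f"need >= {2 ** depth}"
        )
    coords = g.coordinates()
    first = coords[:, 0] if coords.shape[1] else np.zeros(n)

    def grow(members: np.ndarray, level: int, node_id: str) -> TreeNode:
        node = TreeNode(members=members, level=level, node_id=node_id)
        if level == depth:
            return node
        if len(members) < 2:
            raise ValueError("insufficient entities for requested depth")
        min_child = 2 ** (depth - level - 1)
        left, right = _split_members(
            members, coords, first, _node_seed(seed, node_id), min_child
        )
        node.children = (
            grow(left, level + 1, node_id + "0"),
            grow(right, level + 1, node_id + "1"),
        )
        return node

    root = grow(np.arange(n), 0, "")
    return PartitionTree(list(g.ids), root, depth)


# ---------------------------------------------------------------------------
# tree-approximate earth mover's distance


def _node_weights_and_means(
    X: np.ndarray, tree: PartitionTree, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-tree-node weights 2**(-alpha*level) * |node|/n and per-point node
    means of the profiles in ``X`` (rows = points, columns = tree members)."""
    n_bins = X.shape[1]
    nodes = list(tree.iter_nodes())
    weights = np.array(
        [2.0 ** (-alpha * nd.level) * len(nd.members) / n_bins for nd in nodes]
    )
    averaging = np.zeros((len(nodes), n_bins))
    for r, nd in enumerate(nodes):
        averaging[r, nd.members] = 1.0 / len(nd.members)
    return weights, X @ averaging.T


def tree_emd_distance(
    X: np.ndarray, tree: PartitionTree, alpha: float = 0.5
) -> np.ndarray:
    """Pairwise tree-approximate EMD between the rows of ``X``:
    sum over tree nodes of weight * |difference of node means|."""
    weights, means = _node_weights_and_means(X, tree, alpha)
    d = cdist(means, means, metric="minkowski", p=1, w=weights)
    np.fill_diagonal(d, 0.0)
    return d


def tree_emd_affinity(
    m: QualityMatrix,
    tree: PartitionTree,
    cfg: PipelineConfig,
    axis: str = "entities",
) -> AffinityKernel:
    """Affinity kernel exp(-d^2/eps) from the tree-EMD between entity rows
    (tree over measures) or measure columns (tree over entities)."""
    if axis == "entities":
        X, ids, tree_ids = m.values, m.entity_ids, m.measure_ids
    elif axis == "measures":
        X, ids, tree_ids = m.values.T, m.measure_ids, m.entity_ids
    else:
        raise ValueError(f"axis must be 'entities' or 'measures', got {axis!r}")
    if list(tree.ids) != list(tree_ids):
        raise ValueError("partition tree ids do not match the profile axis")
    d = tree_emd_distance(X, tree, cfg.emd_level_decay)
    iu = np.triu_indices_from(d, k=1)
    eps = bandwidth_from_rule(d[iu] ** 2, cfg)
    w = np.exp(-(d**2) / eps)
    np.fill_diagonal(w, 1.0)
    w = (w + w.T) / 2.0
    return AffinityKernel(list(ids), w)


# ---------------------------------------------------------------------------
# the coupled iteration


@dataclass
class CoupledResult:
    """Final geometries and trees of the alternating co-organization."""

    entity_geometry: DiffusionGeometry
    measure_geometry: DiffusionGeometry
    entity_tree: PartitionTree
    measure_tree: PartitionTree
    ari_log: list[float] = field(default_factory=list)


def run_coupled_iterations(m: QualityMatrix, cfg: PipelineConfig) -> CoupledResult:
    """Alternate between organizing measures and entities.

    Round 0 builds the measure geometry from cosine affinity, a measure tree,
    then the entity geometry from tree-EMD over that tree and an entity tree.
    Later rounds rebuild the measure affinity by tree-EMD over the entity
    tree (transposed matrix).  Stops after ``cfg.n_coupled_iterations`` rounds
    or once consecutive entity-leaf partitions agree (adjusted Rand index >=
    ``cfg.early_stop_ari``).
    """
    seed = cfg.rng_seed
    entity_depth = cfg.tree_depth
    measure_kernel = ensure_connected(cosine_affinity(m, axis="measures"))
    prev_labels: Optional[np.ndarray] = None
    ari_log: list[float] = []
    for it in range(cfg.n_coupled_iterations):
        measure_geom = diffusion_embed(measure_kernel, cfg)
        measure_tree = build_partition_tree(
            measure_geom, cfg.measure_tree_depth, seed + 101 * it
        )
        entity_kernel = ensure_connected(
            tree_emd_affinity(m, measure_tree, cfg, axis="entities")
        )
        entity_geom = diffusion_embed(entity_kernel, cfg)
        entity_tree = build_partition_tree(entity_geom, entity_depth, seed + 211 * it)
        labels = entity_tree.leaf_labels()
        if prev_labels is not None:
            ari = float(adjusted_rand_score(prev_labels, labels))
            ari_log.append(ari)
            if ari >= cfg.early_stop_ari:
                break
        prev_labels = labels
        if it < cfg.n_coupled_iterations - 1:
            measure_kernel = ensure_connected(
                tree_emd_affinity(m, entity_tree, cfg, axis="measures")
            )
    return CoupledResult(entity_geom, measure_geom, entity_tree, measure_tree, ari_log)
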