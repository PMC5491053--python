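import itertools

import numpy as np
import pytest
from scipy.optimize import linprog
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from hospmap import PipelineConfig
from hospmap.coupled_geometry import (
    AffinityKernel,
    build_partition_tree,
    cosine_affinity,
    diffusion_embed,
    ensure_connected,
    run_coupled_iterations,
    tree_emd_affinity,
    tree_emd_distance,
)
from hospmap.preprocessing import preprocess

from conftest import make_qm, manual_tree


class TestCosineAffinity:
    def test_known_values(self):
        qm = make_qm(np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]).T)
        k = cosine_affinity(qm, axis="measures")
        # measure profiles are the columns: identical, orthogonal, 45 degrees
        assert k.weights[0, 1] == pytest.approx(1.0)
        assert k.weights[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert k.weights[0, 3] == pytest.approx(0.7071, abs=1e-4)

    def test_negative_cosine_clipped(self):
        qm = make_qm(np.array([[1.0, -1.0], [2.0, -2.0]]))
        k = cosine_affinity(qm, axis="measures")
        assert k.weights[0, 1] == 0.0

    def test_zero_norm_profile_rejected(self):
        qm = make_qm([[0.0, 1.0], [0.0, 2.0]])
        with pytest.raises(ValueError, match="m0"):
            cosine_affinity(qm, axis="measures")


def _two_block_kernel(n=6, across=0.01):
    w = np.full((n, n), across)
    w[:3, :3] = 1.0
    w[3:, 3:] = 1.0
    np.fill_diagonal(w, 1.0)
    return AffinityKernel([f"p{i}" for i in range(n)], w)


class TestDiffusionEmbed:
    def test_trivial_pair(self, cfg):
        g = diffusion_embed(_two_block_kernel(), cfg)
        assert g.eigenvalues[0] == pytest.approx(1.0)
        lead = g.eigenvectors[:, 0]
        assert np.allclose(lead, lead[0])

    def test_first_nontrivial_separates_blocks(self, cfg):
        k = _two_block_kernel()
        g = diffusion_embed(k, cfg)
        signs = np.sign(g.eigenvectors[:, 1])
        assert len(set(signs[:3])) == 1 and len(set(signs[3:])) == 1
        assert signs[0] != signs[3]
        # independent oracle: dense eigendecomposition of the Markov matrix
        P = k.weights / k.weights.sum(axis=1, keepdims=True)
        vals, vecs = np.linalg.eig(P)
        order = np.argsort(-vals.real)
        oracle = vecs[:, order[1]].real
        assert adjusted_rand_score(signs, np.sign(oracle)) == 1.0

    def test_self_distance_zero(self, cfg):
        g = diffusion_embed(_two_block_kernel(), cfg)
        assert g.diffusion_distance(2, 2) == 0.0

    def test_disconnected_kernel_rejected(self, cfg):
        w = np.zeros((5, 5))
        w[:2, :2] = 1.0
        w[2:, 2:] = 1.0
        np.fill_diagonal(w, 1.0)
        k = AffinityKernel(list("abcde"), w)
        with pytest.raises(ValueError, match=r"\[3, 2\]"):
            diffusion_embed(k, cfg)

    def test_matches_markov_power_distances(self, rng):
        """Spectral diffusion distances equal the weighted L2 distance between
        rows of the t-step Markov matrix (full spectrum, t=1)."""
        n = 8
        x = rng.normal(0, 1, (n, 2))
        sq = ((x[:, None] - x[None]) ** 2).sum(-1)
        w = np.exp(-sq / np.median(sq))
        np.fill_diagonal(w, 1.0)
        k = AffinityKernel([f"p{i}" for i in range(n)], w)
        cfg = PipelineConfig(n_eigenvectors=n - 1, diffusion_time=1.0)
        g = diffusion_embed(k, cfg)

        deg = w.sum(axis=1)
        P = w / deg[:, None]
        pi = deg / deg.sum()
        for i, j in itertools.combinations(range(n), 2):
            brute = np.sqrt(np.sum((P[i] - P[j]) ** 2 / pi))
            assert g.diffusion_distance(i, j) == pytest.approx(brute, abs=1e-6)


class TestPartitionTree:
    def test_recovers_two_planted_groups(self, cfg):
        g = diffusion_embed(_two_block_kernel(), cfg)
        # 6 points: indices 0-2 and 3-5
        tree = build_partition_tree(g, depth=1, seed=0)
        leaves = tree.leaves()
        groups = [sorted(leaf.members.tolist()) for leaf in leaves]
        assert sorted(groups) == [[0, 1, 2], [3, 4, 5]]

    def test_depth5_on_512_points_gives_32_leaves(self, rng):
        x = rng.normal(0, 1, (512, 3))
        sq = ((x[:, None] - x[None]) ** 2).sum(-1)
        w = np.exp(-sq / np.median(sq))
        np.fill_diagonal(w, 1.0)
        g = diffusion_embed(
            AffinityKernel([f"p{i}" for i in range(512)], w), PipelineConfig()
        )
        tree = build_partition_tree(g, depth=5, seed=0)
        assert len(tree.leaves()) == 32

    def test_leaves_partition_members(self, rng, cfg):
        x = rng.normal(0, 1, (40, 2))
        sq = ((x[:, None] - x[None]) ** 2).sum(-1)
        w = np.exp(-sq / np.median(sq))
        np.fill_diagonal(w, 1.0)
        g = diffusion_embed(AffinityKernel([f"p{i}" for i in range(40)], w), cfg)
        tree = build_partition_tree(g, depth=3, seed=1)
        all_members = np.concatenate([leaf.members for leaf in tree.leaves()])
        assert sorted(all_members.tolist()) == list(range(40))

    def test_insufficient_points_rejected(self, cfg):
        g = diffusion_embed(_two_block_kernel(), cfg)  # 6 points
        with pytest.raises(ValueError, match="insufficient"):
            build_partition_tree(g, depth=3, seed=0)


class TestTreeEMD:
    def test_identical_profiles(self, cfg):
        qm = make_qm(np.tile([1.0, 2.0, 3.0, 4.0], (3, 1)))
        tree = manual_tree(qm.measure_ids, ((0, 1), (2, 3)))
        d = tree_emd_distance(qm.values, tree, cfg.emd_level_decay)
        assert np.allclose(d, 0.0)
        k = tree_emd_affinity(qm, tree, PipelineConfig(kernel_bandwidth_rule="fixed"))
        assert np.allclose(k.weights, 1.0)

    def test_symmetry(self, rng, cfg):
        X = rng.normal(0, 1, (6, 4))
        tree = manual_tree([f"m{j}" for j in range(4)], ((0, 1), (2, 3)))
        d = tree_emd_distance(X, tree, cfg.emd_level_decay)
        assert np.allclose(d, d.T)

    def test_single_leaf_delta_follows_ancestor_path(self):
        """Perturbing one measure by delta changes the distance by delta times
        the summed weight of that leaf's ancestor path (hand-enumerated on a
        depth-2 tree over 4 measures)."""
        alpha, delta, n = 0.5, 0.8, 4
        X = np.zeros((2, n))
        X[1, 0] += delta  # measure 0 sits under nodes: root, (0,1), (0,)
        tree = manual_tree(
            [f"m{j}" for j in range(n)], (((0,), (1,)), ((2,), (3,)))
        )
        d = tree_emd_distance(X, tree, alpha)
        path = [
            2 ** (-alpha * 0) * (4 / 4) * (delta / 4),  # root mean shifts delta/4
            2 ** (-alpha * 1) * (2 / 4) * (delta / 2),  # node {m0,m1}
            2 ** (-alpha * 2) * (1 / 4) * delta,        # leaf {m0}
        ]
        assert d[0, 1] == pytest.approx(sum(path), abs=1e-12)

    def test_root_only_tree_reduces_to_grand_mean_difference(self, rng):
        X = rng.normal(0, 1, (5, 6))
        from hospmap.coupled_geometry import PartitionTree, TreeNode

        root = TreeNode(members=np.arange(6), level=0, node_id="")
        tree = PartitionTree([f"m{j}" for j in range(6)], root, 0)
        d = tree_emd_distance(X, tree, alpha=0.5)
        gm = X.mean(axis=1)
        assert np.allclose(d, np.abs(gm[:, None] - gm[None, :]), atol=1e-12)

    def test_pseudometric_on_random_instances(self, rng):
        X = rng.normal(0, 1, (10, 8))
        tree = manual_tree(
            [f"m{j}" for j in range(8)],
            ((((0,), (1,)), ((2,), (3,))), (((4,), (5,)), ((6,), (7,)))),
        )
        d = tree_emd_distance(X, tree, 0.5)
        assert (d >= -1e-12).all()
        assert np.allclose(d, d.T)
        for i, j, k in itertools.permutations(range(10), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-9

    def test_orders_pairs_like_exact_lp_transport(self, rng):
        """Tree-EMD pair ordering agrees (Spearman >= 0.9) with exact EMD by
        linear programming, ground metric = tree path length between leaves."""
        n_meas, n_prof = 6, 8
        tree = manual_tree(
            [f"m{j}" for j in range(n_meas)],
            ((((0,), (1,)), (2,)), (((3,), (4,)), (5,))),
        )
        # leaf path-length ground metric
        paths = {}
        def collect(node, path):
            if node.children is None:
                for m in node.members:
                    paths[int(m)] = path
            else:
                collect(node.children[0], path + "0")
                collect(node.children[1], path + "1")
        collect(tree.root, "")
        cost = np.zeros((n_meas, n_meas))
        for a in range(n_meas):
            for b in range(n_meas):
                pa, pb = paths[a], paths[b]
                lcp = 0  # longest common prefix

                for x, y in zip(pa, pb):
                    if x != y:
                        break
                    lcp += 1
                cost[a, b] = (len(pa) - lcp) + (len(pb) - lcp)

        profiles = rng.dirichlet(np.ones(n_meas), size=n_prof)

        def exact_emd(p, q):
            c = cost.ravel()
            A_eq = np.zeros((2 * n_meas, n_meas * n_meas))
            for i in range(n_meas):
                A_eq[i, i * n_meas : (i + 1) * n_meas] = 1.0
                A_eq[n_meas + i, i::n_meas] = 1.0
            res = linprog(c, A_eq=A_eq, b_eq=np.concatenate([p, q]),
                          bounds=(0, None), method="highs")
            assert res.success
            return res.fun

        d_tree = tree_emd_distance(profiles, tree, 0.5)
        iu = np.triu_indices(n_prof, 1)
        d_lp = np.array(
            [exact_emd(profiles[i], profiles[j]) for i, j in zip(*iu)]
        )
        rho = spearmanr(d_tree[iu], d_lp).statistic
        assert rho >= 0.9


class TestCoupledIterations:
    def _qm(self, rng):
        # 4-block bicluster: 2 entity clusters x 2 measure blocks
        ent = np.repeat([0, 1], 20)
        mea = np.repeat([0, 1], 6)
        mean = np.where((ent[:, None] + mea[None, :]) % 2 == 0, 2.0, -2.0)
        vals = mean + rng.normal(0, 0.5, (40, 12))
        return make_qm(vals)

    def test_single_iteration_equals_composition(self, rng):
        qm = self._qm(rng)
        cfg = PipelineConfig(
            rng_seed=3, n_coupled_iterations=1, measure_tree_depth=2,
            n_reference_profiles=4,
        )
        m = preprocess(qm, cfg)
        res = run_coupled_iterations(m, cfg)

        mk = ensure_connected(cosine_affinity(m, axis="measures"))
        mg = diffusion_embed(mk, cfg)
        mt = build_partition_tree(mg, cfg.measure_tree_depth, cfg.rng_seed)
        ek = ensure_connected(tree_emd_affinity(m, mt, cfg, axis="entities"))
        eg = diffusion_embed(ek, cfg)
        et = build_partition_tree(eg, cfg.tree_depth, cfg.rng_seed)

        assert np.allclose(res.entity_geometry.eigenvalues, eg.eigenvalues)
        assert np.array_equal(res.entity_tree.leaf_labels(), et.leaf_labels())
        assert np.array_equal(res.measure_tree.leaf_labels(), mt.leaf_labels())

    def test_recovers_planted_measure_blocks(self, rng):
        """Planted 4-block bicluster: depth-1 measure-tree leaves recover the
        2 measure blocks; entity leaves separate the 2 entity clusters."""
        qm = self._qm(rng)
        cfg = PipelineConfig(
            rng_seed=3, measure_tree_depth=1, n_reference_profiles=2
        )
        m = preprocess(qm, cfg)
        res = run_coupled_iterations(m, cfg)
        mea = np.repeat([0, 1], 6)
        assert adjusted_rand_score(mea, res.measure_tree.leaf_labels()) >= 0.9
        ent = np.repeat([0, 1], 20)
        assert adjusted_rand_score(ent, res.entity_tree.leaf_labels()) >= 0.9

    def test_deterministic(self, rng):
        qm = self._qm(rng)
        cfg = PipelineConfig(rng_seed=5, measure_tree_depth=2, n_reference_profiles=4)
        m = preprocess(qm, cfg)
        a = run_coupled_iterations(m, cfg)
        b = run_coupled_iterations(m, cfg)
        assert np.array_equal(a.entity_tree.leaf_labels(), b.entity_tree.leaf_labels())
        assert np.array_equal(a.entity_geometry.eigenvectors, b.entity_geometry.eigenvectors)
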