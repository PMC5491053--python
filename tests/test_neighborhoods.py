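import itertools

import numpy as np
import pandas as pd
import pytest

from hospmap.neighborhoods import (
    assign_neighborhoods,
    classify_domain_performance,
    heat_cover_time,
    neighborhood_profile,
    place_sources,
)
from hospmap.ssl_embedding import EmbeddingResult

from conftest import make_qm


def _embedding(points):
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    ids = [f"e{i}" for i in range(len(points))]
    return EmbeddingResult(ids, points - points.mean(axis=0), np.ones(points.shape[1]))


def _brute_force_kcenter(D, k):
    n = len(D)
    best, best_obj = None, np.inf
    for combo in itertools.combinations(range(n), k):
        obj = D[:, combo].min(axis=1).max()
        if obj < best_obj - 1e-12:
            best, best_obj = combo, obj
    return best_obj


class TestPlaceSources:
    def test_every_point_a_source_gives_zero_objective(self, rng):
        e = _embedding(rng.normal(0, 1, (6, 2)))
        src = place_sources(e, 6, seed=0)
        assert sorted(src) == sorted(e.entity_ids)
        asg = assign_neighborhoods(e, src, 6)
        assert asg.objective == 0.0

    def test_minimax_single_source_on_line(self):
        e = _embedding([0.0, 1.0, 10.0])
        assert place_sources(e, 1, seed=0) == ["e1"]

    def test_one_source_per_well_separated_cluster(self, rng):
        centers = np.array([[0.0, 0.0], [50.0, 0.0], [0.0, 50.0]])
        pts = np.vstack([c + rng.normal(0, 0.5, (4, 2)) for c in centers])
        e = _embedding(pts)
        src = place_sources(e, 3, seed=1)
        groups = {int(s[1:]) // 4 for s in src}
        assert groups == {0, 1, 2}

    @pytest.mark.parametrize("n,k", [(8, 2), (10, 3), (12, 3)])
    def test_matches_exhaustive_minimax(self, rng, n, k):
        pts = rng.normal(0, 1, (n, 2))
        e = _embedding(pts)
        D = e.distance_matrix()
        src = place_sources(e, k, seed=3)
        idx = [e.entity_ids.index(s) for s in src]
        achieved = D[:, idx].min(axis=1).max()
        assert achieved == pytest.approx(_brute_force_kcenter(D, k), rel=1e-9)

    def test_too_many_sources_rejected(self, rng):
        e = _embedding(rng.normal(0, 1, (4, 2)))
        with pytest.raises(ValueError, match="exceeds"):
            place_sources(e, 5, seed=0)


class TestAssignNeighborhoods:
    def test_source_assigned_to_itself(self, rng):
        e = _embedding(rng.normal(0, 1, (20, 2)))
        src = place_sources(e, 4, seed=0)
        asg = assign_neighborhoods(e, src, 4)
        for s in src:
            assert s == asg.source_of_label[asg.labels[s]]
            assert asg.distance_to_source[s] == 0.0

    def test_sixteen_labels_a_through_p(self, rng):
        e = _embedding(rng.normal(0, 1, (80, 3)))
        src = place_sources(e, 16, seed=0)
        asg = assign_neighborhoods(e, src, 16)
        assert sorted(asg.sizes) == [chr(ord("A") + i) for i in range(16)]
        assert sum(asg.sizes.values()) == 80
        assert set(asg.labels) == set(e.entity_ids)

    def test_labels_ordered_by_descending_size(self, rng):
        e = _embedding(np.concatenate([np.zeros(8), np.full(3, 10.0)]))
        asg = assign_neighborhoods(e, ["e0", "e9"], 2)
        assert asg.sizes["A"] == 8 and asg.sizes["B"] == 3

    def test_midpoint_tie_is_deterministic(self):
        e = _embedding([0.0, 2.0, 1.0])  # e2 exactly between e0 and e1
        runs = {assign_neighborhoods(e, ["e1", "e0"], 2).labels["e2"] for _ in range(5)}
        assert len(runs) == 1
        # canonical order sorts source ids: e0 before e1
        asg = assign_neighborhoods(e, ["e1", "e0"], 2)
        assert asg.source_of_label[asg.labels["e2"]] == "e0"

    def test_duplicate_sources_rejected(self, rng):
        e = _embedding(rng.normal(0, 1, (5, 2)))
        with pytest.raises(ValueError, match="duplicate"):
            assign_neighborhoods(e, ["e0", "e0"], 2)

    def test_partition_sums_to_n(self, rng):
        for n, k in ((30, 4), (57, 7)):
            e = _embedding(rng.normal(0, 1, (n, 2)))
            asg = assign_neighborhoods(e, place_sources(e, k, seed=0), k)
            assert sum(asg.sizes.values()) == n


class TestNeighborhoodProfile:
    def test_identical_entities(self):
        qm = make_qm(np.tile([0.5, -0.5, 1.0], (11, 1)))
        e = _embedding(np.arange(11.0))
        prof = neighborhood_profile(qm, e, "e0", 10)
        assert np.allclose(prof, [0.5, -0.5, 1.0])

    def test_two_row_mean(self):
        qm = make_qm([[0.0, 0.0], [2.0, 4.0], [100.0, 100.0]])
        e = _embedding([0.0, 1.0, 50.0])
        prof = neighborhood_profile(qm, e, "e0", 1)
        assert np.allclose(prof, [1.0, 2.0])

    def test_profile_length_is_n_measures(self, rng):
        qm = make_qm(rng.normal(0, 1, (12, 7)))
        e = _embedding(rng.normal(0, 1, (12, 3)))
        assert neighborhood_profile(qm, e, "e3", 5).shape == (7,)

    def test_insufficient_entities_rejected(self, rng):
        qm = make_qm(rng.normal(0, 1, (5, 2)))
        e = _embedding(rng.normal(0, 1, (5, 2)))
        with pytest.raises(ValueError, match="5"):
            neighborhood_profile(qm, e, "e0", 5)


class TestClassifyDomainPerformance:
    def _meta(self, domains):
        meta = pd.DataFrame(
            {"domain": domains, "direction": "higher_better"},
            index=[f"m{j}" for j in range(len(domains))],
        )
        meta.index.name = "measure_id"
        return meta

    def test_unanimous_above_is_good(self):
        cls = classify_domain_performance(
            np.array([0.5, 0.5, 0.5]), self._meta(["process"] * 3)
        )
        assert cls.by_domain["process"] == "good"

    def test_split_signs_are_mixed(self):
        cls = classify_domain_performance(
            np.array([0.5, -0.5]), self._meta(["process"] * 2)
        )
        assert cls.by_domain["process"] == "mixed"

    def test_near_zero_is_average(self):
        cls = classify_domain_performance(
            np.array([0.05, -0.03, 0.01]), self._meta(["safety"] * 3)
        )
        assert cls.by_domain["safety"] == "average"

    def test_majority_below_is_poor(self):
        cls = classify_domain_performance(
            np.array([-0.4, -0.6, 0.2]), self._meta(["mortality"] * 3)
        )
        assert cls.by_domain["mortality"] == "poor"

    def test_one_sd_flags(self):
        cls = classify_domain_performance(
            np.array([1.3, -1.2, 0.0]), self._meta(["process", "process", "process"])
        )
        assert cls.particularly_good == ["m0"]
        assert cls.particularly_poor == ["m1"]

    def test_empty_meta_rejected(self):
        with pytest.raises(ValueError):
            classify_domain_performance(np.array([1.0]), self._meta(["process"] * 2))


def test_heat_simulation_agrees_with_kcenter_ranking(rng):
    """The literal heat-propagation mode: the minimax-optimal source set
    covers the map no more slowly than a deliberately bad source set."""
    centers = np.array([[0.0, 0.0], [6.0, 0.0], [0.0, 6.0]])
    pts = np.vstack([c + rng.normal(0, 0.4, (5, 2)) for c in centers])
    e = _embedding(pts)
    good = place_sources(e, 3, seed=0)
    bad = [e.entity_ids[0], e.entity_ids[1], e.entity_ids[2]]  # one cluster only
    t_good = heat_cover_time(e, good, bandwidth=4.0)
    t_bad = heat_cover_time(e, bad, bandwidth=4.0)
    assert t_good <= t_bad
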