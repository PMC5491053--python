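import numpy as np
import pandas as pd
import pytest

from hospmap import PipelineConfig, QualityMatrix
from hospmap.coupled_geometry import PartitionTree, TreeNode
from hospmap.preprocessing import DOMAINS


def make_qm(
    values,
    observed=None,
    domains=None,
    directions=None,
    entity_ids=None,
    measure_ids=None,
) -> QualityMatrix:
    """Assemble a QualityMatrix from plain arrays for unit tests."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if observed is None:
        observed = ~np.isnan(values)
    observed = np.asarray(observed, dtype=bool)
    entity_ids = entity_ids or [f"e{i}" for i in range(n)]
    measure_ids = measure_ids or [f"m{j}" for j in range(p)]
    domains = domains or [DOMAINS[j % len(DOMAINS)] for j in range(p)]
    directions = directions or ["higher_better"] * p
    meta = pd.DataFrame(
        {"domain": domains, "direction": directions}, index=measure_ids
    )
    meta.index.name = "measure_id"
    return QualityMatrix(entity_ids, measure_ids, values, observed, meta)


def manual_tree(ids, nested) -> PartitionTree:
    """Build a PartitionTree from nested member-index lists, e.g.
    ``((0, 1), (2, 3))`` for a depth-1 split of four points."""

    def grow(spec, level, node_id):
        if isinstance(spec, tuple) and len(spec) == 2 and not isinstance(spec[0], int):
            left = grow(spec[0], level + 1, node_id + "0")
            right = grow(spec[1], level + 1, node_id + "1")
            members = np.concatenate([left.members, right.members])
            node = TreeNode(members=members, level=level, node_id=node_id)
            node.children = (left, right)
            return node
        return TreeNode(
            members=np.asarray(list(spec), dtype=int), level=level, node_id=node_id
        )

    root = grow(nested, 0, "")

    def depth(n):
        return n.level if n.children is None else max(depth(c) for c in n.children)

    return PartitionTree(list(ids), root, depth(root))


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig(rng_seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
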