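import numpy as np
import pandas as pd
import pytest

from agripop.datatypes import GenotypeMatrix


@pytest.fixture
def toy_gm() -> GenotypeMatrix:
    """4 samples x 5 markers with two missing calls."""
    dosages = np.array(
        [
            [0, 2, 1, 0, 2],
            [1, 2, 1, 0, 2],
            [2, 1, 0, 0, 2],
            [0, 0, 2, 0, 1],
        ]
    )
    mask = np.zeros((4, 5), dtype=bool)
    mask[0, 2] = True
    mask[3, 4] = True
    return GenotypeMatrix(
        [f"S{i}" for i in range(1, 5)], [f"M{j}" for j in range(1, 6)], dosages, mask
    )


@pytest.fixture
def toy_groups() -> pd.DataFrame:
    return pd.DataFrame(
        {"sample_id": ["S1", "S2", "S3", "S4"], "group": ["A", "A", "B", "B"]}
    )


def random_additive_tree(rng, n_taxa):
    """Random binary tree with U(0.5, 2) branch lengths (skbio TreeNode)."""
    from skbio import TreeNode

    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.5, 2.0))
        b.length = float(rng.uniform(0.5, 2.0))
        parent = TreeNode(children=[b, a])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    return nodes[0]


def random_gm(rng, n=10, m=50, missing_rate=0.1) -> GenotypeMatrix:
    dosages = rng.integers(0, 3, size=(n, m))
    mask = rng.random((n, m)) < missing_rate
    return GenotypeMatrix(
        [f"S{i}" for i in range(n)], [f"M{j}" for j in range(m)], dosages, mask
    )
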