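import io

import numpy as np
import pytest
from skbio import TreeNode

from vclasso.kernels import OTUTable
from vclasso.simulate import random_coalescent_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def three_leaf_tree():
    """((a:1,b:1):1,c:1); — the unit-branch-length hand-oracle tree."""
    return TreeNode.read(io.StringIO("((a:1,b:1):1,c:1);"))


@pytest.fixture
def two_sample_table():
    """Samples A=(1,0,0), B=(0,1,0) on leaves a, b, c."""
    return OTUTable(
        counts=np.array([[1, 0, 0], [0, 1, 0]]),
        sample_ids=["A", "B"],
        otu_ids=["a", "b", "c"],
        taxon_of={"a": "g", "b": "g", "c": "g"},
    )


def random_table_and_tree(rng, n_samples=8, n_otus=12, depth=500):
    """Random fixture: coalescent tree + multinomial counts, no zero rows."""
    otus = [f"otu{i}" for i in range(n_otus)]
    tree = random_coalescent_tree(otus, rng)
    p = rng.dirichlet(np.ones(n_otus))
    counts = np.vstack([rng.multinomial(depth, p) for _ in range(n_samples)])
    counts[:, 0] += 1  # guarantee every sample has reads
    table = OTUTable(counts, [f"S{i}" for i in range(n_samples)], otus,
                     {o: "g" for o in otus})
    return table, tree


def random_psd(rng, n, rank=None):
    """Random PSD matrix scaled to unit Frobenius norm."""
    rank = rank or n
    A = rng.standard_normal((n, rank))
    K = A @ A.T
    return K / np.linalg.norm(K, "fro")
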