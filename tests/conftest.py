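import numpy as np
import pytest

from benthodiv import CountTable, PhyloTree
from benthodiv.synthetic import SyntheticConfig, simulate_dataset


@pytest.fixture(scope="session")
def caterpillar_tree() -> PhyloTree:
    """((A:1,B:2):3,C:4); — total branch length 10."""
    return PhyloTree.from_newick("((A:1,B:2):3,C:4);")


@pytest.fixture(scope="session")
def unit_tree() -> PhyloTree:
    """((A:1,B:1):1,C:1); — all unit branch lengths."""
    return PhyloTree.from_newick("((A:1,B:1):1,C:1);")


@pytest.fixture(scope="session")
def small_dataset():
    """Default-condition synthetic transect, scaled to 120 zOTUs."""
    return simulate_dataset(SyntheticConfig(seed=7, n_otus=120))


@pytest.fixture()
def tiny_table() -> CountTable:
    counts = np.array([[1, 2, 3], [0, 4, 0]])
    return CountTable(counts, ["s1", "s2"], ["o1", "o2", "o3"])
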