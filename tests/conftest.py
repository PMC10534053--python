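import numpy as np
import pytest

from msasim import SiteRateModel, jukes_cantor, parse_model_spec, parse_newick
from msasim.treeio import PhyloTree, TreeNode

#: Seven-tip reference topology; with deterministic id assignment the
#: preorder visit sequence is 7, 8, 9, 10, 0, 1, 2, 11, 3, 4, 12, 5, 6.
FIG_TREE_NEWICK = (
    "((((0:0.1,1:0.1):0.1,2:0.1):0.1,(3:0.1,4:0.1):0.1):0.1,(5:0.1,6:0.1):0.1);"
)


@pytest.fixture
def fig_tree():
    return parse_newick(FIG_TREE_NEWICK)


@pytest.fixture
def jc_model():
    return jukes_cantor()


@pytest.fixture
def uniform_rates():
    return SiteRateModel()  # single rate class, rate 1


@pytest.fixture
def gtr_ig():
    """The benchmark model: GTR, p_inv = 0.2, Gamma(0.5) with 4 categories."""
    return parse_model_spec("GTR+I{0.2}+G{4}{0.5}")


def two_tip_tree(t1: float, t2: float) -> PhyloTree:
    root = TreeNode()
    root.add_child(TreeNode(name="A", length=t1))
    root.add_child(TreeNode(name="B", length=t2))
    return PhyloTree(root)


class RecordingSink:
    """Collects (name, sequence-bytes) records in write order."""

    def __init__(self):
        self.records = []

    def write(self, name, sequence):
        self.records.append((name, sequence))

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
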