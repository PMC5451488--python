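import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode
from io import StringIO

from aridnet.io import OtuTable
from aridnet.synthetic import GradientDesign, simulate_dataset


@pytest.fixture(scope="session")
def tiny_design():
    """A fast design without planted blocks for plumbing tests."""
    return GradientDesign(n_sites=5, pits_per_site=2, n_otus=60,
                          n_blocks=0, seed=42,
                          depth_lognormal_params=(np.log(2000), 0.1))


@pytest.fixture(scope="session")
def tiny_dataset(tiny_design):
    dataset, truth = simulate_dataset(tiny_design)
    return dataset, truth


@pytest.fixture(scope="session")
def small_block_design():
    """A small design with planted modules, used for recovery tests."""
    return GradientDesign(n_sites=8, pits_per_site=3, n_otus=220,
                          n_blocks=6, block_size_range=(6, 14), seed=7,
                          depth_lognormal_params=(np.log(8000), 0.1))


@pytest.fixture(scope="session")
def small_block_dataset(small_block_design):
    return simulate_dataset(small_block_design)


@pytest.fixture
def four_leaf_tree():
    return TreeNode.read(StringIO("((A:1,B:1):1,(C:1,D:1):1);"))


@pytest.fixture
def toy_table():
    counts = pd.DataFrame(
        [[5, 0, 3, 1],
         [2, 2, 0, 4],
         [0, 7, 1, 0]],
        index=["s1", "s2", "s3"], columns=["A", "B", "C", "D"])
    return OtuTable(counts)


def metadata_record(**overrides):
    record = {
        "vegetation_cover": 0.0,
        "shallow_nitrate": 1.0,
        "shallow_sulfate": 10.0,
        "salar_override": False,
    }
    record.update(overrides)
    return record
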