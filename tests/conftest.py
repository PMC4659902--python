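import io

import numpy as np
import pytest
from skbio import TreeNode

from rivercoherence.datatypes import OtuTable, SampleFrame
from rivercoherence.simulate import SimConfig, simulate_dataset

import pandas as pd


def tree_from(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick), convert_underscores=False)


@pytest.fixture(scope="session")
def default_bundle():
    """One full-size simulated bundle under the default study design."""
    return simulate_dataset(SimConfig(), seed=1)


@pytest.fixture(scope="session")
def small_bundle():
    """A small, fast bundle for I/O and pipeline tests."""
    from rivercoherence.simulate import ClassSpec

    config = SimConfig(
        classes=[
            ClassSpec("ClassA", "PhylumA", 30, 0.55, +1, +1),
            ClassSpec("ClassB", "PhylumB", 20, 0.35, -1, -1),
        ],
        n_filler=10,
        filler_share=0.1,
        depth_range=(1000, 2000),
    )
    return simulate_dataset(config, seed=7)


@pytest.fixture
def star_tree():
    return tree_from("(A:1,B:1,C:1);")


@pytest.fixture
def caterpillar_tree():
    return tree_from("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def toy_table():
    return OtuTable(
        ["o1", "o2", "o3"],
        ["s1", "s2"],
        np.array([[1, 0], [2, 5], [0, 3]]),
    )


@pytest.fixture
def river_frames():
    """Minimal 4-site design: 2 upstream, 1 reservoir, 1 downstream."""
    rows = []
    for site, reach, order in [
        ("U1", "upstream", 1),
        ("U2", "upstream", 2),
        ("R1", "reservoir", 3),
        ("D1", "downstream", 4),
    ]:
        rows.append(
            {
                "sample_id": f"{site}_a",
                "site_id": site,
                "reach": reach,
                "flow_order": order,
                "campaign": "a",
            }
        )
    return SampleFrame(pd.DataFrame(rows))
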