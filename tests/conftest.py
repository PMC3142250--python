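import numpy as np
import pytest

import palmdiv as pv


@pytest.fixture
def toy_tree() -> pv.Chronogram:
    """Three tips, crown age 10, internal ages {10, 5}."""
    return pv.parse_newick("((A:5,B:5):5,C:10);")


@pytest.fixture
def toy_bt(toy_tree) -> pv.BranchingTimes:
    return toy_tree.branching_times()


@pytest.fixture
def balanced4() -> pv.Chronogram:
    """Balanced four-tip tree with internal ages {12, 7, 4}."""
    return pv.parse_newick("((A:4,B:4):8,(C:7,D:7):5);")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
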