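import sys
from pathlib import Path

import numpy as np
import pytest

import corrtrait as ct

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable


@pytest.fixture
def balanced_quartet():
    """Ultrametric 4-tip tree ((A,B),(C,D)) with unit cherry branches."""
    return ct.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def three_tip_tree():
    return ct.parse_newick("((A:0.7,B:1.2):0.8,C:2.1);")


def random_small_tree(rng, n_min=3, n_max=5):
    n = int(rng.integers(n_min, n_max + 1))
    return ct.simulate_tree(n, 1.0, int(rng.integers(2**31)))


def random_dependent_q(rng, lo=-1.0, hi=0.5):
    rates = 10.0 ** rng.uniform(lo, hi, 8)
    return ct.build_q(ct.dependent_model(), rates)


@pytest.fixture
def rng():
    return np.random.default_rng(20170301)
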