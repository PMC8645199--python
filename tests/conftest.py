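import numpy as np
import pytest
from hypothesis import settings

from phylodecouple.phylo import read_newick

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from phylodecouple.synthetic_data import simulate_tree


@pytest.fixture(scope="session")
def cherry():
    """Two-tip tree with unit branches."""
    return read_newick("(A:1,B:1);")


@pytest.fixture(scope="session")
def three_tip():
    """The worked three-tip example: ((A:1,B:1):1,C:2)."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def radiation_tree():
    """A 234-tip, 10-My pure-birth radiation (fixed seed)."""
    return simulate_tree(234, 10.0, seed=2021)


@pytest.fixture(scope="session")
def small_tree():
    """A 50-tip, 10-My tree reused by the rate-model tests."""
    return simulate_tree(50, 10.0, seed=11)


def random_triangle(rng):
    """A non-degenerate random 2-D triangle."""
    while True:
        pts = rng.normal(0, 1, (3, 2))
        if np.abs(np.cross(pts[1] - pts[0], pts[2] - pts[0])) > 0.1:
            return pts
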