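import numpy as np
import pytest

from rateshift import TraitMap, parse_newick, rockfish_fixture
from rateshift.simulate import SimulationConfig


@pytest.fixture(scope="session")
def rockfish():
    """Shipped 24-tip rockfish tree with published-style trait flags."""
    return rockfish_fixture()


@pytest.fixture(scope="session")
def rockfish_tree(rockfish):
    return rockfish[0]


@pytest.fixture(scope="session")
def rockfish_traits(rockfish):
    return rockfish[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def star10():
    """Star tree: 10 tips directly under the root, unit branches."""
    return parse_newick("(" + ",".join(f"t{i}:1.0" for i in range(10)) + ");")


def random_tree(rng, n_tips: int, scale: float = 0.1):
    """Random binary rooted tree with exponential branch lengths."""
    nodes = [f"t{i}:{rng.exponential(scale):.6f}" for i in range(n_tips)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.exponential(scale):.6f}")
    return parse_newick(f"({nodes[0]},{nodes[1]});")
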