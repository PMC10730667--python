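import numpy as np
import pytest

from mfnj import AlgoConfig, DistanceMatrix, bear_fixture

# The nine-bear matrix typed directly from its printed lower-triangular
# form, as an oracle independent of the packaged fixture.
BEAR_LOWER_PHYLIP = """\
9
Abruzzo
Pyrenees 1.3
Kodiak 4.3 4.3
Captive-3 4.3 4.3 0.7
Captive-4 2.7 2.3 5.0 5.0
Captive-5 3.0 3.0 1.3 1.3 3.7
Grizzly 1.7 1.7 2.7 2.7 2.3 2.0
Polar-2 2.0 2.0 3.0 3.0 2.7 2.3 0.3
Black 8.7 8.0 10.0 10.0 10.0 8.7 9.0 9.4
"""


@pytest.fixture(scope="session")
def bears() -> DistanceMatrix:
    return bear_fixture()


@pytest.fixture
def cfg() -> AlgoConfig:
    return AlgoConfig()


def unrooted_edge_lengths(tree) -> list:
    """Sorted branch lengths of the unrooted tree: a degree-2 serialization
    root contributes its two child branches as one merged edge."""
    lengths = [
        n.branch_length for n in tree.nodes() if n.branch_length is not None
    ]
    if len(tree.root.children) == 2:
        a, b = (c.branch_length for c in tree.root.children)
        lengths.remove(a)
        lengths.remove(b)
        lengths.append(a + b)
    return sorted(lengths)


def random_distance_matrix(rng: np.random.Generator, n: int) -> DistanceMatrix:
    """A generic random symmetric matrix (not additive; ties measure-zero)."""
    vals = rng.uniform(0.5, 10.0, size=(n, n))
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(tuple(f"T{i}" for i in range(n)), vals)
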