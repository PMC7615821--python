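"""Shared fixtures: hand-constructed toy spaces and small synthetic objects."""

import numpy as np
import pytest

from semfluency.semantic_space import SemanticSpace
from semfluency.synthetic import ClusterSpaceSpec, make_clustered_space


@pytest.fixture(scope="session")
def toy_space() -> SemanticSpace:
    """Four 2-D word vectors chosen for exact hand arithmetic.

    norms: hund 5, katze 2, maus 5, esel 1;
    cos(hund, katze) = 8/10 = 0.8, cos(katze, maus) = 6/10 = 0.6,
    cos(hund, maus) = 24/25 = 0.96.
    """
    return SemanticSpace(
        ("hund", "katze", "maus", "esel"),
        np.array([[3.0, 4.0], [0.0, 2.0], [4.0, 3.0], [1.0, 0.0]]),
    )


@pytest.fixture(scope="session")
def clustered_space() -> SemanticSpace:
    return make_clustered_space(ClusterSpaceSpec(seed=123))
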