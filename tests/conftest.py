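import numpy as np
import pytest

from chromoran import FitnessScheme, build_family

# (name, builder args, N_G, N_R, k_G, k_R) for the biregular properly
# two-colored fixture suite used by the engine-agreement tests
BIREGULAR_FIXTURES = [
    ("cycle4", ("cycle", 4), 2, 2, 2, 2),
    ("cycle6", ("cycle", 6), 3, 3, 2, 2),
    ("cycle8", ("cycle", 8), 4, 4, 2, 2),
    ("K11", ("complete_bipartite", 1, 1), 1, 1, 1, 1),
    ("K22", ("complete_bipartite", 2, 2), 2, 2, 2, 2),
    ("K33", ("complete_bipartite", 3, 3), 3, 3, 3, 3),
    ("K24", ("complete_bipartite", 2, 4), 2, 4, 4, 2),
    ("star4", ("star", 4), 3, 1, 1, 3),
    ("star5", ("star", 5), 4, 1, 1, 4),
    ("star8", ("star", 8), 7, 1, 1, 7),
    ("star10", ("star", 10), 9, 1, 1, 9),
    ("path3", ("path", 3), 2, 1, 1, 2),
]


@pytest.fixture(scope="session")
def biregular_suite():
    """Built graphs paired with their (N_G, N_R, k_G, k_R) profile."""
    return [
        (name, build_family(*args), counts)
        for name, args, *counts in [
            (n, a, ng, nr, kg, kr) for n, a, ng, nr, kg, kr in BIREGULAR_FIXTURES
        ]
    ]


def random_scheme(rng: np.random.Generator) -> FitnessScheme:
    """A random positive fitness table, away from degeneracy."""
    return FitnessScheme(*rng.uniform(0.2, 2.0, size=4))
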