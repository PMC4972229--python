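import numpy as np
import pytest

from drwr import LandscapeConfig, OccurrenceMatrix, generate_landscape


@pytest.fixture
def abc_occ() -> OccurrenceMatrix:
    """Three-site worked example: A={sp1,sp2}, B={sp2}, C={sp3}."""
    return OccurrenceMatrix(
        ["A", "B", "C"],
        ["sp1", "sp2", "sp3"],
        np.array([[1, 1, 0], [0, 1, 0], [0, 0, 1]]),
    )


@pytest.fixture
def random_occ():
    """Factory for seeded random occurrence matrices."""

    def make(seed: int, n_sites: int, n_species: int, p: float = 0.3):
        rng = np.random.default_rng(seed)
        inc = rng.random((n_sites, n_species)) < p
        return OccurrenceMatrix(
            [f"s{i:03d}" for i in range(n_sites)],
            [f"sp{j:03d}" for j in range(n_species)],
            inc,
        )

    return make


@pytest.fixture(scope="session")
def default_landscape():
    """One default synthetic landscape shared across read-only tests."""
    return generate_landscape(LandscapeConfig(seed=23))
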