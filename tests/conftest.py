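import numpy as np
import pandas as pd
import pytest

from hetqtl import simulate as sim


@pytest.fixture(scope="session")
def small_reference():
    return sim.generate_reference(n_genes=24, n_chromosomes=3, seed=11)


@pytest.fixture(scope="session")
def default_marker_map():
    return sim.generate_marker_map(seed=7)


@pytest.fixture(scope="session")
def marked_map():
    """Default map but with chr03 markers on a fixed 11-cM grid (44 cM is a marker)."""
    return sim.generate_marker_map(
        positions_cm={"chr03": [0, 11, 22, 33, 44, 55, 66, 77, 88, 99, 110]}, seed=7
    )


@pytest.fixture(scope="session")
def ril_population(default_marker_map):
    return sim.simulate_ril_genotypes(default_marker_map, n_lines=266, seed=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def toy_counts():
    """50 signatures x 5 libraries of raw counts with library metadata."""
    gen = np.random.default_rng(3)
    sigs = [f"SIG{i:03d}" for i in range(50)]
    libs = [f"L{j}" for j in range(5)]
    counts = pd.DataFrame(
        gen.integers(0, 40, size=(50, 5)), index=sigs, columns=libs
    )
    counts.iloc[0] = 0  # an all-zero row
    meta = pd.DataFrame(
        {
            "library": libs,
            "genotype": ["P1", "P1", "P2", "F1", "F1"],
            "tissue": ["leaf", "leaf", "leaf", "leaf", "root"],
            "replicate": [1, 2, 1, 1, 1],
        }
    )
    return counts, meta
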