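import numpy as np
import pytest

from asescan.synthetic_data import SimulationConfig, simulate_population
from asescan.types import PhasedGenotypeMatrix, Variant


def make_matrix(hap_pairs, variants=None, samples=None, phased=None):
    """Build a small PhasedGenotypeMatrix from a nested list of (hapA, hapB)
    pairs, shape (n_samples, n_variants)."""
    haps = np.array(hap_pairs, dtype=np.int8)
    n_samples, n_variants = haps.shape[:2]
    if samples is None:
        samples = [f"S{i}" for i in range(n_samples)]
    if variants is None:
        variants = [
            Variant(f"v{j}", "chr1", 1000 * (j + 1), "A", "G")
            for j in range(n_variants)
        ]
    return PhasedGenotypeMatrix(samples, variants, haps, phased)


@pytest.fixture
def tiny_matrix():
    """4 samples x 3 variants, all phased, no missing data."""
    return make_matrix(
        [
            [(0, 1), (0, 0), (0, 1)],
            [(1, 0), (0, 1), (1, 1)],
            [(0, 0), (1, 1), (0, 1)],
            [(1, 1), (0, 1), (0, 0)],
        ]
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A 2-gene synthetic dataset at study-default settings but reduced
    gene count, shared across read-only tests."""
    return simulate_population(SimulationConfig(n_genes=2, rng_seed=11))
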