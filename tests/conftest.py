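import numpy as np
import pytest

from pithorep import SimConfig, simulate_genome
from pithorep.detection import DetectionParams, detect_repeats


@pytest.fixture(scope="session")
def small_sim():
    """Compact planted genome for fast detection tests.

    Kept dense (40 regions in 150 kb) so per-element alignment
    multiplicities stay in the range the derivative cutoff expects.
    """
    return simulate_genome(SimConfig(genome_length=150_000, n_regions=40, seed=11))


@pytest.fixture(scope="session")
def small_detection(small_sim):
    return detect_repeats(small_sim.genome)


@pytest.fixture(scope="session")
def full_sim():
    """The study-condition genome: 600 kb, 100 regions, seed 7."""
    return simulate_genome(SimConfig(seed=7))


@pytest.fixture(scope="session")
def full_detection(full_sim):
    return detect_repeats(full_sim.genome)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
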