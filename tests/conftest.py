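import numpy as np
import pytest

from assortscan.simulate import SimConfig, sample_traps, simulate_population


@pytest.fixture(scope="session")
def small_sim():
    """One modest strong-assortment simulation shared across tests.

    Smaller than the package defaults (it backs structural checks, not the
    calibrated recovery claims), but same dynamics.
    """
    cfg = SimConfig(n_females=250, n_males=250, n_background_snps=300,
                    generations=30, seed=1234)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def small_panel(small_sim):
    """Trap sample of 31+31 males with genotype matrix and metadata."""
    meta, idx = sample_traps(small_sim, 31, seed=77)
    return meta, idx, small_sim.genotype_matrix(idx)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
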