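import numpy as np
import pytest

from phylosieve.simulate import SimulationParams, simulate_locus_set


@pytest.fixture
def rng():
    return np.random.default_rng(20150)


@pytest.fixture(scope="session")
def roster20():
    return [f"taxon{i:02d}" for i in range(1, 21)]


@pytest.fixture(scope="session")
def small_locus_set(roster20):
    """A modest simulated collection shared by tests that only read it."""
    params = SimulationParams(
        roster=roster20,
        n_loci=30,
        locus_length_range=(80, 160),
        rate_multipliers=(0.25, 1.0, 4.0),
        missing_cell_rate=0.05,
        taxon_dropout_rate=0.1,
        seed=42,
    )
    loci, truth = simulate_locus_set(params)
    return params, loci, truth
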