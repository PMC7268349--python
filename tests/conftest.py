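import numpy as np
import pytest

from sortscreen import SimConfig, analyze_guides, default_extreme_bins, simulate_screen


@pytest.fixture(scope="session")
def extreme_bins():
    """Six 10% bins on the distribution extremes, three per tail."""
    return default_extreme_bins()


@pytest.fixture(scope="session")
def mean_screen():
    """One simulated mean-altering benchmark screen (2000 guides)."""
    return simulate_screen(SimConfig(seed=11))


@pytest.fixture(scope="session")
def mean_guide_results(mean_screen):
    """Guide-level analysis of the shared benchmark screen."""
    return analyze_guides(mean_screen.counts, mean_screen.bins)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
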