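import logging

import numpy as np
import pandas as pd
import pytest

from cnagain import calling, genome, simulate

logging.getLogger("lifelines").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy_build():
    return simulate.toy_build()


@pytest.fixture(scope="session")
def thresholds():
    return calling.CallThresholds()


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 80-sample simulated cohort (seed 11) for cross-module tests."""
    return simulate.simulate_cohort(simulate.SimulationConfig(seed=11, n_samples=80))


@pytest.fixture()
def profile_factory():
    def make(sample_id="S1", segments=(), ploidy=2.0):
        seg = pd.DataFrame(list(segments), columns=["chrom", "start", "end", "cn"])
        return genome.SegmentedProfile(sample_id, seg, ploidy=ploidy)

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
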