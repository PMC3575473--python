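import numpy as np
import pytest

import hyphasim as hs


@pytest.fixture
def growth():
    return hs.GrowthParams()


@pytest.fixture
def thresholds():
    return hs.MetabolicThresholds()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_runs():
    """Five replicate full pellet simulations (31 h, default parameters).

    Shared by the pellet-scale reproduction, antibiotic-onset and
    interface-calibration tests; also timed so runtime can be asserted.
    """
    import time

    runs, durations = [], []
    for seed in range(1, 6):
        t0 = time.perf_counter()
        runs.append(hs.run(seed=seed))
        durations.append(time.perf_counter() - t0)
    return runs, durations


@pytest.fixture(scope="session")
def short_run():
    """One 8 h default run for event-log and metrics-consistency tests."""
    return hs.run(settings=hs.RunSettings(t_end=8.0), seed=7)
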